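"""Cell-cycle periodicity scoring of expression time courses.

Preprocessing follows the standard microarray recipe: drop genes with more
than half their values missing, average duplicate rows, KNN-impute the
remaining gaps (K = 10, Euclidean distance over co-observed timepoints), and
center every gene to mean zero. Each centered series is then decomposed by
discrete Fourier transform; the cell-cycle frequency index ``f_cc`` is found
either as the secondary maximum of the mean amplitude spectrum (the global
maximum in alpha-factor time courses is typically a slow synchronization
artifact, not the cell cycle) or as the primary maximum over a reference set
of known cell-cycle genes. A gene's periodicity distance is
``d_g = |argmax-frequency - f_cc|`` and genes with ``d_g`` below the knee
(``d_inflection``) of the sorted d_g curve are called cell-cycle regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import ExpressionError

_MISSING_FRAC = 0.5  # strict >: genes with more than half missing are dropped


@dataclass
class PeriodicityResult:
    """Per-gene periodicity scores plus the global frequency and cutoff.

    ``table`` is indexed by gene, sorted ascending by ``d_g`` (ties by gene
    id), with columns peak_freq, peak_amplitude, d_g, is_cyclic, rank.
    """

    table: pd.DataFrame
    f_cc: int
    d_inflection: float

    def cyclic_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_cyclic"]])

    def d_g(self, gene: str) -> float:
        return float(self.table.loc[gene, "d_g"])

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])


def _check_uniform_timepoints(columns) -> np.ndarray:
    t = np.asarray([float(c) for c in columns])
    if t.size < 2:
        raise ExpressionError("need at least two timepoints")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ExpressionError(
            "non-uniform timepoint spacing; resample the series before analysis"
        )
    return t


def preprocess(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Filter, average duplicates, KNN-impute, and center an expression matrix.

    Steps, in order: (1) drop genes with >50% missing values, (2) average
    duplicate gene rows elementwise ignoring missing, (3) impute each missing
    cell as the unweighted mean of the k nearest genes (nan-aware Euclidean
    distance), (4) center each gene to mean zero. Columns are timepoints in
    minutes and must be uniformly spaced.
    """
    if k < 1:
        raise ExpressionError("k must be >= 1")
    _check_uniform_timepoints(matrix.columns)
    df = matrix.astype(float)
    frac_missing = df.isna().mean(axis=1)
    df = df.loc[frac_missing <= _MISSING_FRAC]
    if df.empty:
        raise ExpressionError("no genes left after the missing-value filter")
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    if df.isna().all(axis=0).any():
        bad = [c for c in df.columns if df[c].isna().all()]
        raise ExpressionError(f"timepoint(s) {bad} missing in every gene")
    if df.isna().any().any():
        n_neighbors = min(k, len(df) - 1)
        if n_neighbors < 1:
            raise ExpressionError("cannot impute with a single gene")
        if n_neighbors < k:
            warnings.warn(
                f"only {n_neighbors} candidate neighbor(s) available; using all"
            )
        imputer = KNNImputer(n_neighbors=n_neighbors, weights="uniform")
        values = imputer.fit_transform(df.to_numpy())
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    df = df.sub(df.mean(axis=1), axis=0)
    df.attrs["centered"] = True
    return df


def amplitude_spectrum(series) -> np.ndarray:
    """One-sided amplitude spectrum of a complete series.

    Returns amplitudes at frequency indices 1..floor(T/2) (index 0 of the
    result is frequency 1; the DC term is excluded because series are
    centered). Scaling is 2/T, except the Nyquist term for even T which is
    scaled 1/T.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1:
        raise ExpressionError("amplitude_spectrum expects a 1-D series")
    if v.size < 4:
        raise ExpressionError("series too short (need T >= 4)")
    if np.isnan(v).any():
        raise ExpressionError("series contains missing values; impute first")
    T = v.size
    X = np.fft.rfft(v)
    amp = 2.0 * np.abs(X) / T
    if T % 2 == 0:
        amp[-1] = np.abs(X[-1]) / T
    return amp[1:]


def spectra(matrix: pd.DataFrame) -> np.ndarray:
    """Amplitude spectra for every gene row; shape (n_genes, floor(T/2))."""
    v = matrix.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ExpressionError("matrix contains missing values; preprocess first")
    T = v.shape[1]
    if T < 4:
        raise ExpressionError("series too short (need T >= 4)")
    X = np.fft.rfft(v, axis=1)
    amp = 2.0 * np.abs(X) / T
    if T % 2 == 0:
        amp[:, -1] = np.abs(X[:, -1]) / T
    return amp[:, 1:]


def _ranked_indices(mean_amp: np.ndarray) -> list[int]:
    # frequency indices (1-based) sorted by descending amplitude, ties -> lower index
    return sorted(range(1, mean_amp.size + 1), key=lambda k: (-mean_amp[k - 1], k))


def detect_cell_cycle_frequency(
    matrix: pd.DataFrame,
    mode: str = "secondary_max",
    reference_genes=None,
) -> int:
    """Identify the cell-cycle frequency index ``f_cc``.

    ``secondary_max``: the frequency with the second-largest mean amplitude
    over all genes (the largest is treated as a non-cell-cycle artifact).
    ``reference_set``: the frequency with the largest mean amplitude over a
    supplied set of known cell-cycle genes. Ties resolve to the lower index.
    """
    S = spectra(matrix)
    if mode == "secondary_max":
        mean_amp = S.mean(axis=0)
        ranked = _ranked_indices(mean_amp)
        if mean_amp[ranked[0] - 1] == mean_amp[ranked[1] - 1]:
            warnings.warn("tie at the decisive rank; resolved to lower frequency index")
        return ranked[1]
    if mode == "reference_set":
        if reference_genes is None or len(reference_genes) == 0:
            raise ExpressionError("reference_set mode requires a nonempty reference set")
        present = [g for g in reference_genes if g in matrix.index]
        if not present:
            raise ExpressionError("none of the reference genes are in the matrix")
        if len(present) < len(set(reference_genes)):
            warnings.warn(
                f"{len(set(reference_genes)) - len(present)} reference gene(s) "
                "absent from the matrix; using the intersection"
            )
        sub = spectra(matrix.loc[present])
        mean_amp = sub.mean(axis=0)
        return _ranked_indices(mean_amp)[0]
    raise ExpressionError(f"unknown mode {mode!r}")


def knee_value(sorted_vals: np.ndarray) -> float:
    """Knee of an ascending curve: the value at the point of maximum
    perpendicular distance to the chord joining the curve's endpoints
    (coordinates normalized to the unit square)."""
    v = np.asarray(sorted_vals, dtype=float)
    if v.size < 3:
        raise ExpressionError("need at least 3 points to locate a knee")
    if v[0] == v[-1]:
        raise ExpressionError("degenerate distribution (all values equal)")
    x = np.linspace(0.0, 1.0, v.size)
    y = (v - v[0]) / (v[-1] - v[0])
    i = int(np.argmax(np.abs(y - x)))
    return float(v[i])


def score_and_classify(
    matrix: pd.DataFrame,
    f_cc: int,
    d_threshold: float | None = None,
) -> PeriodicityResult:
    """Score every gene's distance to the cell-cycle frequency and classify.

    ``d_g = |argmax-amplitude frequency index - f_cc|``; the cutoff
    ``d_inflection`` is the knee of the sorted d_g curve unless an explicit
    ``d_threshold`` is given. ``is_cyclic`` iff ``d_g < d_inflection``. Genes
    are ranked ascending by d_g (ties by gene id).
    """
    S = spectra(matrix)
    K = S.shape[1]
    if not (1 <= f_cc <= K):
        raise ExpressionError(f"f_cc = {f_cc} outside valid frequency range 1..{K}")
    peak = np.argmax(S, axis=1) + 1  # np.argmax returns the lowest tied index
    amp = S[np.arange(len(S)), peak - 1]
    d_g = np.abs(peak - f_cc).astype(float)
    if d_threshold is not None:
        d_inf = float(d_threshold)
    else:
        sorted_d = np.sort(d_g)
        if sorted_d[0] == sorted_d[-1]:
            raise ExpressionError(
                "all d_g values are equal; the inflection point is undefined — "
                "pass an explicit d_threshold"
            )
        d_inf = knee_value(sorted_d)
    table = pd.DataFrame(
        {
            "peak_freq": peak,
            "peak_amplitude": amp,
            "d_g": d_g,
            "is_cyclic": d_g < d_inf,
        },
        index=matrix.index,
    )
    order = np.lexsort((table.index.astype(str), table["d_g"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return PeriodicityResult(table=table, f_cc=int(f_cc), d_inflection=d_inf)
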