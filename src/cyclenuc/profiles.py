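"""Motif-centered nucleosome profile matrices and the associated statistics.

Each (gene, motif-hit) pair contributes one row of normalized occupancy over
offsets -flank..+flank around the motif center, extracted in gene orientation
(5'->3' toward the ATG) and ordered by the gene's periodicity distance d_g.
Group comparisons use Welch's t test on the per-row values at the trough
(minimum) of the pooled average profile, and the Mann-Whitney U test for the
cyclic-vs-acyclic association between occupancy and periodicity.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ProfileError
from .motifs import MotifHit
from .periodicity import PeriodicityResult
from .track import NucleosomeTrack, extract_window

logger = logging.getLogger(__name__)

EXACT_LIMIT = 20  # combined sample size at or below which the U test is exact


@dataclass
class ProfileMatrix:
    """Rows of motif-centered occupancy, periodicity-ranked.

    ``values`` is (n_rows, 2*flank + 1) with NaN at contig edges; ``meta``
    carries gene, d_g, is_cyclic and the hit's ATG-relative offset per row,
    in the same order.
    """

    values: np.ndarray
    offsets: np.ndarray
    meta: pd.DataFrame

    @property
    def flank(self) -> int:
        return (self.values.shape[1] - 1) // 2

    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, mask) -> "ProfileMatrix":
        mask = np.asarray(mask)
        return ProfileMatrix(
            self.values[mask], self.offsets, self.meta.iloc[mask].reset_index(drop=True)
        )


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    trough_offset: int | None = None


def build_profile_matrix(
    track: NucleosomeTrack,
    hits: Sequence[MotifHit],
    periodicity: PeriodicityResult,
    flank: int = 300,
) -> ProfileMatrix:
    """One row per (gene, hit): the +/-flank occupancy window in gene
    orientation, rows sorted ascending by the gene's d_g (ties by gene id).

    Hits whose gene has no periodicity entry are dropped with a warning.
    """
    if not track.normalized:
        raise ProfileError("profile matrices are built from the normalized track")
    tab = periodicity.table
    rows = []
    meta_rows = []
    dropped = 0
    for h in hits:
        if h.gene is None or h.gene not in tab.index:
            dropped += 1
            continue
        if h.upstream_strand is None:
            gene_strand = h.strand
        else:
            gene_strand = "+" if h.strand == h.upstream_strand else "-"
        window = extract_window(
            track, h.contig, h.genomic_center, flank, orient_minus=gene_strand == "-"
        )
        rows.append(window)
        meta_rows.append(
            {
                "gene": h.gene,
                "d_g": float(tab.loc[h.gene, "d_g"]),
                "is_cyclic": bool(tab.loc[h.gene, "is_cyclic"]),
                "offset": h.offset,
            }
        )
    if dropped:
        warnings.warn(f"dropped {dropped} hit(s) without a periodicity entry")
    if not rows:
        raise ProfileError("no profile rows could be built")
    values = np.vstack(rows)
    meta = pd.DataFrame(meta_rows)
    order = np.lexsort((meta["gene"].astype(str), meta["d_g"].to_numpy()))
    return ProfileMatrix(
        values=values[order],
        offsets=np.arange(-flank, flank + 1),
        meta=meta.iloc[order].reset_index(drop=True),
    )


def average_profile(
    matrix: ProfileMatrix, rows: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset mean (ignoring missing cells) and per-offset n over a row subset."""
    if rows is None:
        v = matrix.values
    else:
        rows = np.asarray(rows)
        if rows.size == 0:
            raise ProfileError("cannot average an empty row subset")
        v = matrix.values[rows]
    if v.shape[0] == 0:
        raise ProfileError("cannot average an empty row subset")
    n = np.sum(~np.isnan(v), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(v, axis=0)
    return mean, n


def find_trough(avg: np.ndarray, offsets: np.ndarray) -> int:
    """Offset of the minimum of an average profile.

    Ties break toward the offset nearest the motif center (0), then to the
    negative (upstream) side; a flat profile therefore yields 0.
    """
    finite = np.flatnonzero(~np.isnan(avg))
    if finite.size == 0:
        raise ProfileError("average profile has no finite values")
    best = min(finite, key=lambda j: (avg[j], abs(int(offsets[j])), int(offsets[j])))
    return int(offsets[best])


def _welch_from_values(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        if float(np.mean(a)) == float(np.mean(b)):
            return 0.0, 1.0
        return math.inf, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def trough_welch_test(
    matrix_a: ProfileMatrix, matrix_b: ProfileMatrix
) -> TestResult:
    """Welch's t test between two groups at the pooled-average trough offset.

    The trough is located on the average profile of all rows of both groups
    together; the per-row values at that single offset are then compared by a
    two-sided Welch (unequal-variance) t test.
    """
    pooled = np.vstack([matrix_a.values, matrix_b.values])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(pooled, axis=0)
    offsets = matrix_a.offsets
    trough = find_trough(avg, offsets)
    col = int(np.flatnonzero(offsets == trough)[0])
    a = matrix_a.values[:, col]
    b = matrix_b.values[:, col]
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ProfileError("need >= 2 complete values at the trough in each group")
    t, p = _welch_from_values(a, b)
    return TestResult("welch_t", t, p, a.size, b.size, trough)


def _exact_mwu_p(pooled: np.ndarray, n: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration over all C(n+m, n) labelings.

    Handles ties exactly: the null distribution of U is built from the
    observed pooled values themselves. p = P(|U - nm/2| >= |u_obs - nm/2|).
    """
    m = pooled.size - n
    ranks = stats.rankdata(pooled)
    center = n * m / 2.0
    target = abs(u_obs - center) - 1e-12
    count = 0
    total = 0
    base = n * (n + 1) / 2.0
    for idx in itertools.combinations(range(pooled.size), n):
        u = sum(ranks[i] for i in idx) - base
        if abs(u - center) >= target:
            count += 1
        total += 1
    return count / total


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact for combined n <= 20 (full enumeration when ties are present),
    normal approximation with tie and continuity corrections otherwise. The
    statistic reported is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ProfileError("both groups must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n + m <= EXACT_LIMIT:
        has_ties = np.unique(pooled).size < pooled.size
        if has_ties:
            p = _exact_mwu_p(pooled, n, u_x)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            p = float(res.pvalue)
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return TestResult("mann_whitney_u", u_x, min(p, 1.0), n, m)


def periodicity_association_test(
    matrix: ProfileMatrix,
    summary_window: int | None = None,
) -> TestResult:
    """Association between nucleosome occupancy at motifs and periodicity.

    Rows are split by the gene's is_cyclic label; each row is summarized by
    its value at the pooled-average trough offset (default) or by its mean
    over offsets within +/-``summary_window`` of the motif center. The two
    groups of summaries are compared by a two-sided Mann-Whitney U test.
    """
    cyclic_mask = matrix.meta["is_cyclic"].to_numpy(dtype=bool)
    if not cyclic_mask.any():
        raise ProfileError("cyclic group is empty")
    if cyclic_mask.all():
        raise ProfileError("acyclic group is empty")
    if summary_window is None:
        avg, _ = average_profile(matrix)
        trough = find_trough(avg, matrix.offsets)
        col = int(np.flatnonzero(matrix.offsets == trough)[0])
        summaries = matrix.values[:, col]
    else:
        trough = None
        cols = np.abs(matrix.offsets) <= summary_window
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            summaries = np.nanmean(matrix.values[:, cols], axis=1)
    ok = ~np.isnan(summaries)
    xc = summaries[cyclic_mask & ok]
    ya = summaries[~cyclic_mask & ok]
    if xc.size == 0:
        raise ProfileError("cyclic group is empty at the summary offset")
    if ya.size == 0:
        raise ProfileError("acyclic group is empty at the summary offset")
    res = mann_whitney(xc, ya)
    res.trough_offset = trough
    return res


def export_figure_tables(
    matrix: ProfileMatrix,
    expression: pd.DataFrame,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write row-aligned profile and expression TSVs for heatmap rendering.

    Both files share one row per (gene, hit) in the matrix's periodicity
    order; genes absent from the expression matrix are excluded from both and
    logged. Round-tripping the files reproduces the matrices exactly.
    """
    shared = matrix.meta["gene"].isin(expression.index).to_numpy()
    if not shared.any():
        raise ProfileError("matrix and expression share no genes")
    n_excluded = int((~shared).sum())
    if n_excluded:
        logger.info("excluded %d row(s) with genes absent from expression", n_excluded)
    sub = matrix.subset(shared)
    out_prefix = Path(out_prefix)
    prof_path = out_prefix.parent / f"{out_prefix.name}_profiles.tsv"
    expr_path = out_prefix.parent / f"{out_prefix.name}_expression.tsv"
    prof = pd.DataFrame(sub.values, columns=sub.offsets)
    prof.insert(0, "motif_offset", sub.meta["offset"].to_numpy())
    prof.insert(0, "gene", sub.meta["gene"].to_numpy())
    # %.17g round-trips float64 exactly even through mixed-dtype frames
    prof.to_csv(prof_path, sep="\t", index=False, float_format="%.17g")
    expr = expression.loc[sub.meta["gene"]].reset_index()
    expr.columns = ["gene"] + [str(c) for c in expression.columns]
    expr.to_csv(expr_path, sep="\t", index=False, float_format="%.17g")
    return prof_path, expr_path


def read_figure_tables(prof_path, expr_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bit-exact reader for the tables written by :func:`export_figure_tables`."""
    prof = pd.read_csv(prof_path, sep="\t", float_precision="round_trip")
    expr = pd.read_csv(expr_path, sep="\t", float_precision="round_trip")
    return prof, expr
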