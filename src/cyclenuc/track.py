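"""Per-base nucleosome occupancy tracks: pileup, normalization, QC filters,
and motif-centered window extraction.

Reads are extended from their 5' end to a mono-nucleosome footprint
(147 bp by default) and piled up per base. The raw track is normalized as
``log(raw + pseudocount) / log(median(raw + pseudocount))`` so the genome
median of the normalized signal is 1. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, NormalizationError, TrackError


@dataclass
class NucleosomeTrack:
    """Per-contig vectors of per-base signal.

    ``normalized`` distinguishes raw integer pileup counts from the
    log-median-normalized signal; ``genome_median_raw`` is the median raw
    count recorded at normalization time.
    """

    data: dict[str, np.ndarray]
    normalized: bool = False
    genome_median_raw: float | None = None
    n_rejected_reads: int = 0

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])


@dataclass
class ContigCoverage:
    contig: str
    covered_bp: int
    length: int
    fraction: float
    passes: bool


def pileup_reads(
    reads: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    extension: int = 147,
) -> NucleosomeTrack:
    """Pile mapped read intervals into a raw per-base count track.

    Each read contributes +1 to ``extension`` bases starting at its 5' end in
    read orientation, clipped at contig ends. Reads whose recorded interval
    falls outside the contig are rejected (counted, warned); an unknown contig
    is an error.
    """
    required = {"contig", "start", "end", "strand"}
    if not required.issubset(reads.columns):
        raise TrackError(f"reads table must have columns {sorted(required)}")
    if len(reads) and extension < int((reads["end"] - reads["start"]).max()):
        raise ConfigError("extension must be >= read length")
    data = {c: np.zeros(int(n), dtype=float) for c, n in contig_lengths.items()}
    rejected = 0
    for contig, grp in reads.groupby("contig", sort=False):
        if contig not in data:
            raise TrackError(f"reads mapped to unknown contig {contig!r}")
        n = len(data[contig])
        start = grp["start"].to_numpy(dtype=int)
        end = grp["end"].to_numpy(dtype=int)
        ok = (start >= 0) & (end <= n) & (start < end)
        rejected += int((~ok).sum())
        start, end = start[ok], end[ok]
        plus = grp["strand"].to_numpy()[ok] == "+"
        fivep = np.where(plus, start, end - 1)
        lo = np.where(plus, fivep, fivep - extension + 1)
        hi = lo + extension
        lo = np.clip(lo, 0, n)
        hi = np.clip(hi, 0, n)
        diff = np.zeros(n + 1, dtype=float)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        data[contig] += np.cumsum(diff[:-1])
    if rejected:
        warnings.warn(f"rejected {rejected} read(s) outside contig bounds")
    return NucleosomeTrack(data=data, normalized=False, n_rejected_reads=rejected)


def normalize_track(track: NucleosomeTrack, pseudocount: float = 1.0) -> NucleosomeTrack:
    """Log-median normalization: ``out = log(raw+pc) / log(median(raw+pc))``.

    The genome median of the output is 1. Raises if the track is already
    normalized (idempotence guard) or if the genome median after the
    pseudocount is <= 1 (the log ratio is then undefined or degenerate).
    """
    if track.normalized:
        raise NormalizationError("track is already normalized")
    allv = track.concatenated() + pseudocount
    med = float(np.median(allv))
    if med <= 1.0:
        raise NormalizationError(
            f"median(raw + pseudocount) = {med:g} <= 1; log-median normalization undefined"
        )
    logmed = np.log(med)
    data = {c: np.log(v + pseudocount) / logmed for c, v in track.data.items()}
    return NucleosomeTrack(
        data=data,
        normalized=True,
        genome_median_raw=float(np.median(track.concatenated())),
        n_rejected_reads=track.n_rejected_reads,
    )


def _union_bp(starts: np.ndarray, ends: np.ndarray) -> int:
    if starts.size == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
        else:
            cur_e = max(cur_e, int(e))
    total += cur_e - cur_s
    return total


def contig_coverage_filter(
    regions: pd.DataFrame | None = None,
    *,
    track: NucleosomeTrack | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    threshold: float = 0.20,
    call_threshold: float = 1.0,
) -> list[ContigCoverage]:
    """Fraction of each contig covered by nucleosome regions; strict ``>`` cutoff.

    Either pass called nucleosome ``regions`` (contig/start/end intervals;
    overlaps are unioned) plus ``contig_lengths``, or a normalized ``track``,
    in which case covered bases are those with signal >= ``call_threshold``
    (median-level occupancy as a proxy for called nucleosome centers).
    """
    if (regions is None) == (track is None):
        raise TrackError("pass exactly one of regions= or track=")
    out: list[ContigCoverage] = []
    if track is not None:
        lengths = contig_lengths or track.contig_lengths()
        for contig in sorted(lengths):
            n = int(lengths[contig])
            if n == 0:
                raise TrackError(f"zero-length contig {contig!r}")
            covered = int((track.data[contig] >= call_threshold).sum())
            frac = covered / n
            out.append(ContigCoverage(contig, covered, n, frac, frac > threshold))
        return out
    if contig_lengths is None:
        raise TrackError("contig_lengths required with interval regions")
    by_contig = dict(tuple(regions.groupby("contig", sort=False)))
    for contig in sorted(contig_lengths):
        n = int(contig_lengths[contig])
        if n == 0:
            raise TrackError(f"zero-length contig {contig!r}")
        grp = by_contig.get(contig)
        if grp is None:
            covered = 0
        else:
            covered = _union_bp(
                grp["start"].to_numpy(int).clip(0, n),
                grp["end"].to_numpy(int).clip(0, n),
            )
        frac = covered / n
        out.append(ContigCoverage(contig, covered, n, frac, frac > threshold))
    return out


def exclude_high_signal_genes(
    track: NucleosomeTrack,
    genes: pd.DataFrame,
    factor: float = 100.0,
) -> tuple[list[str], dict[str, str]]:
    """Drop genes whose mean raw signal exceeds ``factor`` x the genome mean.

    Strict ``>`` at the cutoff: a gene at exactly ``factor`` x is retained.
    Genes on contigs absent from the track are excluded with reason
    'uncovered'. Returns (retained gene names, {excluded: reason}).
    """
    if track.normalized:
        raise TrackError("exclusion filter operates on the raw track")
    if factor <= 1:
        raise ConfigError("factor must be > 1")
    total = track.total_signal()
    nbases = sum(len(v) for v in track.data.values())
    genome_mean = total / nbases if nbases else 0.0
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for _, g in genes.iterrows():
        name = g["name"]
        contig = g["contig"]
        if contig not in track.data:
            excluded[name] = "uncovered"
            continue
        span = track.data[contig][int(g["start"]) : int(g["end"])]
        if span.size == 0:
            excluded[name] = "uncovered"
            continue
        if genome_mean > 0 and float(span.mean()) > factor * genome_mean:
            excluded[name] = "high_signal"
        else:
            retained.append(name)
    return retained, excluded


def extract_window(
    track: NucleosomeTrack,
    contig: str,
    center: int,
    flank: int,
    orient_minus: bool = False,
) -> np.ndarray:
    """Signal vector of length ``2*flank + 1`` centered on ``center``.

    Index ``i`` holds the signal at ``center - flank + i`` (plus orientation)
    or ``center + flank - i`` (minus). Positions off the contig are NaN, not
    zero; a center off the contig is an error.
    """
    if contig not in track.data:
        raise TrackError(f"unknown contig {contig!r}")
    v = track.data[contig]
    n = len(v)
    if not (0 <= center < n):
        raise TrackError(f"center {center} outside contig {contig!r} of length {n}")
    out = np.full(2 * flank + 1, np.nan)
    lo = max(0, center - flank)
    hi = min(n, center + flank + 1)
    out[lo - (center - flank) : hi - (center - flank)] = v[lo:hi]
    if orient_minus:
        out = out[::-1]
    return out
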