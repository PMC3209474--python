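"""Bracket-consensus motifs: parsing, strand-aware scanning, upstream extraction,
gene assignment, and mutual-information enrichment against periodicity bins.

A consensus like ``[AGT][AT]CGCGT[CT][AGT]`` (the MBP1 site) is a sequence of
allowed-base sets; a window matches when every position's base is in its set.
``N`` never matches. Upstream hits are reported with the motif *center* offset
relative to the coding start (negative = upstream), with the upstream window
covering offsets ``[-length, 0)``.
"""

from __future__ import annotations

import functools
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MotifParseError, CycleNucError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus in bracket notation.

    ``positions[i]`` is the set of bases allowed at motif position ``i``.
    """

    pattern: str
    positions: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        """True if ``window`` (length == motif length) satisfies every position."""
        if len(window) != len(self.positions):
            return False
        return all(b in s for b, s in zip(window.upper(), self.positions))

    def reverse_complement(self) -> "ConsensusMotif":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_sets = tuple(
            frozenset(comp[b] for b in s) for s in reversed(self.positions)
        )
        return ConsensusMotif(pattern=_sets_to_pattern(rc_sets), positions=rc_sets)


def _sets_to_pattern(sets: Iterable[frozenset]) -> str:
    parts = []
    for s in sets:
        bases = "".join(sorted(s))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def parse_consensus(pattern: str) -> ConsensusMotif:
    """Parse a bracket-class consensus string into a :class:`ConsensusMotif`.

    Raises :class:`MotifParseError` naming the offending position for
    unbalanced brackets, empty classes, or invalid characters.
    """
    sets: list[frozenset] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise MotifParseError(f"unbalanced '[' at position {i} in {pattern!r}")
            cls = pattern[i + 1 : j].upper()
            if not cls:
                raise MotifParseError(f"empty class at position {i} in {pattern!r}")
            bad = set(cls) - _VALID_BASES
            if bad:
                raise MotifParseError(
                    f"invalid character(s) {sorted(bad)} at position {i} in {pattern!r}"
                )
            sets.append(frozenset(cls))
            i = j + 1
        elif c == "]":
            raise MotifParseError(f"unbalanced ']' at position {i} in {pattern!r}")
        else:
            cu = c.upper()
            if cu not in _VALID_BASES:
                raise MotifParseError(
                    f"invalid character {c!r} at position {i} in {pattern!r}"
                )
            sets.append(frozenset(cu))
            i += 1
    if not sets:
        raise MotifParseError("empty pattern")
    return ConsensusMotif(pattern=pattern, positions=tuple(sets))


@dataclass
class MotifHit:
    """A consensus match.

    Fresh from :func:`scan_sequence` the coordinates are local to the scanned
    sequence and ``gene``/``offset`` are unset; :func:`assign_hits_to_genes`
    lifts hits from gene-oriented upstream windows into genomic coordinates and
    fills in the gene association, the ATG-relative center ``offset`` and the
    genomic center position. ``matched_seq`` is always the sequence that
    matches the motif (i.e. reverse-complemented for '-' hits).
    """

    contig: str
    start: int
    end: int
    strand: str
    matched_seq: str
    gene: str | None = None
    offset: int | None = None
    genomic_center: int | None = None
    upstream_strand: str | None = None


@functools.lru_cache(maxsize=64)
def _compiled(pattern: str) -> "re.Pattern[str]":
    motif = parse_consensus(pattern)
    body = "".join(
        "".join(s) if len(s) == 1 else "[" + "".join(sorted(s)) + "]"
        for s in motif.positions
    )
    # lookahead makes overlapping matches visible
    return re.compile(f"(?=({body}))")


def scan_sequence(
    seq: str,
    motif: ConsensusMotif,
    strands: str = "both",
    contig: str = "",
) -> list[MotifHit]:
    """Report every consensus match in ``seq`` on the requested strands.

    Minus-strand matches are found by scanning ``seq`` for the reverse
    complement of the motif, and reported with strand ``'-'`` at their
    location on the given sequence. Overlapping hits are all reported.
    """
    if strands not in ("plus", "both"):
        raise CycleNucError(f"strands must be 'plus' or 'both', got {strands!r}")
    s = seq.upper()
    hits: list[MotifHit] = []
    for m in _compiled(motif.pattern).finditer(s):
        frag = m.group(1)
        hits.append(
            MotifHit(contig, m.start(), m.start() + len(frag), "+", frag)
        )
    if strands == "both":
        rc = motif.reverse_complement()
        if rc.pattern == motif.pattern:
            # palindromic consensus: '-' hits coincide with '+' hits
            rc_iter = _compiled(motif.pattern).finditer(s)
        else:
            rc_iter = _compiled(rc.pattern).finditer(s)
        for m in rc_iter:
            frag = m.group(1)
            hits.append(
                MotifHit(
                    contig,
                    m.start(),
                    m.start() + len(frag),
                    "-",
                    reverse_complement(frag),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class UpstreamRegion:
    """Gene-oriented upstream window ending at the coding start.

    ``seq[i]`` sits at ATG-relative offset ``offsets[i]`` (in ``[-L, 0)``) and
    genomic coordinate ``genomic[i]``. Minus-strand genes are reverse
    complemented so the sequence always reads 5'->3' toward the ATG.
    """

    gene: str
    contig: str
    strand: str
    seq: str
    offsets: np.ndarray = field(repr=False)
    genomic: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.seq)


def extract_upstream(
    gene: Mapping,
    genome: Mapping[str, str],
    length: int = 600,
) -> UpstreamRegion:
    """Extract the ``length`` bases 5' of a gene's coding start.

    ``gene`` needs keys contig, strand, name and coding_start (genomic
    coordinate of the first ATG base). The window is truncated, not padded,
    at contig ends.
    """
    contig = gene["contig"]
    if contig not in genome:
        raise CycleNucError(f"gene {gene['name']!r} on unknown contig {contig!r}")
    chrom = genome[contig]
    cs = int(gene["coding_start"])
    name = gene["name"]
    if gene["strand"] == "+":
        lo = max(0, cs - length)
        seq = chrom[lo:cs]
        L = len(seq)
        genomic = np.arange(lo, cs)
        offsets = np.arange(-L, 0)
    else:
        hi = min(len(chrom), cs + 1 + length)
        window = chrom[cs + 1 : hi]
        seq = reverse_complement(window)
        L = len(seq)
        genomic = np.arange(cs + L, cs, -1)
        offsets = np.arange(-L, 0)
    return UpstreamRegion(name, contig, gene["strand"], seq, offsets, genomic)


def assign_hits_to_genes(
    hits_by_gene: Mapping[str, Sequence[MotifHit]],
    regions: Mapping[str, UpstreamRegion],
) -> list[MotifHit]:
    """Annotate upstream-local hits with gene, ATG-relative center offset and
    genomic coordinates.

    The motif center is ``start + len // 2`` in gene-oriented coordinates.
    Genes with zero hits simply contribute no records; a hit shared by two
    genes' overlapping windows appears once per gene (callers pass it under
    both genes).
    """
    out: list[MotifHit] = []
    for gene, hits in hits_by_gene.items():
        region = regions[gene]
        for h in hits:
            center_local = h.start + (h.end - h.start) // 2
            offset = int(region.offsets[center_local])
            gcenter = int(region.genomic[center_local])
            gpos = region.genomic[h.start : h.end]
            gstart, gend = int(gpos.min()), int(gpos.max()) + 1
            if region.strand == "+":
                genomic_strand = h.strand
            else:
                genomic_strand = "-" if h.strand == "+" else "+"
            out.append(
                MotifHit(
                    contig=region.contig,
                    start=gstart,
                    end=gend,
                    strand=genomic_strand,
                    matched_seq=h.matched_seq,
                    gene=gene,
                    offset=offset,
                    genomic_center=gcenter,
                    upstream_strand=h.strand,
                )
            )
    return out


def find_upstream_hits(
    genes: pd.DataFrame,
    genome: Mapping[str, str],
    motif: ConsensusMotif,
    length: int = 600,
    strands: str = "both",
) -> tuple[list[MotifHit], dict[str, UpstreamRegion]]:
    """Convenience: extract every gene's upstream window, scan it, and assign hits."""
    regions: dict[str, UpstreamRegion] = {}
    raw: dict[str, list[MotifHit]] = {}
    for _, g in genes.iterrows():
        region = extract_upstream(g, genome, length)
        regions[region.gene] = region
        raw[region.gene] = scan_sequence(region.seq, motif, strands, contig=region.contig)
    return assign_hits_to_genes(raw, regions), regions


@dataclass
class MIResult:
    mi_bits: float
    p_value: float
    n_bins: int
    n_perm: int
    n_genes: int


def _mi_bits(presence: np.ndarray, bin_id: np.ndarray, n_bins: int) -> float:
    n = presence.size
    joint = np.bincount(bin_id * 2 + presence.astype(int), minlength=2 * n_bins)
    p = joint.reshape(n_bins, 2) / n
    pb = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pb * pm))
    return float(np.nansum(terms))


def mi_enrichment(
    presence: Sequence[bool],
    d_ranks: Sequence[int],
    n_bins: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> MIResult:
    """Mutual information (bits) between motif presence and periodicity-rank bins.

    Genes are split by rank into ``n_bins`` near-equal bins (rank 1 = most
    cell-cycle-like). The permutation p-value shuffles the presence flags and
    uses the (1 + hits) / (1 + n_perm) correction so p is never exactly zero.
    """
    presence = np.asarray(presence, dtype=bool)
    ranks = np.asarray(d_ranks, dtype=int)
    n = presence.size
    if ranks.size != n:
        raise CycleNucError("presence and d_ranks length mismatch")
    if sorted(ranks.tolist()) != list(range(1, n + 1)):
        raise CycleNucError("d_ranks must be a permutation of 1..n")
    if n_bins < 2:
        raise CycleNucError("n_bins must be >= 2")
    if presence.all() or not presence.any():
        warnings.warn("motif presence is constant; MI undefined, returning 0")
        return MIResult(0.0, 1.0, n_bins, n_perm, n)
    order = np.argsort(ranks)
    bin_id = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_id[chunk] = b
    observed = _mi_bits(presence, bin_id, n_bins)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _mi_bits(rng.permutation(presence), bin_id, n_bins) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MIResult(observed, p, n_bins, n_perm, n)
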