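"""Cross-species classification of upstream motif conservation.

Three progressively stricter definitions are implemented for a motif found
upstream of a gene in species A with an ortholog in species B:

* presence  — conserved iff the ortholog's 600-bp upstream window contains at
  least one consensus match anywhere (position-free).
* positional — conserved iff some ortholog hit center lies within a +/-window
  (default 200 bp) of the same ATG-relative position; 'absent' otherwise.
* aligned   — on a pairwise upstream alignment: conserved iff the whole motif
  span is gap-free in both species and the ortholog bases still realize the
  consensus (identical or any other allowed form); 'lost' if aligned but no
  longer a consensus match; 'unaligned' if any motif column is gapped.

Also provides the TF-bound/unbound gene partition and the top-quantile
expression filter used to restrict analyses to expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentIntegrityError, CycleNucError
from .motifs import ConsensusMotif, MotifHit, reverse_complement

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class PairwiseAlignment:
    """Gapped alignment of two gene-oriented upstream windows.

    Column offsets map each non-gap column to that species' ATG-relative
    offset (the degapped sequence occupies offsets ``[-L, 0)``).
    """

    gene_a: str
    gene_b: str
    aligned_a: str
    aligned_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentIntegrityError(
                f"aligned lengths differ for {self.gene_a}/{self.gene_b}"
            )

    def degapped(self, which: str) -> str:
        s = self.aligned_a if which == "a" else self.aligned_b
        return s.replace(GAP, "")

    def offset_to_column(self, which: str) -> dict[int, int]:
        s = self.aligned_a if which == "a" else self.aligned_b
        cols = [i for i, c in enumerate(s) if c != GAP]
        L = len(cols)
        return {-L + j: col for j, col in enumerate(cols)}


def verify_alignment(
    aln: PairwiseAlignment, upstream_a: str, upstream_b: str
) -> None:
    """Integrity check: the degapped alignment must equal the stored upstreams."""
    if aln.degapped("a") != upstream_a.upper():
        raise AlignmentIntegrityError(
            f"degapped A side of {aln.gene_a} disagrees with its upstream sequence"
        )
    if aln.degapped("b") != upstream_b.upper():
        raise AlignmentIntegrityError(
            f"degapped B side of {aln.gene_b} disagrees with its upstream sequence"
        )


def read_ortholog_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a two-column ortholog table: assignments must be one-to-one."""
    if df.shape[1] < 2:
        raise CycleNucError("ortholog table needs two columns (gene_a, gene_b)")
    df = df.iloc[:, :2].copy()
    df.columns = ["gene_a", "gene_b"]
    if df["gene_a"].duplicated().any() or df["gene_b"].duplicated().any():
        raise CycleNucError("many-to-many ortholog rows are not supported")
    return df


def classify_presence(
    hit: MotifHit, ortholog_hits_in_upstream: Sequence[MotifHit]
) -> str:
    """'conserved' iff the ortholog upstream has >= 1 consensus match anywhere."""
    return "conserved" if len(ortholog_hits_in_upstream) > 0 else "absent"


def classify_positional(
    hit: MotifHit,
    ortholog_hits: Sequence[MotifHit],
    window: int = 200,
) -> str:
    """'absent' iff no ortholog hit center within +/-``window`` bp of the
    hit's ATG-relative center; 'conserved' otherwise."""
    if hit.offset is None:
        raise CycleNucError("hit has no ATG-relative offset; assign it to a gene first")
    for oh in ortholog_hits:
        if oh.offset is not None and abs(oh.offset - hit.offset) <= window:
            return "conserved"
    return "absent"


def classify_aligned(
    hit: MotifHit,
    alignment: PairwiseAlignment,
    motif: ConsensusMotif,
    upstream_a: str | None = None,
) -> str:
    """Fate of a motif under the aligned-position rule.

    'conserved' iff every motif column is gap-free in both species and the
    ortholog bases match the consensus in either orientation; 'lost' iff
    gap-free but no longer a consensus realization; 'unaligned' iff any motif
    column is gapped; 'not_applicable' if the alignment does not cover the
    motif span.
    """
    if hit.offset is None:
        raise CycleNucError("hit has no ATG-relative offset; assign it to a gene first")
    L = motif.length
    start_off = hit.offset - L // 2
    span = range(start_off, start_off + L)
    omap = alignment.offset_to_column("a")
    if any(o not in omap for o in span):
        return "not_applicable"
    cols = [omap[o] for o in span]
    a_bases = "".join(alignment.aligned_a[c] for c in cols)
    if upstream_a is not None:
        expect = (
            hit.matched_seq
            if hit.upstream_strand in (None, "+")
            else reverse_complement(hit.matched_seq)
        )
        if a_bases.upper() != expect.upper():
            raise AlignmentIntegrityError(
                f"alignment of {alignment.gene_a} disagrees with motif hit "
                f"sequence at offsets {start_off}..{start_off + L - 1}"
            )
    b_bases = "".join(alignment.aligned_b[c] for c in cols)
    if GAP in b_bases or GAP in a_bases:
        return "unaligned"
    if motif.matches(b_bases) or motif.matches(reverse_complement(b_bases)):
        return "conserved"
    return "lost"


@dataclass
class ConservationCall:
    gene_a: str
    gene_b: str | None
    offset_a: int
    status_presence: str
    status_positional: str
    status_aligned: str


def classify_hits(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    orthologs: pd.DataFrame,
    motif: ConsensusMotif | None = None,
    alignments: Mapping[str, PairwiseAlignment] | None = None,
    window: int = 200,
) -> list[ConservationCall]:
    """Classify every species-A upstream hit under all three definitions.

    ``orthologs`` maps gene_a -> gene_b (one-to-one). Hits on genes without
    an ortholog are reported 'not_applicable' and logged. The aligned status
    requires ``motif`` and an alignment keyed by gene_a, else
    'not_applicable'.
    """
    orthologs = read_ortholog_frame(orthologs)
    a2b = dict(zip(orthologs["gene_a"], orthologs["gene_b"]))
    hits_b_by_gene: dict[str, list[MotifHit]] = {}
    for h in hits_b:
        hits_b_by_gene.setdefault(h.gene, []).append(h)
    calls: list[ConservationCall] = []
    n_no_ortholog = 0
    for h in hits_a:
        gene_b = a2b.get(h.gene)
        if gene_b is None:
            n_no_ortholog += 1
            calls.append(
                ConservationCall(
                    h.gene, None, h.offset, "not_applicable",
                    "not_applicable", "not_applicable",
                )
            )
            continue
        ortho_hits = hits_b_by_gene.get(gene_b, [])
        presence = classify_presence(h, ortho_hits)
        positional = classify_positional(h, ortho_hits, window=window)
        if motif is not None and alignments is not None and h.gene in alignments:
            aligned = classify_aligned(h, alignments[h.gene], motif)
        else:
            aligned = "not_applicable"
        calls.append(
            ConservationCall(h.gene, gene_b, h.offset, presence, positional, aligned)
        )
    if n_no_ortholog:
        logger.info("%d hit(s) on genes without an ortholog; excluded", n_no_ortholog)
    return calls


def partition_by_binding(
    hits: Sequence[MotifHit],
    bound_sites: pd.DataFrame,
) -> tuple[set, set]:
    """Partition genes with upstream hits into TF-bound and unbound sets.

    ``bound_sites`` holds genomic intervals (contig/start/end). A gene is
    bound iff at least one of its upstream consensus hits overlaps a bound
    site; unbound iff it has hits but none overlap. Genes without hits are in
    neither set.
    """
    sites_by_contig: dict[str, list[tuple[int, int]]] = {}
    for _, s in bound_sites.iterrows():
        sites_by_contig.setdefault(s["contig"], []).append(
            (int(s["start"]), int(s["end"]))
        )
    bound: set = set()
    with_hits: set = set()
    for h in hits:
        if h.gene is None:
            continue
        with_hits.add(h.gene)
        for s, e in sites_by_contig.get(h.contig, []):
            if h.start < e and s < h.end:
                bound.add(h.gene)
                break
    return bound, with_hits - bound


def filter_expressed(
    levels: pd.Series,
    quantile: float = 0.90,
) -> list[str]:
    """Retain the top ``quantile`` fraction of genes by expression level.

    The cutoff is the (1 - quantile) quantile of the per-gene summary (mean
    over the time course); ties at the cutoff are retained inclusively.
    """
    if not 0 < quantile <= 1:
        raise CycleNucError("quantile must be in (0, 1]")
    cutoff = float(np.quantile(levels.to_numpy(dtype=float), 1.0 - quantile))
    return list(levels.index[levels >= cutoff])
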