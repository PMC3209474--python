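"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; BED/TSV tables via pandas. Coordinates are 0-based
half-open throughout; bedGraph is written 0-based half-open and fixed-step
wiggle is read as 1-based and converted. Expression matrices are TSV with a
header row of minutes and empty cells for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import PairwiseAlignment, read_ortholog_frame
from .errors import CycleNucError, ValidationError
from .motifs import MotifHit
from .track import NucleosomeTrack

BED_READ_COLS = ["contig", "start", "end", "name", "score", "strand"]


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genes_bed(path, genes: pd.DataFrame) -> None:
    """BED6 + thickStart/thickEnd, with thickStart = coding-start base."""
    out = genes.copy()
    out["score"] = out.get("score", 0)
    out["thickStart"] = out["coding_start"]
    out["thickEnd"] = out["coding_start"] + 1
    out[["contig", "start", "end", "name", "score", "strand", "thickStart", "thickEnd"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: gene BED needs at least 6 columns")
    df = df.iloc[:, : min(8, df.shape[1])]
    cols = BED_READ_COLS + ["thickStart", "thickEnd"][: df.shape[1] - 6]
    df.columns = cols
    if "thickStart" in df.columns:
        df["coding_start"] = df["thickStart"].astype(int)
    else:
        df["coding_start"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_reads_bed(path, reads: pd.DataFrame) -> None:
    out = reads.copy()
    if "name" not in out.columns:
        out["name"] = [f"read_{i:07d}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    out[BED_READ_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: read BED needs 6 columns")
    df = df.iloc[:, :6]
    df.columns = BED_READ_COLS
    return df


def write_bedgraph(path, track: NucleosomeTrack, precision: int = 6) -> None:
    """Run-length-encoded bedGraph of a per-base track."""
    with open(path, "w") as fh:
        for contig in sorted(track.data):
            v = np.round(track.data[contig], precision)
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [v.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{v[s]:.{precision}g}\n")


def read_bedgraph(path, contig_lengths: Mapping[str, int] | None = None,
                  normalized: bool = True) -> NucleosomeTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "value"], comment="#")
    lengths: dict[str, int] = dict(contig_lengths or {})
    for contig, grp in df.groupby("contig", sort=False):
        lengths.setdefault(contig, int(grp["end"].max()))
    data = {c: np.zeros(int(n)) for c, n in lengths.items()}
    for contig, grp in df.groupby("contig", sort=False):
        v = data[contig]
        for s, e, val in zip(grp["start"], grp["end"], grp["value"]):
            v[int(s) : int(e)] = val
    return NucleosomeTrack(data=data, normalized=normalized)


def read_wiggle(path, contig_lengths: Mapping[str, int] | None = None,
                normalized: bool = True) -> NucleosomeTrack:
    """Fixed-step wiggle (1-based starts, converted to 0-based)."""
    chunks: dict[str, list[tuple[int, int, list[float]]]] = {}
    contig = None
    start = step = span = None
    values: list[float] = []

    def flush():
        if contig is not None and values:
            chunks.setdefault(contig, []).append((start, step, span, list(values)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                flush()
                values = []
                fields = dict(kv.split("=") for kv in line.split()[1:])
                contig = fields["chrom"]
                start = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
            else:
                values.append(float(line))
    flush()
    lengths: dict[str, int] = dict(contig_lengths or {})
    for c, parts in chunks.items():
        needed = max(s + step * (len(v) - 1) + sp for s, step, sp, v in parts)
        lengths[c] = max(lengths.get(c, 0), needed)
    data = {c: np.zeros(int(n)) for c, n in lengths.items()}
    for c, parts in chunks.items():
        for s, step, sp, vals in parts:
            for i, val in enumerate(vals):
                pos = s + i * step
                data[c][pos : pos + sp] = val
    return NucleosomeTrack(data=data, normalized=normalized)


def write_expression(path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.columns = [f"{float(c):g}" for c in out.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def write_orthologs(path, orthologs: pd.DataFrame) -> None:
    orthologs[["gene_a", "gene_b"]].to_csv(path, sep="\t", header=False, index=False)


def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    return read_ortholog_frame(df)


def write_alignments(path, alignments: Sequence[PairwiseAlignment]) -> None:
    """Aligned-FASTA pairs: records come two at a time (species A then B)."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f">{aln.gene_a}\n{aln.aligned_a}\n")
            fh.write(f">{aln.gene_b}\n{aln.aligned_b}\n")


def read_alignments(path) -> list[PairwiseAlignment]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise CycleNucError(f"{path}: aligned FASTA must contain record pairs")
    out = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        out.append(PairwiseAlignment(a.id, b.id, str(a.seq).upper(), str(b.seq).upper()))
    return out


HIT_COLS = [
    "gene", "contig", "start", "end", "strand", "upstream_strand",
    "offset", "genomic_center", "matched_seq",
]


def write_hits(path, hits: Sequence[MotifHit]) -> None:
    rows = [
        {
            "gene": h.gene, "contig": h.contig, "start": h.start, "end": h.end,
            "strand": h.strand, "upstream_strand": h.upstream_strand,
            "offset": h.offset, "genomic_center": h.genomic_center,
            "matched_seq": h.matched_seq,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLS).to_csv(path, sep="\t", index=False)


def read_hits(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            contig=r["contig"], start=int(r["start"]), end=int(r["end"]),
            strand=r["strand"], matched_seq=r["matched_seq"], gene=r["gene"],
            offset=int(r["offset"]), genomic_center=int(r["genomic_center"]),
            upstream_strand=r["upstream_strand"],
        )
        for _, r in df.iterrows()
    ]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
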