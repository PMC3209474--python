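"""Two-species synthetic benchmark with exact ground-truth labels.

The generator emulates the inputs of a nucleosome/cell-cycle divergence
study at desk scale: two yeast-like species whose genes share a fixed layout
on two contigs, alpha-factor-style expression time courses (cyclic genes are
noisy cosines at the cell-cycle period; a fraction of non-cyclic genes carry
a strong shared slow drift so the global maximum-amplitude frequency is a
non-cell-cycle artifact, as in real synchronization series), mono-nucleosome
read intervals sampled from a base intensity with multiplicative Gaussian
dips over "depleted" motifs and over the promoter NDR ~150 bp upstream of
each ATG, planted bracket-consensus motifs upstream of genes, a one-to-one
ortholog map with controlled motif conservation/loss, and gap-free pairwise
upstream alignments consistent with the planted sequences.

Truth labels are exact by construction: planted motifs are written over
i.i.d. uniform background, species-B upstream windows are scrubbed of chance
consensus matches (so "absent" means absent under every conservation
definition), and all randomness flows from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .conservation import PairwiseAlignment
from .errors import ConfigError
from .motifs import ConsensusMotif, parse_consensus, scan_sequence

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CDS_LEN = 400        # bp of coding sequence per synthetic gene
GENE_PAD = 100       # bp of spacer on each side of a gene slot
EDGE_PAD = 200       # bp of gene-free contig edge
READ_LEN = 36        # single-end read length, Illumina-style
FOOTPRINT = 147      # canonical mono-nucleosome footprint
HALF = (FOOTPRINT - 1) // 2
NDR_DEPTH = 0.6      # fixed promoter NDR dip depth
NDR_SD = 60.0        # bp, promoter NDR dip width
NDR_OFFSET = -150    # NDR center relative to the coding start
HIGH_MISSING_FRAC = 0.6  # missingness planted in "high-missing" genes


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 25 five-minute timepoints over a 60-minute cell cycle (just over
    two periods), cosine amplitude 2 with noise sd 1, 30% cyclic genes, 10%
    missing values, one planted motif per cyclic gene (and 30% of acyclic
    genes), 70% of planted motifs conserved in the second species, and 0.8-deep
    50-bp-sd occupancy dips on depleted motifs at 0.2 reads/bp background.
    """

    seed: int = 0
    n_genes_per_species: int = 150
    upstream_len: int = 600
    n_timepoints: int = 25
    sampling_interval: float = 5.0
    cell_cycle_period: float = 60.0
    expression_amplitude: float = 2.0
    expression_noise_sd: float = 1.0
    frac_cyclic: float = 0.3
    frac_artifact: float = 0.5
    artifact_amplitude: float = 3.0
    frac_acyclic_with_motif: float = 0.3
    frac_motif_conserved: float = 0.7
    substitution_rate: float = 0.1
    missing_rate: float = 0.1
    frac_high_missing: float = 0.05
    dip_depth: float = 0.8
    dip_sd: float = 50.0
    background_read_depth: float = 0.2
    motif_consensus: str = "[AGT][AT]CGCGT[CT][AGT]"

    def motif(self) -> ConsensusMotif:
        return parse_consensus(self.motif_consensus)

    @property
    def planted_frequency_index(self) -> int:
        """Frequency index (cycles per series) nearest the cell-cycle period."""
        return int(
            round(self.n_timepoints * self.sampling_interval / self.cell_cycle_period)
        )

    def validate(self) -> None:
        for name in (
            "frac_cyclic", "frac_artifact", "frac_acyclic_with_motif",
            "frac_motif_conserved", "substitution_rate", "missing_rate",
            "frac_high_missing", "dip_depth",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes_per_species < 0:
            raise ConfigError("n_genes_per_species must be >= 0")
        if self.n_timepoints < 4:
            raise ConfigError("n_timepoints must be >= 4")
        if self.sampling_interval <= 0 or self.cell_cycle_period <= 0:
            raise ConfigError("sampling_interval and cell_cycle_period must be > 0")
        if self.n_timepoints * self.sampling_interval < 2 * self.cell_cycle_period:
            raise ConfigError(
                "n_timepoints x sampling_interval must cover at least two "
                "cell-cycle periods"
            )
        motif = self.motif()
        if self.upstream_len < motif.length:
            raise ConfigError("upstream_len must be >= motif length")
        if self.background_read_depth <= 0:
            raise ConfigError("background_read_depth must be > 0")
        if self.dip_sd <= 0:
            raise ConfigError("dip_sd must be > 0")
        if self.expression_noise_sd < 0:
            raise ConfigError("expression_noise_sd must be >= 0")


@dataclass
class GeneTruth:
    """Ground-truth labels and layout for one synthetic gene."""

    gene: str
    species: str
    contig: str
    strand: str
    start: int
    end: int
    coding_start: int
    is_cyclic: bool
    has_artifact: bool
    phase: float
    artifact_phase: float
    motif_positions: list = field(default_factory=list)          # start offsets
    motif_centers_offset: list = field(default_factory=list)
    motif_centers_genomic: list = field(default_factory=list)
    motif_spans_genomic: list = field(default_factory=list)      # (start, end)
    motif_nucleosome_state: list = field(default_factory=list)   # depleted|occupied
    conservation_state: list = field(default_factory=list)       # conserved|absent
    is_bound: bool = False


@dataclass
class SyntheticTruth:
    """All ground truth for a generated study."""

    genes: dict = field(default_factory=dict)        # name -> GeneTruth
    contig_lengths: dict = field(default_factory=dict)  # species -> {contig: bp}
    cell_cycle_frequency_index: int = 0

    def genes_of(self, species: str) -> list:
        return sorted(
            (g for g in self.genes.values() if g.species == species),
            key=lambda g: g.gene,
        )

    def cyclic_genes(self, species: str) -> list:
        return [g.gene for g in self.genes_of(species) if g.is_cyclic]


@dataclass
class SpeciesBundle:
    """Everything generated for one species."""

    species: str
    genome: dict
    genes: pd.DataFrame
    reads: pd.DataFrame
    expression: pd.DataFrame
    bound_sites: pd.DataFrame
    upstreams: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_fasta(outdir / "genome.fa", self.genome)
        cio.write_genes_bed(outdir / "genes.bed", self.genes)
        cio.write_reads_bed(outdir / "reads.bed", self.reads)
        cio.write_expression(outdir / "expression.tsv", self.expression)
        self.bound_sites.to_csv(outdir / "bound_sites.tsv", sep="\t", index=False)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    truth: SyntheticTruth
    species_a: SpeciesBundle
    species_b: SpeciesBundle
    orthologs: pd.DataFrame
    alignments: list

    def bundles(self) -> tuple:
        return self.species_a, self.species_b

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.species_a.write(outdir / "species_a")
        self.species_b.write(outdir / "species_b")
        cio.write_orthologs(outdir / "orthologs.tsv", self.orthologs)
        cio.write_alignments(outdir / "aligned_upstream.fa", self.alignments)
        truth_obj = {
            "cell_cycle_frequency_index": self.truth.cell_cycle_frequency_index,
            "contig_lengths": self.truth.contig_lengths,
            "genes": {
                name: dataclasses.asdict(g) for name, g in self.truth.genes.items()
            },
        }
        cio.write_json(outdir / "truth.json", truth_obj)


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return np.array([_COMP[b] for b in arr[::-1]], dtype=arr.dtype)


def _rand_bases(rng, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _sample_realization(motif: ConsensusMotif, rng) -> np.ndarray:
    return np.array(
        [sorted(s)[rng.integers(0, len(s))] for s in motif.positions], dtype="<U1"
    )


def _ablate(arr: np.ndarray, span: tuple, motif: ConsensusMotif, rng) -> None:
    """Destroy a planted motif by substituting its two most informative positions
    with bases outside the allowed set."""
    s, e = span
    order = sorted(range(motif.length), key=lambda i: (len(motif.positions[i]), i))
    for i in order[:2]:
        disallowed = sorted(set("ACGT") - motif.positions[i])
        if not disallowed:  # fully degenerate position: nothing can break it
            continue
        arr[s + i] = disallowed[rng.integers(0, len(disallowed))]


def _scrub_chance_hits(
    arr: np.ndarray,
    motif: ConsensusMotif,
    protected_spans: Sequence[tuple],
    rng,
    max_iter: int = 200,
) -> None:
    """Resample bases until the only consensus matches (either strand) are the
    planted, protected spans."""
    protected = set(protected_spans)
    protected_pos = {p for s, e in protected for p in range(s, e)}
    for _ in range(max_iter):
        s = "".join(arr)
        spans = {(h.start, h.end) for h in scan_sequence(s, motif, "both")}
        spurious = sorted(spans - protected)
        if not spurious:
            return
        for hs, he in spurious:
            free = [p for p in range(hs, he) if p not in protected_pos]
            for p in free:
                arr[p] = BASES[rng.integers(0, 4)]
    raise RuntimeError("could not scrub chance motif matches")


def _layout(config: SyntheticConfig) -> list:
    """Deterministic gene layout shared by both species."""
    n = config.n_genes_per_species
    U = config.upstream_len
    slot = GENE_PAD + U + CDS_LEN + GENE_PAD
    n_first = math.ceil(n / 2)
    layout = []
    for i in range(n):
        contig = "contig_1" if i < n_first else "contig_2"
        j = i if i < n_first else i - n_first
        base = EDGE_PAD + j * slot
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            cs = base + GENE_PAD + U
            layout.append((contig, strand, cs, cs, cs + CDS_LEN))
        else:
            lo = base + GENE_PAD
            p = lo + CDS_LEN - 1
            layout.append((contig, strand, p, lo, lo + CDS_LEN))
    return layout


def _contig_lengths(config: SyntheticConfig) -> dict:
    n = config.n_genes_per_species
    slot = GENE_PAD + config.upstream_len + CDS_LEN + GENE_PAD
    n_first = math.ceil(n / 2)
    n_second = n - n_first
    lengths = {"contig_1": 2 * EDGE_PAD + max(n_first, 1) * slot}
    lengths["contig_2"] = 2 * EDGE_PAD + max(n_second, 1) * slot
    return lengths


def simulate_expression(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    species: str = "A",
    rng=None,
) -> pd.DataFrame:
    """Expression time-course matrix (genes x minutes) for one species.

    Cyclic genes follow a*cos(2*pi*t/period + phase) + N(0, noise_sd); genes
    flagged with the synchronization artifact follow a slow cosine spanning
    the whole series; the rest are pure noise. A configurable fraction of
    entries is missing-completely-at-random, plus a fraction of genes with
    >50% of values missing to exercise the preprocessing filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = truth.genes_of(species)
    T = config.n_timepoints
    dt = config.sampling_interval
    t = np.arange(T) * dt
    vals = np.zeros((len(genes), T))
    for i, g in enumerate(genes):
        if g.is_cyclic:
            vals[i] = config.expression_amplitude * np.cos(
                2 * np.pi * t / config.cell_cycle_period + g.phase
            )
        elif g.has_artifact:
            vals[i] = config.artifact_amplitude * np.cos(
                2 * np.pi * t / (T * dt) + g.artifact_phase
            )
    if config.expression_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.expression_noise_sd, vals.shape)
    n_high = round(config.frac_high_missing * len(genes))
    high_idx = (
        rng.choice(len(genes), n_high, replace=False) if n_high else np.array([], int)
    )
    n_miss_high = max(int(T * HIGH_MISSING_FRAC), T // 2 + 1)
    for i in high_idx:
        cols = rng.choice(T, n_miss_high, replace=False)
        vals[i, cols] = np.nan
    if config.missing_rate > 0 and len(genes):
        mcar = rng.random(vals.shape) < config.missing_rate
        mcar[high_idx, :] = False
        vals[mcar] = np.nan
    return pd.DataFrame(vals, index=[g.gene for g in genes], columns=t)


def simulate_nucleosome_reads(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    species: str = "A",
    rng=None,
) -> pd.DataFrame:
    """Single-end 36-bp read intervals (BED-like frame) for one species.

    Nucleosome dyads are sampled per base from a background intensity with
    multiplicative Gaussian dips centered on depleted motifs (depth
    ``dip_depth``, sd ``dip_sd``) and a fixed dip ~150 bp upstream of every
    ATG (the promoter NDR). Each dyad emits one read from a random end of its
    147-bp footprint; strand is Bernoulli(1/2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = truth.contig_lengths.get(species, _contig_lengths(config))
    dips: dict[str, list] = {c: [] for c in lengths}
    for g in truth.genes_of(species):
        sgn = 1 if g.strand == "+" else -1
        dips[g.contig].append(
            (g.coding_start + sgn * NDR_OFFSET, NDR_DEPTH, NDR_SD)
        )
        for center, state in zip(g.motif_centers_genomic, g.motif_nucleosome_state):
            if state == "depleted":
                dips[g.contig].append((center, config.dip_depth, config.dip_sd))
    frames = []
    counter = 0
    for contig in sorted(lengths):
        L = int(lengths[contig])
        lam = np.full(L, config.background_read_depth)
        for center, depth, sd in dips.get(contig, []):
            lo = max(0, int(center - 5 * sd))
            hi = min(L, int(center + 5 * sd) + 1)
            x = np.arange(lo, hi)
            lam[lo:hi] *= 1.0 - depth * np.exp(-0.5 * ((x - center) / sd) ** 2)
        edge = HALF + READ_LEN + 1
        lam[:edge] = 0.0
        lam[-edge:] = 0.0
        counts = rng.poisson(lam)
        dyads = np.repeat(np.arange(L), counts)
        minus = rng.random(dyads.size) < 0.5
        start = np.where(minus, dyads + HALF + 1 - READ_LEN, dyads - HALF)
        end = start + READ_LEN
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": start.astype(int),
                    "end": end.astype(int),
                    "name": [f"read_{counter + i:07d}" for i in range(dyads.size)],
                    "score": 0,
                    "strand": np.where(minus, "-", "+"),
                }
            )
        )
        counter += dyads.size
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end", "name", "score", "strand"])
    return pd.concat(frames, ignore_index=True)


def _pick(rng, n_total: int, n_pick: int) -> set:
    if n_pick <= 0:
        return set()
    return set(rng.choice(n_total, size=min(n_pick, n_total), replace=False).tolist())


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the full two-species benchmark; deterministic given the seed."""
    config.validate()
    motif = config.motif()
    L = motif.length
    U = config.upstream_len
    n = config.n_genes_per_species

    ss = np.random.SeedSequence(config.seed)
    (rng_labels, rng_genome_a, rng_species_b, rng_expr_a,
     rng_expr_b, rng_reads_a, rng_reads_b) = (
        np.random.default_rng(c) for c in ss.spawn(7)
    )

    layout = _layout(config)
    lengths = _contig_lengths(config)

    cyclic = _pick(rng_labels, n, round(config.frac_cyclic * n))
    noncyclic = [i for i in range(n) if i not in cyclic]
    artifact = {
        noncyclic[j]
        for j in _pick(rng_labels, len(noncyclic),
                       round(config.frac_artifact * len(noncyclic)))
    }
    acyclic_with_motif = {
        noncyclic[j]
        for j in _pick(rng_labels, len(noncyclic),
                       round(config.frac_acyclic_with_motif * len(noncyclic)))
    }
    with_motif = sorted(cyclic | acyclic_with_motif)
    motif_offset = {
        i: int(rng_labels.integers(-U, -L + 1)) for i in with_motif
    }
    conserved_idx = {
        with_motif[j]
        for j in _pick(rng_labels, len(with_motif),
                       round(config.frac_motif_conserved * len(with_motif)))
    }
    phases = rng_labels.uniform(0, 2 * np.pi, size=n)
    artifact_phases = rng_labels.uniform(0, 2 * np.pi, size=n)

    # species-A upstream windows (gene oriented), motif planted over background
    ups_a: list[np.ndarray] = []
    for i in range(n):
        up = _rand_bases(rng_genome_a, U)
        if i in motif_offset:
            s = U + motif_offset[i]
            up[s : s + L] = _sample_realization(motif, rng_genome_a)
        ups_a.append(up)

    # species-B upstreams: copy A, substitute outside conserved motifs, ablate
    # absent motifs, then scrub any chance consensus match
    ups_b: list[np.ndarray] = []
    for i in range(n):
        up = ups_a[i].copy()
        protected: list[tuple] = []
        if i in motif_offset and i in conserved_idx:
            s = U + motif_offset[i]
            protected.append((s, s + L))
        protected_pos = {p for s, e in protected for p in range(s, e)}
        sub_mask = rng_species_b.random(U) < config.substitution_rate
        for p in np.flatnonzero(sub_mask):
            if p in protected_pos:
                continue
            others = [b for b in "ACGT" if b != up[p]]
            up[p] = others[rng_species_b.integers(0, 3)]
        if i in motif_offset and i not in conserved_idx:
            s = U + motif_offset[i]
            _ablate(up, (s, s + L), motif, rng_species_b)
        _scrub_chance_hits(up, motif, protected, rng_species_b)
        ups_b.append(up)

    truth = SyntheticTruth(
        contig_lengths={"A": dict(lengths), "B": dict(lengths)},
        cell_cycle_frequency_index=config.planted_frequency_index,
    )

    def build_species(species: str, ups: list, rng_genome) -> SpeciesBundle:
        prefix = "spA" if species == "A" else "spB"
        contigs = {
            c: _rand_bases(rng_genome, int(sz)) for c, sz in sorted(lengths.items())
        }
        gene_rows = []
        upstream_seqs = {}
        bound_rows = []
        for i in range(n):
            contig, strand, coding_start, g_start, g_end = layout[i]
            name = f"{prefix}_g{i:04d}"
            arr = contigs[contig]
            up = ups[i]
            if strand == "+":
                arr[coding_start - U : coding_start] = up
                arr[coding_start : coding_start + 3] = list("ATG")
            else:
                arr[coding_start + 1 : coding_start + 1 + U] = _revcomp_arr(up)
                arr[coding_start - 2 : coding_start + 1] = list("CAT")
            upstream_seqs[name] = "".join(up)
            has_motif = i in motif_offset and (
                species == "A" or i in conserved_idx
            )
            positions, centers_off, centers_gen, spans_gen, states, cons = (
                [], [], [], [], [], []
            )
            if has_motif:
                o = motif_offset[i]
                c_off = o + L // 2
                if strand == "+":
                    c_gen = coding_start + c_off
                    span = (coding_start + o, coding_start + o + L)
                else:
                    c_gen = coding_start - c_off
                    span = (coding_start - o - L + 1, coding_start - o + 1)
                positions.append(o)
                centers_off.append(c_off)
                centers_gen.append(int(c_gen))
                spans_gen.append([int(span[0]), int(span[1])])
                states.append("depleted" if i in cyclic else "occupied")
                cons.append("conserved" if i in conserved_idx else "absent")
            is_bound = bool(has_motif and i in cyclic)
            truth.genes[name] = GeneTruth(
                gene=name, species=species, contig=contig, strand=strand,
                start=g_start, end=g_end, coding_start=coding_start,
                is_cyclic=i in cyclic, has_artifact=i in artifact,
                phase=float(phases[i]), artifact_phase=float(artifact_phases[i]),
                motif_positions=positions, motif_centers_offset=centers_off,
                motif_centers_genomic=centers_gen, motif_spans_genomic=spans_gen,
                motif_nucleosome_state=states, conservation_state=cons,
                is_bound=is_bound,
            )
            gene_rows.append(
                {
                    "contig": contig, "start": g_start, "end": g_end,
                    "name": name, "score": 0, "strand": strand,
                    "coding_start": coding_start,
                }
            )
            if is_bound:
                for s, e in spans_gen:
                    bound_rows.append(
                        {"contig": contig, "start": s, "end": e, "gene": name}
                    )
        genome = {c: "".join(a) for c, a in contigs.items()}
        genes_df = pd.DataFrame(
            gene_rows,
            columns=["contig", "start", "end", "name", "score", "strand", "coding_start"],
        )
        bound_df = pd.DataFrame(
            bound_rows, columns=["contig", "start", "end", "gene"]
        )
        return SpeciesBundle(
            species=species, genome=genome, genes=genes_df,
            reads=pd.DataFrame(), expression=pd.DataFrame(),
            bound_sites=bound_df, upstreams=upstream_seqs,
        )

    bundle_a = build_species("A", ups_a, rng_genome_a)
    bundle_b = build_species("B", ups_b, rng_species_b)
    bundle_a.expression = simulate_expression(truth, config, "A", rng_expr_a)
    bundle_b.expression = simulate_expression(truth, config, "B", rng_expr_b)
    bundle_a.reads = simulate_nucleosome_reads(truth, config, "A", rng_reads_a)
    bundle_b.reads = simulate_nucleosome_reads(truth, config, "B", rng_reads_b)

    orthologs = pd.DataFrame(
        {
            "gene_a": [f"spA_g{i:04d}" for i in range(n)],
            "gene_b": [f"spB_g{i:04d}" for i in range(n)],
        }
    )
    alignments = [
        PairwiseAlignment(
            f"spA_g{i:04d}", f"spB_g{i:04d}",
            bundle_a.upstreams[f"spA_g{i:04d}"], bundle_b.upstreams[f"spB_g{i:04d}"],
        )
        for i in range(n)
    ]
    return SyntheticStudy(
        config=config, truth=truth, species_a=bundle_a, species_b=bundle_b,
        orthologs=orthologs, alignments=alignments,
    )
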