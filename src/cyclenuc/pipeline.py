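"""End-to-end orchestration: run every stage on a synthetic study and
summarize the statistics together with truth-recovery metrics.

This is the library behind ``cyclenuc demo`` and the acceptance script: it
generates a two-species benchmark, builds and normalizes the nucleosome
track, scores expression periodicity, scans upstream motifs, computes the
motif/periodicity mutual information, the occupancy-periodicity association,
the bound-vs-unbound Welch comparison at the pooled trough, and the three
cross-species conservation classifications, and compares everything against
the planted truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as cio
from .conservation import ConservationCall, classify_hits, partition_by_binding
from .errors import ValidationError
from .motifs import find_upstream_hits, mi_enrichment
from .periodicity import (
    PeriodicityResult,
    detect_cell_cycle_frequency,
    preprocess,
    score_and_classify,
)
from .profiles import (
    ProfileMatrix,
    average_profile,
    build_profile_matrix,
    find_trough,
    periodicity_association_test,
    trough_welch_test,
)
from .synthetic import SyntheticConfig, SyntheticStudy, generate_study
from .track import contig_coverage_filter, normalize_track, pileup_reads

DEFAULTS = {
    "upstream_len": 600,
    "flank": 300,
    "positional_window": 200,
    "coverage_threshold": 0.20,
    "exclusion_factor": 100.0,
    "knn_k": 10,
    "mi_bins": 10,
    "n_perm": 1000,
    "extension": 147,
    "pseudocount": 1.0,
}


@dataclass
class AnalysisResult:
    """Everything computed by :func:`analyze_study` on species A (plus the
    cross-species comparison toward species B)."""

    periodicity: PeriodicityResult
    profile: ProfileMatrix
    metrics: dict = field(default_factory=dict)
    conservation: list = field(default_factory=list)
    hits_a: list = field(default_factory=list)
    hits_b: list = field(default_factory=list)


def classification_metrics(
    periodicity: PeriodicityResult, truth, species: str = "A"
) -> tuple[float, float, int]:
    """Sensitivity and specificity of the cyclic call vs planted labels,
    over the genes retained after preprocessing."""
    tab = periodicity.table
    tp = fp = tn = fn = 0
    for g in truth.genes_of(species):
        if g.gene not in tab.index:
            continue
        called = bool(tab.loc[g.gene, "is_cyclic"])
        if g.is_cyclic and called:
            tp += 1
        elif g.is_cyclic:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec, tp + fp + tn + fn


def conservation_recovery(
    calls: list, truth, species: str = "A"
) -> tuple[float, float, int]:
    """Agreement of presence and aligned calls with planted conservation
    labels, over planted species-A motifs (matched by center offset)."""
    expected: dict[tuple, str] = {}
    for g in truth.genes_of(species):
        for off, state in zip(g.motif_centers_offset, g.conservation_state):
            expected[(g.gene, off)] = state
    n = ok_presence = ok_aligned = 0
    for c in calls:
        state = expected.get((c.gene_a, c.offset_a))
        if state is None:
            continue
        n += 1
        want_presence = "conserved" if state == "conserved" else "absent"
        want_aligned = "conserved" if state == "conserved" else "lost"
        ok_presence += c.status_presence == want_presence
        ok_aligned += c.status_aligned == want_aligned
    if n == 0:
        return float("nan"), float("nan"), 0
    return ok_presence / n, ok_aligned / n, n


def analyze_study(study: SyntheticStudy, params: Mapping | None = None,
                  mi_seed: int = 0) -> AnalysisResult:
    """Run the full analysis chain on a generated study."""
    p = dict(DEFAULTS)
    if params:
        p.update(params)
    cfg = study.config
    a, b = study.species_a, study.species_b
    motif = cfg.motif()

    lengths = {c: len(s) for c, s in a.genome.items()}
    raw = pileup_reads(a.reads, lengths, extension=p["extension"])
    track = normalize_track(raw, pseudocount=p["pseudocount"])
    coverage = contig_coverage_filter(track=track, threshold=p["coverage_threshold"])
    expr = preprocess(a.expression, k=p["knn_k"])
    f_cc = detect_cell_cycle_frequency(expr, mode="secondary_max")
    periodicity = score_and_classify(expr, f_cc)

    hits_a, _ = find_upstream_hits(a.genes, a.genome, motif, p["upstream_len"])
    hits_b, _ = find_upstream_hits(b.genes, b.genome, motif, p["upstream_len"])

    genes_with_hits = {h.gene for h in hits_a}
    tab = periodicity.table
    presence = tab.index.to_series().isin(genes_with_hits).to_numpy()
    mi = mi_enrichment(
        presence, tab["rank"].to_numpy(), n_bins=min(p["mi_bins"], len(tab)),
        n_perm=p["n_perm"], seed=mi_seed,
    )

    profile = build_profile_matrix(track, hits_a, periodicity, flank=p["flank"])
    association = periodicity_association_test(profile)
    bound, unbound = partition_by_binding(hits_a, a.bound_sites)
    bound_mask = profile.meta["gene"].isin(bound).to_numpy()
    unbound_mask = profile.meta["gene"].isin(unbound).to_numpy()
    welch = trough_welch_test(profile.subset(bound_mask), profile.subset(unbound_mask))
    avg_bound, _ = average_profile(profile, np.flatnonzero(bound_mask))
    trough_bound = find_trough(avg_bound, profile.offsets)

    alignments = {al.gene_a: al for al in study.alignments}
    calls = classify_hits(
        hits_a, hits_b, study.orthologs, motif=motif, alignments=alignments,
        window=p["positional_window"],
    )
    wide_calls = classify_hits(
        hits_a, hits_b, study.orthologs, motif=motif, alignments=alignments,
        window=cfg.upstream_len,
    )
    comparable = [
        (c, w) for c, w in zip(calls, wide_calls)
        if c.status_presence != "not_applicable"
    ]
    positional_eq = (
        float(np.mean([w.status_positional == c.status_presence
                       for c, w in comparable]))
        if comparable else float("nan")
    )
    presence_rec, aligned_rec, n_planted = conservation_recovery(calls, study.truth)
    sens, spec, n_classified = classification_metrics(periodicity, study.truth)

    metrics = {
        "n_genes": int(cfg.n_genes_per_species),
        "n_reads": int(len(a.reads)),
        "track_median_normalized": float(np.median(track.concatenated())),
        "contigs_passing_coverage": int(sum(c.passes for c in coverage)),
        "f_cc": int(f_cc),
        "f_cc_truth": int(study.truth.cell_cycle_frequency_index),
        "d_inflection": float(periodicity.d_inflection),
        "periodicity_sensitivity": float(sens),
        "periodicity_specificity": float(spec),
        "n_genes_classified": int(n_classified),
        "n_hits_a": len(hits_a),
        "n_hits_b": len(hits_b),
        "mi_bits": float(mi.mi_bits),
        "mi_p": float(mi.p_value),
        "association_p": float(association.p_value),
        "association_U": float(association.statistic),
        "association_trough_offset": int(association.trough_offset),
        "n_bound_genes": len(bound),
        "n_unbound_genes": len(unbound),
        "welch_bound_vs_unbound_t": float(welch.statistic),
        "welch_bound_vs_unbound_p": float(welch.p_value),
        "trough_offset_bound": int(trough_bound),
        "presence_conservation_recovery": float(presence_rec),
        "aligned_conservation_recovery": float(aligned_rec),
        "n_planted_motifs_compared": int(n_planted),
        "positional_eq_presence_at_full_window": float(positional_eq),
    }
    return AnalysisResult(
        periodicity=periodicity, profile=profile, metrics=metrics,
        conservation=calls, hits_a=hits_a, hits_b=hits_b,
    )


@dataclass
class DemoReport:
    metrics: dict
    checks: list
    passed: bool
    report_path: Path | None = None


def _demo_checks(m: dict) -> list:
    return [
        ("normalized track median = 1", abs(m["track_median_normalized"] - 1) < 1e-9),
        ("cell-cycle frequency recovered", m["f_cc"] == m["f_cc_truth"]),
        ("periodicity sensitivity >= 0.90", m["periodicity_sensitivity"] >= 0.90),
        ("periodicity specificity >= 0.90", m["periodicity_specificity"] >= 0.90),
        ("occupancy-periodicity association p < 1e-3", m["association_p"] < 1e-3),
        ("motif MI enrichment p <= 0.01", m["mi_p"] <= 0.01),
        ("presence conservation fully recovered",
         m["presence_conservation_recovery"] == 1.0),
        ("aligned conservation fully recovered",
         m["aligned_conservation_recovery"] == 1.0),
        ("bound-group trough within 10 bp of motif center",
         abs(m["trough_offset_bound"]) <= 10),
    ]


def run_demo(seed: int, out_dir, config: SyntheticConfig | None = None,
             params: Mapping | None = None) -> DemoReport:
    """One-command end-to-end run on synthetic data, with a markdown report.

    ``passed`` is False if any truth-recovery property fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SyntheticConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    study = generate_study(config)
    study.write(out_dir / "study")
    result = analyze_study(study, params, mi_seed=seed)
    m = result.metrics
    checks = _demo_checks(m)

    result.periodicity.table.to_csv(out_dir / "periodicity.tsv", sep="\t")
    cio.write_hits(out_dir / "hits_a.tsv", result.hits_a)
    pd.DataFrame([dataclasses.asdict(c) for c in result.conservation]).to_csv(
        out_dir / "conservation.tsv", sep="\t", index=False
    )
    avg_all, n_all = average_profile(result.profile)
    pd.DataFrame(
        {"offset": result.profile.offsets, "mean": avg_all, "n": n_all}
    ).to_csv(out_dir / "averages.tsv", sep="\t", index=False)

    lines = ["# cyclenuc demo report", "", f"- seed: {seed}", "", "## Metrics", ""]
    for key in sorted(m):
        lines.append(f"- {key}: {m[key]:.6g}" if isinstance(m[key], float)
                     else f"- {key}: {m[key]}")
    lines += ["", "## Checks", ""]
    for name, ok in checks:
        lines.append(f"- [{'x' if ok else ' '}] {name}")
    passed = all(ok for _, ok in checks)
    lines += ["", f"Overall: {'PASS' if passed else 'FAIL'}", ""]
    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines))
    cio.write_json(out_dir / "metrics.json", m)
    return DemoReport(metrics=m, checks=checks, passed=passed,
                      report_path=report_path)


@dataclass
class Diagnostic:
    severity: str  # "warning" | "fatal"
    file: str
    message: str


def validate_inputs(
    genome: Mapping[str, str] | None = None,
    genes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    reads: pd.DataFrame | None = None,
    genome_file: str = "genome.fa",
    genes_file: str = "genes.bed",
    expression_file: str = "expression.tsv",
    reads_file: str = "reads.bed",
) -> list[Diagnostic]:
    """Cross-check pipeline inputs; returns structured diagnostics.

    Fatal diagnostics mean the pipeline cannot run (out-of-bounds
    annotations, non-uniform timepoints); warnings flag recoverable issues
    (ids missing from one table).
    """
    diags: list[Diagnostic] = []
    if genome is not None and genes is not None:
        for _, g in genes.iterrows():
            if g["contig"] not in genome:
                diags.append(Diagnostic(
                    "fatal", genes_file,
                    f"gene {g['name']} on unknown contig {g['contig']}"))
            elif not (0 <= int(g["start"]) < int(g["end"]) <= len(genome[g["contig"]])):
                diags.append(Diagnostic(
                    "fatal", genes_file,
                    f"gene {g['name']} coordinates outside contig bounds"))
    if expression is not None:
        t = [float(c) for c in expression.columns]
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0]):
            diags.append(Diagnostic(
                "fatal", expression_file, "non-uniform timepoint spacing"))
        if genes is not None:
            known = set(genes["name"])
            missing = [g for g in expression.index if g not in known]
            if missing:
                diags.append(Diagnostic(
                    "warning", expression_file,
                    f"{len(missing)} gene id(s) absent from {genes_file} "
                    f"(e.g. {missing[0]})"))
    if reads is not None and genome is not None:
        bad = 0
        for _, r in reads.iterrows():
            if r["contig"] not in genome or not (
                0 <= int(r["start"]) < int(r["end"]) <= len(genome[r["contig"]])
            ):
                bad += 1
        if bad:
            diags.append(Diagnostic(
                "warning", reads_file, f"{bad} read(s) out of bounds"))
    return diags
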