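# cyclenuc

Nucleosome occupancy at cell-cycle transcription-factor motifs, and what it
predicts about periodic gene expression and its divergence between yeast
species.

In budding yeasts, the G1/S transcription-factor complexes SBF (Swi4p–Swi6p)
and MBF (Mbp1p–Swi6p) bind degenerate consensus sites such as
`[AGT][AT]CGCGT[CT][AGT]` (MBP1) in promoters. Whether such a site actually
drives periodic, cell-cycle-coupled expression of its downstream gene
correlates with whether the site is nucleosome-depleted or
nucleosome-shielded — and across species, loss of periodic expression can
track a gain of nucleosome occupancy on a conserved motif rather than loss
of the motif itself. `cyclenuc` implements that analysis chain as a tested,
reusable library for researchers in regulatory genomics and chromatin
biology, together with a fully labeled two-species synthetic benchmark so
every stage can be exercised and validated at desk scale.

## What it computes

* **Nucleosome tracks** (`cyclenuc.track`) — per-base occupancy from mapped
  read intervals: each read is extended from its 5′ end to the 147-bp
  mono-nucleosome footprint and piled up; the raw track is normalized as

  $$\mathrm{occ}(b) = \frac{\log\!\big(\mathrm{raw}(b) + c\big)}{\log\!\big(\mathrm{median}(\mathrm{raw} + c)\big)}$$

  so the genome median equals 1. Contigs with ≤ 20% nucleosome coverage and
  genes with mean raw signal > 100× the genome average are flagged out.
* **Periodicity scores** (`cyclenuc.periodicity`) — expression time courses
  are filtered (> 50% missing dropped), duplicate rows averaged, KNN-imputed
  (K = 10, Euclidean distance), and centered; each gene's one-sided DFT
  amplitude spectrum is computed, the cell-cycle frequency index
  $f_{cc}$ is identified (secondary maximum of the mean spectrum, or primary
  maximum over a reference gene set), and each gene gets
  $d_g = |\arg\max_k A_g(k) - f_{cc}|$. Genes with $d_g$ below the knee of
  the sorted-$d_g$ curve ($d_\mathrm{inflection}$) are called cell-cycle
  regulated.
* **Motif scanning** (`cyclenuc.motifs`) — bracket-consensus matching on
  both strands of the 600-bp upstream windows (offsets −600..0 relative to
  the coding start), plus a FIRE-style mutual-information statistic between
  motif presence and periodicity-rank bins with a permutation p-value.
* **Cross-species conservation** (`cyclenuc.conservation`) — three
  definitions per motif: *presence* (≥ 1 consensus match anywhere in the
  ortholog's 600-bp window), *positional* (a match within ±200 bp of the
  same ATG-relative position), and *aligned* (the motif columns of a
  pairwise upstream alignment are gap-free and still realize the consensus);
  plus the TF-bound/unbound gene partition and the top-90%-expressed filter.
* **Profiles and statistics** (`cyclenuc.profiles`) — motif-centered ±300-bp
  occupancy matrices ranked by $d_g$, group averages, the trough (minimum)
  of the average profile, Welch's unequal-variance *t* test on per-row
  values at the pooled trough, and the Mann-Whitney *U* test (exact by
  enumeration for combined *n* ≤ 20, tie-corrected normal approximation
  otherwise) for the occupancy–periodicity association.
* **Synthetic benchmark** (`cyclenuc.synthetic`) — a two-species study with
  exact ground truth: cosine-plus-noise cyclic genes, a slow
  synchronization-artifact component in part of the acyclic genes (so the
  global maximum-amplitude frequency is a noise signal, as in real
  alpha-factor series), 36-bp reads sampled with Gaussian occupancy dips on
  depleted motifs and on the promoter NDR ~150 bp upstream of each ATG,
  planted motifs with controlled cross-species conservation, and gap-free
  upstream alignments.

## Worked example

One command generates a synthetic study, runs every stage, and checks the
results against the planted truth:

```sh
cyclenuc demo --seed 1 --out-dir demo_out
```

which prints (elided):

```
PASS  normalized track median = 1
PASS  cell-cycle frequency recovered
PASS  periodicity sensitivity >= 0.90
PASS  periodicity specificity >= 0.90
PASS  occupancy-periodicity association p < 1e-3
PASS  motif MI enrichment p <= 0.01
PASS  presence conservation fully recovered
PASS  aligned conservation fully recovered
PASS  bound-group trough within 10 bp of motif center
```

and writes `demo_out/report.md` with the underlying numbers, e.g. at seed 1:
`f_cc = 2` (the planted cell-cycle frequency index), periodicity sensitivity
1.00 and specificity 0.94 over 142 classified genes, motif–periodicity
mutual information 0.179 bits (permutation p = 0.000999), occupancy–
periodicity Mann-Whitney p = 4.6e-14 over 124 motif profiles with the
pooled-average trough at offset −4 bp from the motif center, Welch
bound-vs-unbound p = 1.9e-20, and 77/77 planted motifs classified correctly
under both the presence and the aligned conservation rules. The same
quantities are reachable through the library (`cyclenuc.run_demo`,
`cyclenuc.analyze_study`) and as individual subcommands (`simulate`,
`track`, `periodicity`, `scan`, `conserve`, `profile`, `validate`).

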