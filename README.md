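# coldclock

Separating genuinely cold-responsive genes from diurnal-oscillation
artifacts in chilling-stress transcriptomes.

## The problem

When a plant is chilled, hundreds of genes appear differentially
expressed between the cold (4°C) and ambient (24°C) transcriptome — but
chilling also freezes the diurnal oscillation of a large set of
clock-controlled genes. A gene whose mRNA keeps cycling at 24°C while
staying flat at 4°C looks "differentially expressed" without ever being
driven by cold signalling. The fix is a **dual-control design**: sample a
pre-treatment baseline (T0) *and* a concurrent ambient control, and
classify every DEG by two fold-changes,

- FC(4vsT0) — expression at the cold timepoint over T0,
- FC(24vsT0) — expression at the matched ambient timepoint over T0.

A DEG is **cold-induced** if FC(4vsT0) ≥ 1.5 at 30 min (≥ 2 at 3 h),
**cold-repressed** if FC(4vsT0) ≤ 2/3 at 30 min (≤ 1/2 at 3 h),
**cold-static** if the cold fold fails both cutoffs but the ambient fold
passes one (the signature of a frozen oscillation), and
**indeterminate** otherwise. Static genes split into `static_induced`
(ambient fell, cold flat — gene appears up vs 24°C) and
`static_repressed` (ambient rose).

`coldclock` implements this analysis end to end, plus a synthetic
diurnal/cold transcriptome generator with full ground truth so that every
stage is testable without sequencing data:

- **profiles / simulate** — expression model
  μ(t) = b·exp(a·cos(2π(t−φ)/P)) with cold responses (static with
  dampening d; monotone induction/repression with fold F and rate k;
  phase-reset resumption after release), NB counts (Var = μ + αμ²) with
  TMM-style library structure, and a multinomial amplicon-assay
  simulator (11,000–37,000 reads/sample).
- **normalize / de** — trimmed-mean-of-M-values normalization (30% M /
  5% A trim, precision weights) and per-gene NB GLM testing with a
  quasi-likelihood F-test (Rao score numerator, empirical-Bayes-moderated
  quasi-dispersion, trended dispersion via binned Pearson
  pseudo-likelihood), BH FDR control.
- **classify** — the dual-control classifier above, with per-contrast
  summaries and cross-timepoint/organ overlap tables.
- **enrichment** — ortholog-map translation, rhythmic-set extraction
  ("n.r" flag convention), upper-tail hypergeometric overlap, and
  GMT-based over-representation.
- **trajectory** — reference-gene-relative amplicon series, cubic-spline
  trajectory fits (df=4 on log1p ratios), moderated-F ambient-vs-cold
  comparison, peak finding and clock-resumption timing.
- **pipeline / cli** — a configuration-driven driver
  (`coldclock all --seed ... --outdir ...`) tying every stage together
  deterministically.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (about two minutes in total):

```sh
python analysis/01_simulate_dataset.py
python analysis/02_differential_expression.py
python analysis/03_classify_dual_control.py
python analysis/04_diurnal_overlap.py
python analysis/05_clock_trajectories.py
```

With the default 2000-gene panel (10% induced, 10% repressed, 25%
diurnal-static, 55% unaffected; n = 3 replicates, NB dispersion 0.05)
the run prints, among other things:

```
shoot T0.5: 231 DEGs at FDR < 0.01 (of 2000 genes tested)
shoot T3: 902 DEGs at FDR < 0.01 (of 2000 genes tested)
  shoot:T3: {'static': 499, 'induced': 200, 'repressed': 198, 'indeterminate': 5, ...}
truth recovery ... shoot:T3: induced=1.00, repressed=0.99, static=1.00
shoot T3: 499/499 static genes rhythmic (reference 500/2000), hypergeometric p = 0.000e+00
  CCA1: F = 160.6, p = 1.64e-13 (dampened)
noise-free ambient peak times (ZT h): {'CCA1': 2.5, ..., 'PRR7': 14.5, 'ELF3': 18.5}
hours from cold release to first CCA1 peak: {'3.0': 3.0, '6.0': 3.0, '9.0': 3.0}
```

Reading: at 3 h the static class dominates the DEG list exactly as the
ground truth dictates, and the classifier recovers the truth almost
perfectly; the static set coincides with the rhythmic genes
(hypergeometric overlap); every clock gene's cold trajectory is
significantly flattened relative to ambient; and CCA1 peaks 3 h after
the end of cold treatment regardless of treatment length. The 30-minute
timepoint shows far fewer DEGs — monotone responders have not yet
cleared the cutoffs and the ambient controls have barely moved, mirroring
the early-response behaviour the dual-control design is built to expose.

The same stages are available as subcommands on files
(`coldclock simulate|de|classify|enrich|trajectory|all`).

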