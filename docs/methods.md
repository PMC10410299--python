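# Methods

## Expression model

Every simulated gene follows a log-scale cosine oscillation under
ambient conditions:

    mu(t) = b * exp(a * cos(2*pi*(t - phi)/P)),

with baseline `b` (arbitrary mean-count units), amplitude `a`
(dimensionless), peak phase `phi` (ZT hours) and period `P = 24` h.
Putting the oscillation on the log scale makes peak-to-trough ratios
fold-changes independent of `b`, which matches how clock-gene changes
are reported (always as folds). The chilling treatment starts at
`t_treat = 2.5` ZT h (morning) and modifies the trajectory by category:

- **static** — the oscillation freezes at its pre-treatment level with a
  residual fraction `d` of amplitude:
  `mu_c(t) = mu(t_treat) + d*(mu(t) - mu(t_treat))`. `d = 0` is a fully
  flat trajectory, `d = 1` recovers ambient behaviour exactly.
- **induced / repressed** — monotone first-order approach to `F`-fold
  above (below) the pre-treatment level:
  `mu_c(t) = mu(t_treat) * (1 + (F - 1)(1 - e^{-k(t - t_treat)}))`
  (with `1/F` for repression). `k` is per hour; the trajectory is
  monotone and saturates at the declared fold.
- **none** — cold trajectory identical to ambient.

After return to ambient temperature at `t_release`, oscillating genes
resume with their phase reset so the next peak falls
`resume_peak_delay` hours after release (default 3 h). This is a
deliberate modelling commitment: the observed resumption is anchored to
the release time, not the time of day, and is independent of cold
duration. The model therefore allows a discontinuity at the release
instant (the post-release cosine does not in general pass through the
frozen cold level); only peak timing downstream depends on this segment.
Monotone responders instead relax exponentially back to the ambient
curve at rate `k`.

`calibrate_amplitude` inverts the cosine model so a declared fold
between two ZT hours is honoured exactly:
`a = ln(F) / (cos(2*pi*(t0-phi)/P) - cos(2*pi*(t1-phi)/P))`; it raises
when the two cosines coincide (amplitude unidentifiable).
`calibrate_dampening` converts an ambient fold and a cold fold into `d`.

### Default clock panel

The packaged shoot panel encodes the reported ambient T0→T3 (ZT2.5→5.5)
folds — CCA1 0.1×, RVE6 0.5×, RVE8 0.2×, PRR7 2×, GI 8×, ELF3 2.5× —
with phases CCA1/RVE6/RVE8 at ZT2.5, PRR7 at ZT14.5, ELF3 at ZT18.5 and
GI at ZT12 (a canonical evening phase; no printed value). CCA1's cold
dampening is calibrated so its cold T0→T3 decrease is 30%
(`d = (0.7-1)/(0.1-1) = 1/3`); other static genes default to `d = 0`.
PRR9 is aberrantly cold-induced (2.5×) and CBF3 strongly cold-induced
(F = 400 shoot / 155 root, `k = 2`/h so the fold saturates within 3 h).
EF1a is the constant amplicon reference. One caveat: ELF3's printed
evening phase and printed morning *induction* cannot both hold under a
single cosine (ZT2.5→5.5 moves toward its trough); the panel keeps the
phase and the amplitude magnitude, so ELF3's realized T0→T3 fold is the
reciprocal of the printed one. No downstream check depends on ELF3's
fold direction.

## Count simulation

Counts are negative-binomial with `Var = mu + alpha*mu^2`
(`alpha = 0.05` by default, Poisson at `alpha = 0`), n = 3 replicates
per condition/timepoint, and lognormal library sizes (mean 1e6, CV 0.2);
expected per-sample totals equal the library size. The amplicon
simulator draws each run's depth uniformly from 11,000–37,000 reads and
distributes reads multinomially across the panel in proportion to
expected expression, so ratios to the reference gene are
depth-invariant by construction. The benchmarking panel
(`random_panel`) is 10% induced / 10% repressed / 25% static / 55%
unaffected by default; monotone effect sizes are log-uniform on [3, 10]
and static genes' amplitudes are solved so their ambient ZT2.5→5.5 fold
clears the 3-hour classifier cutoff (amplitude capped at 6 to exclude
near-degenerate phase solutions). Unaffected genes carry a small
amplitude (≤ 0.2) that continues identically under cold.

What the generator does *not* emulate: batch effects, gene–gene
correlation, organ-specific gene panels, transcript-length bias, or
composition shifts large enough to stress TMM. Passing tests therefore
demonstrate correctness of the machinery under the stated noise model,
not robustness to every artifact of real sequencing data.

## Normalization and differential expression

TMM factors follow the canonical recipe: reference column = the sample
whose upper-quartile expression is closest to the mean upper quartile;
per-gene log2 ratios (M) and average log intensities (A) computed
against the reference on library-size-scaled counts; genes with a zero
in either member of the pair excluded; double trim (30% of M, 5% of A,
rank-based); inverse-variance weighted mean of the surviving M-values
with delta-method count-level weights; factors rescaled to geometric
mean 1. CPM = counts / (library size × factor) × 1e6.

Testing is per-gene NB GLM (log link, effective-library-size offset,
two-group design) with a quasi-likelihood F-test:

1. **Dispersion trend.** Genes are binned (deciles of log mean) and a
   common dispersion per bin is solved from the within-group Pearson
   statistic (sum of (y-m)²/(m+αm²) equated to its residual df). This
   moment estimator is nearly unbiased at n = 3, where per-gene
   method-of-moments values are strongly skewed. GLM fits use the
   trend; gene-wise variability enters through the quasi-dispersion
   (the QL convention). A per-gene estimator (signed MoM shrunk toward
   the trend with prior df 10, clamped at 0) is exposed separately for
   inspection.
2. **Score numerator.** The test statistic is the Rao score statistic of
   the group effect evaluated at the null fit. On 20,000-gene null
   simulations (n = 3 vs 3, dispersion 0.05) the score statistic is
   calibrated into the deep tail (fraction p < 0.001 ≈ 0.0010) whereas
   the deviance-difference statistic runs heavy (≈ 0.00125); this
   choice is what keeps the empirical FDR of called DEG sets at its
   nominal level.
3. **Moderation.** The per-gene quasi-dispersion s² = residual
   deviance / df is shrunk across genes by fitting a scaled
   inverse-chi-square prior to the log-variances (moment matching with a
   trigamma inversion, prior df `d0` possibly infinite); the moderated
   F = score / s²_post is referred to F(1, df + d0).

Zeros: all-zero genes get p = 1, logFC = 0 and a flag; logFC is the GLM
coefficient, falling back to a 0.5-pseudocount CPM ratio when the
coefficient is degenerate. BH adjustment is the standard step-up
procedure; DEGs are FDR < 0.01 per contrast (cold vs ambient at the
matched timepoint, per organ).

## Dual-control classification

Cutoffs are inclusive: induced ≥ 1.5 (30 min) / ≥ 2 (3 h); repressed
≤ 2/3 / ≤ 1/2. The cold fold is evaluated first; only genes failing
both cold cutoffs are tested on the ambient fold (a gene passing both a
cold and an ambient cutoff is induced/repressed, not static — such genes
rarely survive the 4°C-vs-24°C DE gate in the first place). Folds are
means of TMM-CPM over replicates with a 0.5 pseudocount on both sides.
Numeric timepoints ≥ 1 h use the 3-hour cutoffs. Static subtypes come
from the ambient fold's direction. The classifier is total and
deterministic; raising FC(4vsT0) with FC(24vsT0) fixed can only move a
gene repressed → static/indeterminate → induced.

## Set overlap and enrichment

Rhythmic sets are "every gene not flagged `n.r`", case-insensitive by
default. Overlap significance is the exact upper tail P[X ≥ k] of the
hypergeometric distribution; the universe is the gene set shared by the
expression space and the ortholog map's target space (identity map when
none is supplied). One-to-many ortholog policies: `all` (default),
`first`, `drop_ambiguous`. GMT collections are tested flat — no
ontology-graph propagation — with BH across the collection and a 0.05
FDR default.

## Trajectory analysis

Relative expression is gene reads / reference-gene reads per sample.
Fits are least squares of log1p(ratio) on a degree-3 B-spline basis with
df = 4 (knots at quantiles of observed times). The B-spline basis is
used because together with the intercept it spans all cubic polynomials
on the observed range; a natural-spline basis (`cr`) is available but
constrains curvature at the boundaries. log1p is chosen over log because
ratios can be exactly zero at sequencing depth. The ambient-vs-cold test
regresses both conditions jointly and F-tests the full condition block
(offset + condition×basis, 5 numerator df), so level shifts and shape
changes both count; residual variances are moderated across genes with
the same scaled-inv-chi-square machinery as the DE module when ≥ 5
genes are available, otherwise the ordinary F-test is used (the amplicon
panel has 8 clock genes, but single-gene analyses are common). Peaks are
grid argmaxes (0.1 h default, ties to the earliest time) with a
flat-trajectory guard (relative range < 1e-6 → "no peak"). Resumption
timing simulates the noise-free trajectory through cold and release and
reports the first post-release peak relative to the release time.

On the default 13-point amplicon grid the df = 4 spline tracks every
panel trajectory with r > 0.985 on the fitting scale; the hardest case
is CCA1, whose 10-fold-in-3-hours decay implies a peak:trough ratio of
about 7×10⁶ and caps the fit at r ≈ 0.99.

## Pipeline

`run_pipeline` chains simulation (or file input) → validation → TMM/DE →
classification → enrichment → trajectories, writes TSV tables plus a
`summary.json` containing stage counts, the seed and a config hash
(outdir excluded), and is byte-deterministic given config + seed. All
randomness flows from one integer seed through a single
`numpy.random.Generator` stream. Exit codes: 0 success, 2 validation
failure, 1 internal error.

## Problem sizes used in the test-suite simulations

Monte-Carlo checks use 2,000–5,000 genes for calibration suites,
1,000-gene panels for classifier-recovery runs, 50-seed medians for
fold-change recovery, and 100-run power estimates for the trajectory
comparison — sizes at which the binomial error of each estimated rate is
small relative to the asserted tolerance while the whole suite stays
fast on a single CPU.

## Known limitations

- The resumption model is phenomenological (phase reset + fixed delay),
  not a dynamical clock model; it encodes the observed behaviour rather
  than explaining it.
- The QL score-F test covers two-group contrasts only; no multi-factor
  designs or batch terms.
- The dispersion trend assumes exchangeability within expression bins;
  strongly bimodal mean-dispersion relationships would need a finer
  binning.
- GO-style enrichment ignores term-term structure (flat sets).
- The classifier operates on replicate means; it does not propagate
  replicate variance into the fold-change cutoffs.
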