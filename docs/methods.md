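# Methods

## The analysis model

The pipeline treats the microbiota's effect on the host as whatever
differs between germ-free (GF) and fecal-microbiota-transplant (FMT)
mice, and the diet panel as the axis along which that effect varies.
Three quantities are computed per diet d:

- ΔBW(g)(d): mean over FMT mice of (week-8 BW − week-0 BW) minus the
  same mean over GF mice, in grams. Week 8 is fixed as the endpoint
  even when feeding continues longer.
- ΔBW(s)(d): pooled OLS slope of BW on week over all FMT mice's raw
  (week, BW) points, minus the GF pooled slope, in g/week. Pooling raw
  points (rather than averaging per-mouse slopes) matches fitting one
  regression line per group; with a complete common week grid the two
  coincide exactly, because the per-mouse intercepts are orthogonal to
  the within-mouse time contrast.
- ΔGEL(g, d): mean expression of gene g over FMT samples minus the GF
  mean, per tissue, on the input (FPKM-like) scale. Means are taken on
  the raw scale, not log, because the downstream correlation is meant
  to weight diets by the magnitude of the expression shift.

The gene–weight screen computes Pearson r between the gene's ΔGEL
vector and each ΔBW vector over the diets (n = 6 by default) and the
exact two-sided p via t = r√(n−2)/√(1−r²); at df = 4 this reduces to
the closed form p = 1 − (3/2)|r| + (1/2)|r|³. Selection is
max(|r_abs|, |r_slope|) ≥ 0.70 **inclusive at two-decimal precision**
(a value printing as 0.70 selects): published screens of this design
bold rows printed as 0.70 and rows qualifying on the slope measure
only, so both choices are required to reproduce the published 17-gene
set from the 66-row table bundled in `gutlink.data`. Negative
correlations select by absolute value. No multiple-testing correction
is applied to the r thresholds — the screen thresholds r, not q.

The taxon–gene screen aggregates counts to a taxonomic rank (summing
member counts; lineage gaps pool into `unclassified`), closes each
sample to relative abundance, averages per diet over FMT mice only
(GF mice carry no microbiota), and counts selected genes with
|r| > 0.8 (strict) against the taxon's diet-mean vector. Group sizes
may differ between the abundance and expression cohorts; the screen
correlates diet-level summaries, so unequal n per layer is fine. The
taxon–BW regression is a simple OLS of week-8 body weight on relative
abundance across individual FMT mice, reported as R² (squared Pearson
r).

### ANCOVA

`ancova_compare` fits three nested models — separate lines, common
slope with separate elevations, single line — and reports
F_slope = (RSS_common − RSS_separate)/(RSS_separate/(N−4)) with
(1, N−4) df and F_elev = (RSS_single − RSS_common)/(RSS_common/(N−3))
with (1, N−3) df. Both p-values are reported; the elevation test is
the meaningful group contrast when slopes are homogeneous. Exactly
linear (noiseless) data make the tests undefined; the growth stage
then records the deltas and leaves the ANCOVA empty rather than
failing.

### Differential-expression screen

The two-group test is a Welch t test on log₂(value + 1); the pass
criteria are raw p < 0.05 and any directional difference
(|log₂FC| > 0, computed with the same pseudo-count). BH q-values are
computed within each tissue×diet family and reported but do not gate
the filter. This deliberately replaces the negative-binomial count
model some pipelines use: the screen's contribution is the
threshold-and-intersect logic across diets and tissues, not the
two-group test, and absolute DEG counts are not a reproduction target.
Degenerate zero-variance genes resolve by convention (equal means →
p = 1; different means → p = 0, flagged), so noiseless synthetic
fixtures remain testable.

### Diversity analytics

- Shannon entropy uses natural log by default (base switchable); the
  index is often cited without a base.
- Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), which
  is defined when no doubletons exist.
- Jensen–Shannon divergence uses log base 2, so JSD ∈ [0, 1]; the
  default distance is √JSD, which is a metric (the triangle inequality
  is property-tested on random profile triples). Raw divergence is
  available via a switch.
- PCoA is classical MDS on −½D² double-centred; negative eigenvalues
  are reported with a warning, never corrected or silently dropped.
- UPGMA merges the closest pair, size-weighted average linkage, node
  height = d/2; ties break on the lexicographically smallest label
  pair, making output deterministic. Output newick uses 17-significant-
  digit branch lengths so cophenetic distances reproduce ultrametric
  inputs exactly.
- Unweighted UniFrac: fraction of branch length on paths to exactly
  one community's taxa over branch length on paths to either's, on a
  rooted tree with nonnegative lengths.
- Rarefaction to a fixed depth is available as an explicit seeded step
  (off by default; synthetic libraries are already equal-depth).

## The synthetic cohort generator

The generator emulates the study design, not any particular dataset:
two colonization states × six diets (ND, StaHC, SucHC, FruHC, SaHF,
USaHF) with 4 or 7 mice per cell (drawn per diet, the same n for GF
and FMT), weekly weights for weeks 0–8, two tissues' expression, and
16S-like count tables for FMT mice.

A per-diet scalar effect u_d ~ U(0.2, 1) couples the three layers:

- Growth: BW_i(t) = b0_i + s·t + ε, b0_i ~ N(20 g, 1 g²) truncated
  positive, ε ~ N(0, 0.5² g²) per observation, GF slopes
  ~ U(0.35, 0.65) g/week and FMT slope = GF slope + 1.0·u_d g/week.
  The 1.0 g/week effect scale yields week-8 FMT−GF gaps of ~1.6–8 g,
  the magnitude such studies report; the within-group noise level is a
  calibration choice (no variance is published) fixed before the
  recovery tests were frozen.
- Expression: gene baselines are log-normal (median 50, ln-scale sd 1);
  multiplicative log-normal noise with CV 0.2. A planted gene k has its
  FMT mean scaled by (1 + 1.0·g_k·u_d), g_k = ±1 — linear in u_d, so
  the noiseless ΔGEL row is exactly proportional to u_d and the
  cross-diet correlation with ΔBW is exactly ±1 (an exponential
  response would curve away from proportionality and blur the planted
  r toward the selection boundary).
- Microbiome: per-sample composition ~ Dirichlet(300·base_d), counts ~
  Multinomial(20 000). Planted taxa get base mass at 1.5× the 80th
  percentile of the Gamma(0.8) background weights; in diet d their
  proportion scales by exp(h_j·u_d). The three taxa sharing the planted
  family (named Ruminococcaceae, under Bacillota/Clostridia) carry
  coherent gains h ~ U(1.4, 1.8); the remaining planted taxa are
  singletons in random families with weaker gains h ~ U(0.6, 1.0).
  That hierarchy — a family of coherently responding species versus
  isolated responders — is precisely the structure the family-level
  aggregation screens are designed to reward, and with equal gains the
  singletons' host families would tie or beat the planted family at
  family rank. GF mice get all-zero count columns and are excluded
  from all microbiome stages. The phylogeny is a random bifurcation
  with Exp(1) branch lengths: only UniFrac's branch-set logic is
  exercised, not phylogenetic realism.

One integer seed drives everything; each table draws from a fixed
substream (`default_rng([seed, offset])`), so regenerating one table
never perturbs another, and identical (config, seed) produce
byte-identical files.

### What the generator does not emulate

Real cohorts have nonlinear growth, diet-specific baseline expression
shared by GF and FMT mice, phylogenetically structured compositions,
library-size variation, and zero inflation beyond the
Dirichlet-multinomial. Passing recovery tests therefore show the
*screens* do what they claim under the stated noise model — they do
not certify performance on real sequencing data.

### A note on the screen's null rate

The |r| ≥ 0.70 selection rule at n = 6 diets has a null selection
probability of ≈ 0.12 per measure (the df = 4 closed form at r = 0.7),
≈ 0.15–0.20 for the max over the two correlated ΔBW measures. This is
a property of the threshold geometry, not of any noise setting:
Pearson r is scale-free, so no generator configuration can push the
false-selection rate among null genes materially below that floor.
The recovery suite reports the measured rate (~0.15 under the frozen
defaults) and the null-calibration test verifies it matches a
permutation-estimated null within Monte-Carlo error. Consumers of the
screen should treat the 0.70 threshold as a ranking device at this
panel size, not an error-rate guarantee — the published design
mitigates this by screening only genes that already passed the
cross-diet DEG intersection.

## Numerical and design choices

- Pearson on zero-variance input raises a typed error; callers exclude
  the record with a logged reason. |r| = 1 returns p = 0 with a
  degeneracy flag instead of raising, because noiseless fixtures hit
  it legitimately.
- Benjamini–Hochberg is the standard step-up (verified against
  statsmodels); it preserves ordering and never shrinks a p-value but
  is not idempotent in edge cases (q-vectors are not always valid
  p-value configurations), so no idempotence is claimed.
- The two-way ANOVA uses type-II sums of squares via an OLS fit
  (statsmodels), chosen because the designs are unbalanced (n = 4 or
  7) and type II does not depend on factor order. Empty cells raise an
  explicit unsupported-layout error. Tukey–Kramer p-values evaluate
  the studentized-range distribution (scipy) with the pooled residual
  df.
- All tables are TSV (UTF-8, header row, full-precision float repr;
  matrices read back exactly via round-trip float parsing); trees are
  newick; ground truth and run manifests are JSON. Diet order is taken
  from the contrast table and validated against every downstream
  vector to prevent silent misalignment in the correlation screens.
- Default problem sizes (200 genes × 2 tissues, 150 taxa, ~66 mice,
  10 planted genes, 5 planted taxa) keep a full cohort generation plus
  all screens under ~2 s, so recovery statistics over 10–20 seeds run
  in well under a minute each.

## Known limitations

- The Welch-on-log substitute will not reproduce absolute DEG counts
  from count-model pipelines; only the screening logic is comparable.
- ΔGEL uses raw-scale means; a log-scale switch would change which
  genes dominate the correlation and is not currently exposed.
- Weighted UniFrac is not implemented (presence/absence only).
- The ANCOVA assumes a straight-line mean trajectory; growth curves
  with a plateau need a different model before the contrast step.
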