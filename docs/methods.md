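# Methods

This note documents the models behind each `trmet` stage, the synthetic
study the package tests itself against, the numerical choices, and what the
passing tests do and do not establish about real data.

## Quantification model

Measured intensity of ion *i* in a well of plate *p* is modeled as

    I = gamma_p * (alpha_i,cell * N + beta_i) * (1 + eps)

with per-plate instrument factor gamma_p, per-(ion, line) slope alpha,
extracted cell number N, cell-independent background beta, and
multiplicative noise eps.

**Plate factors.** gamma_p is a single scalar per plate shared across ions
(the log-linear pooled-extract model has no ion index on gamma). The
two-factor model log I = log gamma_p + log M_(i,pool) is fitted by
alternating projections over all pooled wells; for balanced designs one
pass is the exact least-squares solution, and iteration (tolerance 1e-12)
covers unbalanced ones. Pooled compositions are shared only within an
experiment batch, so the plate/pool design graph decomposes into connected
components; the gauge `prod(gamma_p) = 1` is applied per component (the
global intensity scale is unidentifiable anyway). Plates in different
components are comparable only up to a factor, which the returned component
labels make explicit rather than erroring out.

**Cell-number regression.** For each ion, one multiple regression over all
lines with a block-diagonal design (one alpha per line, one shared
intercept) — all ions share the design, so a single pseudo-inverse solves
every ion. Standard errors and two-sided t-test p-values per alpha come
from the per-ion residual variance. Lines whose samples do not span at
least two distinct cell counts are flagged missing rather than fitted.

**Ion filter.** Retained iff Bonferroni-significant
(p <= 0.05 / (n_lines x n_ions)) in at least one line *and* nominally
significant (p < 0.05) in more than 80 % of lines. The second criterion
deliberately uses the nominal level: requiring Bonferroni in 80 % of lines
would make retention depend on panel size in a way the screening design
does not intend. At 54 lines and 2723 ions the Bonferroni threshold is
3.4e-7.

**Volume correction.** PCA on the retained alpha matrix (lines as
observations) with per-ion standardization; ions correlating with PC1 at
Pearson r > 0.8 (p < 0.05) are volume reporters; each selected row is
rescaled to unit mean before averaging into the per-line consensus factor,
so high-abundance ions do not dominate. Standardization before PCA is a
deliberate choice: raw per-cell slopes span orders of magnitude between
ions, and on the synthetic study the center-only variant locks PC1 onto the
few most abundant ions (volume recovery r = 0.23) while the standardized
variant recovers the volume factor essentially exactly (r = 0.9998). A
`standardize_pca=False` switch restores the center-only behavior. PC1 is
oriented so the selected reporters correlate positively.

**Z-scores** use the population (1/n) standard deviation. Rows constant to
within float precision (SD <= 1e-10 of the row's magnitude) are flagged
undefined rather than amplified into noise. Missing values propagate and
are treated as zero by downstream correlation stages (they mark abundances
at background level).

**Annotation.** Deprotonation ([M-H]-, proton mass 1.007276 amu) at 0.003
amu tolerance; alpha-keto acids are additionally matched as phenylhydrazone
derivatives (+C6H8N2 -H2O = +90.05818 amu, from standard atomic masses).
All matches within tolerance are reported; annotation is putative by
construction.

## TR activity

Expression is decomposed as E ≈ A·P with A restricted to a signed
TR→target support. The solver is alternating least squares:

* **A-step**: per-gene sign-restricted least squares (activation loadings
  >= 0, repression <= 0, unknown unconstrained), batched over genes with
  equal support size via stacked normal equations (jitter 1e-12 x mean
  Gram diagonal); sign violations are handled by an active-set pass that
  zeroes the violating loadings and refits.
* **P-step**: unconstrained least squares, followed by a per-TR scale gauge
  (max |activity| = 1; the product A·P is invariant).
* Convergence: relative objective change < 1e-6 (default), max 60-100
  iterations; non-convergence returns the best iterate with a flag. The
  objective is non-increasing by construction.

**Growth pseudo-TR and identifiability.** A dense pseudo-TR column absorbs
proliferation's pleiotropic, approximately rank-one imprint on expression.
Because its loadings are unconstrained and it targets every gene, each real
TR's activity row is identified only up to adding multiples of the growth
row: the transformation P_j -> P_j - c_j P_growth, A_growth -> A_growth +
sum_j c_j A_j leaves A·P and all sign constraints untouched. The solver
therefore reports the gauge representative with every TR row orthogonal to
the growth row. Consequently "TR activity" here means the
growth-orthogonal component of the regulatory signal — the only component
any method can recover under this model — and the synthetic generator
defines its ground-truth activities the same way.

**Bootstrap.** Each TR seeds `subnetworks_per_tr` subnetworks of itself,
k = 48 uniformly drawn others and the growth pseudo-TR (50 TR columns at
the defaults); estimates are collected for *every* TR in a subnetwork, so
at 728 TRs each TR is estimated ~490 times. Per subnetwork, each TR row is
sign-aligned (orientation chosen so the edge-sign-weighted covariance with
its targets' expression is positive; prior signs where known, fitted
loading signs for unknown-mode edges) and normalized by its max |value|; a
`normalize="global"` switch rescales per TR across all estimates instead.
The reported activity is the median per (TR, line), with SD and estimate
counts. Sign enforcement from edge annotations is on by default and can be
disabled.

## Association network

Spearman correlations (average ranks for ties, t approximation for p) over
the shared cell lines. The 0.1 % FDR link threshold resamples the
metabolome's cell-line labels with replacement, independently of the
activity table — the pairing must break to form a null; a paired bootstrap
would preserve the signal and misestimate the threshold. All |R| from 100
resamples are pooled and the threshold is the 99.9th percentile. The same
machinery provides the augmented TR-enzyme network (|R| > 0.5 on a
compendium), per-metabolite tissue ANOVA with Storey q-values, and a
tissue-similarity ROC over all unordered line pairs (Spearman profile
similarity by default; the similarity metric is an option).

## Metabolic-network distance

The stoichiometric model is a bipartite graph (metabolites, reactions;
participation edges; direction ignored) with a flat gene -> reaction map.
The enzyme-metabolite distance is the number of reaction nodes on the
shortest alternating path, counting the enzyme's own reaction (distance 1
for its own substrates/products); TR distance is the minimum over enzyme
targets. Distance-vs-|R| curves sweep thresholds cumulatively (a binned
mode exists); the null randomizes the graph by bipartite double-edge swaps
(2 x |E| accepted swaps, duplicates rejected), which preserves both degree
sequences exactly and avoids density artifacts. Permutation p per threshold
is the fraction of randomized graphs with a mean distance at least as
small. Currency-metabolite hubs can optionally be excluded by a max-degree
flag (off by default). BFS runs once per graph from the union of all TRs'
reactions (scipy sparse BFS), making 10,000 randomizations feasible on one
CPU in minutes.

## Enrichment and multiple testing

Hypergeometric enrichment is the exact upper tail. The rank-based variant
computes, per pathway, the minimum hypergeometric p over all ranking
prefixes ending at a member; because that minimum is selected, its
significance is calibrated against random permutations of the ranking
(the analytic correction of the original iterative formulation is not
reproduced here; the permutation calibration is the package's documented
substitution). Storey q-values estimate pi0 on a lambda grid with a cubic
extrapolation to lambda -> 1; below 10 tests the estimate is unstable and
the function falls back to Benjamini-Hochberg with a warning.

## Scores

C_TR = R x (-log10 p) per metabolite (two-sided Spearman p); undefined
pairs contribute zero. S = C·x / ||C||_1 bounds |S| by max |x|. The
in-vivo permutation p is one-sided (fraction of metabolite-order shuffles
with S at least as large), with no pseudocount — p = 0 is reportable, and
the resolution is 1/n_perm; metabolites are put in a canonical order before
shuffling so the Monte-Carlo p is invariant to input ordering. q-values are
per patient across TRs; TRs are summarized by the median q and median S
across patients (median-of-q, not q-of-median). Knockdown ranking applies
the same score per siRNA concentration and ranks by median; per-metabolite
significance multiplies the per-concentration p-values. The drug model
regresses sensitivity on one TR's activity plus tissue indicators (the
indicators take the intercept's role); lambda's t-test is
Bonferroni-controlled at alpha / (n_TR x n_drug), and cluster x
mechanism-of-action enrichment of significant pairs is hypergeometric with
its own Bonferroni threshold. Raw GI50 panels should be log-transformed
(`log_transform=True`); the synthetic panel is already on a log-like scale.

## Effector models

activity = a + b·protein·f(met; K_m)·f(kin; K_k), f activating x/(K+x) or
inhibiting K/(K+x), modulators rescaled to unit median. (a, b) are profiled
out in closed form at every objective evaluation, so the search runs only
over log10 K in [-4, 4]: a 7-point grid per dimension followed by one
Nelder-Mead refinement (~1-5 ms per fit). Per TR the candidate set is 2M
metabolite-only + 2K kinase-only + 4MK combined models. The null pools
delta-MSE values from refits against activity rows with permuted cell-line
labels across all specs; a spec passes at FDR f iff its delta-MSE exceeds
the (1-f) null quantile, and the scan refuses to run if the pool cannot
resolve that quantile. A negative delta-MSE beyond numerical tolerance
marks optimizer failure and the spec is excluded rather than clipped. The
functional forms are this package's choice and are pluggable; the scan
does not attempt to reproduce any particular published model count.

## The synthetic study

The generator emulates the study design end to end; its defaults are the
package's study conditions and are deliberately fixed:

* 54 lines from 8 tissues, batches of 5 lines, 5 plates per batch (one per
  time point), 12 pooled wells and 3 blanks per plate; triplicate wells at
  5 daily time points give 15 metabolome samples per line. Logistic
  confluence growth from ~4-8 % seeding; doubling times uniform 18-45 h;
  characteristic cell areas uniform 1200-3600 um^2 with constant cell
  height (12 um), so volume is proportional to area.
* 500 ions, of which 300 are true metabolites: per-cell slopes are
  ion scale x relative cell volume x exp(biology), with log-normal ion
  scales (log-sd 1), per-(ion, line) biological variation (log-sd 0.4),
  60 pure volume-reporter ions (fatty-acid-like), 40 metabolites with
  tissue-dependent shifts (log-sd 0.6), and 10 TRs each coupled to ~8
  metabolites adjacent to their enzyme targets in a ring-shaped toy
  metabolic graph (coupling: one log-unit per activity unit). The other
  200 ions carry only background. Intensity noise is multiplicative
  log-normal at CV 10 % (FIA-MS noise scales with signal); plate factors
  are log-normal (log-sd 0.25) with product 1 per batch.
* 100 TRs over 1200 genes with 12-24 signed targets each (70 %
  activation); expression is A·P plus a rank-one growth confounder
  (strength 2, proportional to standardized 1/doubling-time) plus N(0,
  0.1) noise. Activities are iid normal rows drawn orthogonal to the
  growth direction (see identifiability above). The gene/TR ratio and
  target counts sit in the range of curated human TR-target resources;
  with substantially denser co-regulation the 49-real-TR subnetworks leave
  enough unmodeled signal that a few TRs drop below 0.9 recovery.
* Patient cohorts: per patient FC = effect x C_perturbed + N(0, 1), 2 %
  values missing at random plus ~12 mostly-missing metabolites to exercise
  the >10-missing filter. Knockdowns move metabolites against the TR's
  signature, scaled by siRNA concentration. The proteome is log-normal
  with unit median; planted effector TRs follow the saturable model with
  activity noise at the configured CV; drug sensitivities are
  lambda x activity + tissue effects + noise, with one drug class targeting
  one TR cluster.

What the generator does **not** emulate: raw spectra, isotopes and adduct
chemistry beyond the two annotation modes; correlated biological programs
beyond the planted couplings (real metabolomes have pervasive co-variation);
non-linear intensity saturation; batch-varying noise; realistic metabolic
network topology (a decorated ring, not a genome-scale reconstruction);
dropout that depends on abundance. Passing recovery tests therefore shows
the estimators are correct and well-calibrated under the stated model, not
that real data satisfy that model.

## Problem sizes used by the test suite

The acceptance tests run the full default study (54 lines, 500 ions, 100
TRs, 10 subnetworks per TR, 10,000 permutations and randomized graphs
where those defaults apply); unit and property tests use scaled-down
studies (12-24 lines, 40-80 metabolites, 15-30 TRs) that preserve the
statistical structure. The bootstrap-coverage quantity reported by
`scripts/acceptance.py` is computed by executing the sampling scheme at
full scale; its average over TRs equals 490 for every seed because the
total number of appearance slots is fixed by the design.

## Known limitations

* NCA identifiability is handled for the dense growth column, but
  pathological supports (e.g. a TR whose target set contains another's)
  can still mix; the bootstrap median mitigates but does not eliminate
  this.
* The iterative rank test's permutation calibration caches nulls per set
  size; p-values are floored at 1/n_perm.
* Storey's pi0 uses a polynomial smoother; for small test counts the BH
  fallback is conservative.
* The plate-factor model assumes pooled-well compositions are identical
  across a batch's plates pre-noise; drift within a batch is absorbed into
  noise.
* Distances ignore reaction direction and gene-reaction boolean rules.
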