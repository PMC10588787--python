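# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Study design and data model

A study consists of three analyte blocks measured on the same plasma
samples — proteins (~hundreds of analytes), eicosanoids (~tens), targeted
metabolites (~hundreds) — with one metadata record per sample: group
(healthy / remission / active), age in years, sex coded 0/1. All models
operate on log2 intensities. The three pairwise group comparisons are
called contrasts; a contrast named `A_vs_B` is estimated as mean(B) −
mean(A), so a positive estimate means "up in the later disease state".

## Preprocessing

* **Valid-value filter.** An analyte is retained when at least
  `min_valid` observed values exist in at least one group (default 3 for
  plasma blocks; 5 is conventional for tissue). The filter is idempotent
  and monotone in `min_valid`. Counting happens before any imputation.
* **Gaussian down-shift imputation** (protein block). Missing cells are
  drawn from N(μ_c − 1.8σ_c, (0.3σ_c)²) with μ_c, σ_c the mean and sample
  SD of the observed values of analyte c — the convention of mainstream
  proteomics software, which treats missingness as predominantly
  below-detection. Columns with fewer than two observed values fall back
  to the whole-matrix SD (and mean, if nothing is observed). Note the
  known side effect, visible in the validation runs: for strongly
  group-shifted analytes σ_c includes the group variance, so imputed
  values are pulled low in every group and fold-change estimates are
  attenuated. This is faithful to practice, not a defect of the
  implementation.
* **Below-LOD imputation** (eicosanoid block; metabolites if censored).
  Censored cells become min_observed(analyte)/√2, then the whole block is
  log2-transformed. Observed values pass through bit-identically before
  the log. Analytes with no observed value cannot be imputed and are
  dropped with a warning. Censoring itself (in the generator) flags
  values strictly below the per-analyte empirical quantile, so tied
  all-equal analytes are never partially censored.

## Moderated contrasts (stage 1)

Per analyte, ordinary least squares on the design
[healthy, remission, active indicators (no intercept), centred age, sex];
contrasts are differences of group coefficients, so all three pairwise
comparisons come from one joint fit (a pairwise-subset mode exists behind
a switch). Residual variances s²_g with d degrees of freedom are modelled
as s²_g | σ²_g ~ σ²_g χ²_d/d with the scaled-inverse-χ² prior
σ²_g ~ s₀²·d₀/χ²_{d₀}. The marginal moments of log s²_g give closed-form
estimators: the excess variance of log s² beyond trigamma(d/2) is
inverted through the trigamma function to d₀, and s₀² follows from the
mean. Non-positive excess variance means the observed variances are at
least as concentrated as sampling noise alone predicts ⇒ d₀ = ∞ and
complete shrinkage (frequent at a few dozen samples). The posterior
variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) yields a moderated t with d₀ + d
df (Gaussian when d₀ = ∞). The estimator is cross-checked in the test
suite against the Bioconductor reference implementation of the same
moment-matching scheme and against both limits (d₀ → 0: ordinary t;
d₀ → ∞: s̃² = s₀²).

Multiple testing: Benjamini–Hochberg per contrast and per block at
q = 0.05. Plain Welch t-tests (`two_sided_ttests`) are provided for the
volcano-style single-block analyses; Welch rather than pooled because
group variances are not assumed equal.

## Sub-network discovery (stage 2)

The conditional-independence graph of each block is estimated by
neighborhood selection: every analyte j (standardized internally) is
lasso-regressed on all others with per-node penalty

    λ_j(K) = K · σ̂_j · √(2 · log p / n),

σ̂_j being the response SD on the standardized scale, and an edge i–j is
kept when both regressions select the pair (AND rule; OR available). The
lasso is solved exactly (coordinate descent, objective
(1/2n)‖y − Xw‖² + λ‖w‖₁); the identification of λ with that objective's
penalty weight is this package's calibration of the scalar-K semantics,
fixed by two requirements checked in the tests: independent data at K = 2
(p = 20, n = 200) yield an essentially empty graph, and a planted
correlation clique (loading 0.9, n = 400) is recovered edge-perfectly at
K = 1.5. AND-symmetrization is the default because the sub-networks serve
as a conservative reduction of the analyte space.

K sweeps 1.0–6.0 in 0.5 steps. At each K every connected component of
size ≥ 2 is tested against every contrast with the signed Stouffer
statistic S = m^{−1/2} Σ sign(β̂_j)·Φ⁻¹(1 − p_j/2) over the m members
(raw p and direction from stage 1), calibrated by resampling m analytes
from the block's analyte universe (default 10,000 permutations in the
library; 2,000 in the shipped pipeline configuration, which bounds the
Monte-Carlo SE of a 5% p-value at ~0.5%). Permutation p-values use the
add-one estimator (1 + #{|S*| ≥ |S|})/(n_perm + 1) and are BH-adjusted
within each (K, contrast) stratum. The chosen K maximizes the number of
significant (sub-network, contrast) pairs, ties toward smaller K (sparser
graphs). If nothing is significant at any K, a sentinel is returned and
integration proceeds with single analytes only.

Chosen sub-networks are summarized by PCA of their standardized member
columns: PC1 alone when it explains at least 75% of the variance, PC1+PC2
when strictly below. Fractions within 1e−9 of the threshold count as at
it — the boundary case is otherwise decided by floating-point rounding.
Component signs follow the largest-|loading|-positive convention.

A known behaviour of the count-maximizing K rule, characterized during
validation: when a module's members all carry strong, *homogeneous*
effects, every fragment of the module remains set-significant, so the
rule can prefer the penalty region where the module splits (more
significant sets). With heterogeneous member effects — the realistic
case — fragments lose set-level power and the rule settles on the intact
modules. The validation experiments therefore plant graded within-module
shifts (member-level contrast z of roughly 3.2/1.6/1.6/0.8/0.8).

## Integration network (stages 3–4)

Per contrast, the variable set pools: all significant single analytes not
already inside a summarized sub-network (de-duplication), every chosen
sub-network PC score, age and sex (sex as a 0/1 numeric column — an
approximation shared with the standard partial-correlation packages).
Partial correlations between all pairs given all remaining columns come
from the inverse correlation matrix, R_ij = −P_ij/√(P_ii·P_jj); this is
verified against the residual-regression definition to 1e−10 in the
tests. When n_samples ≤ n_variables + 2 a ridge of 1e−3 is added to the
correlation diagonal (reported on the result) — the thresholding happens
after regularization. The network keeps edges with |R| strictly greater
than 0.6, retains isolated nodes, preserves edge signs, and carries
per-node log2 fold-changes (for a sub-network node: its members' values,
plus their mean) for downstream rendering.

## Trajectory taxonomy

Per analyte, log2 values are residualized on age and sex (with
intercept), the residuals z-scored across all samples (sample SD), and
group means (z_h, z_r, z_a) taken. Classification, with span = |z_a − z_h|
and δ = 1/3 (configurable, echoed in every output table):

1. span = 0 → `no_signal`;
2. |z_r − z_h| ≤ δ·span → `normalising`; |z_r − z_a| ≤ δ·span →
   `non_normalising` (the closer end wins when δ admits both);
3. otherwise z_h strictly between z_r and z_a → `exceptional`
   (healthy_between), or z_a strictly between → `exceptional`
   (active_between);
4. otherwise `intermediate`.

The δ-closeness classes are evaluated before betweenness deliberately: a
marker sitting essentially at the healthy level would otherwise be tipped
into `exceptional` by the sampling sign of z_r − z_h, which happens on
half of all null draws. `intermediate` exists because the three verbal
classes are not exhaustive. Classification is invariant to a global sign
flip of the profile.

## Synthetic-data generator

The generator emulates: (i) planted correlation modules — members share a
latent factor, x_j = ρf + √(1−ρ²)ε_j, so within-module correlation has
expectation ρ² and the module's conditional-independence graph is a
clique; (ii) additive group shifts keyed by contrast (applied to the
second-named group); (iii) planted trajectory profiles realized as group
mean patterns (0, 0, Δ), (0, Δ, Δ) and (0, −Δ, Δ); (iv) age slopes on
centred age (age ~ U(25, 65), matching the cohorts' span without their
sex imbalance; sex ~ Bernoulli(0.5)); (v) left-censoring of the
eicosanoid block at a per-analyte quantile of the raw scale; (vi) MCAR
missingness in the protein block, with an optional
intensity-dependent (MNAR) mode, off by default because no distributional
form for it is established. Analyte baselines are uniform on log2
[12, 20] so the raw scale stays positive. Everything planted is recorded
in a `GroundTruth` object; given a seed, generation is bit-reproducible.

It does **not** emulate: mass-spectral artefacts (peak shapes, retention
time drift, isotopes), technical replicates, batch effects, inter-block
correlation beyond what planted modules induce, or heavy-tailed /
non-Gaussian intensity distributions. Passing tests therefore demonstrate
correctness of the statistical machinery under a Gaussian additive model,
not robustness to real acquisition artefacts.

Default sizes (60 proteins / 24 eicosanoids / 90 metabolites, 12 samples
per group) mirror the cohort's group sizes at a reduced analyte count;
full-size studies are one config field away. The default planted
trajectory span is 2.5 residual SDs: since z-profiles are standardized
across all samples (which folds the between-group variance into the
denominator), 2.5 SDs places the δ = 1/3 class boundaries about two
group-mean standard errors from the planted profile at n = 12/group —
the smallest span for which class recovery is a sharp property rather
than a coin flip. The reference demo study plants module shifts of 1.2 to
2.4 log2 units, the 2- to 5-fold range reported for acute-phase plasma
proteins and platelet-released eicosanoids in flares.

## Validation experiments

`triomics.validation` (shared by the test suite and
`scripts/acceptance.py`) measures, with all problem sizes chosen to keep
the whole suite inside a few minutes on one CPU:

* max |partial R − residual-regression oracle| over 50 random instances
  (8 variables, 40 samples);
* max |BH − by-definition step-up| over 1000 random p-vectors;
* the moderated-t limits (d₀ → 0 and d₀ → ∞) on a 200-analyte study;
* empirical FDR at q = 0.05 over 50 null studies (500 analytes,
  12 samples/group, age/sex effects present, no group effects);
* planted-partition recovery through the *entire* stage-2 machinery
  (sweep, set tests, K choice) on 20 studies with three 5-analyte modules
  (loading 0.9) among 60 analytes at n = 300 — scored as Adjusted Rand
  Index between chosen-K component membership and the planted sets over
  the planted analytes, unassigned analytes counting as singletons;
* trajectory class recovery over 20 studies (30 planted profiles each);
* mean estimated log2 fold-change over 50 independently planted analytes
  (true shift 2.0).

## Known limitations

* The neighborhood-selection graph is a stand-in for exact
  partial-correlation model search; edge sets at a given K are not
  comparable across implementations, only the recovered component
  structure is.
* The count-maximizing K rule is only as stable as the set-significance
  landscape (see stage 2 above); its fragmentation preference under
  homogeneous strong effects is inherent to the rule, not removable by
  implementation.
* Down-shift imputation biases fold-change estimates of strongly shifted,
  partially missing analytes toward zero (attenuation), as in standard
  practice.
* With analyte counts near the sample count the ridge-regularized partial
  correlations are biased toward zero; the |R| > 0.6 threshold then acts
  conservatively.
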