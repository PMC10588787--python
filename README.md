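# triomics

Integration of three-block plasma omics profiles — proteins, eicosanoids
and targeted metabolites — for three-group case-control studies that
compare **healthy controls**, patients in **remission**, and patients with
**active** inflammatory disease (the motivating setting is ulcerative
colitis). The central question the pipeline answers: *which molecular
markers separate the disease states, how do they hang together across
omics layers, and which of them fail to return to healthy levels during
clinical remission?*

## The method

Given samples × analytes intensity matrices for each block plus per-sample
group, age and sex, the pipeline runs five stages:

1. **Preprocessing.** Proteomics missing values: analytes are kept when at
   least `min_valid` (default 3) observed values exist in one group, and
   the remaining holes are drawn from a down-shifted Gaussian,
   N(μ<sub>c</sub> − 1.8σ<sub>c</sub>, (0.3σ<sub>c</sub>)²) per analyte c.
   Eicosanoid values below the detection limit are imputed as
   min<sub>observed</sub>/√2, then the block is log2-transformed.
2. **Moderated contrasts.** One linear model per analyte with group
   indicators plus age and sex; residual variances are shrunk by empirical
   Bayes, s̃²<sub>g</sub> = (d₀s₀² + d·s²<sub>g</sub>)/(d₀ + d), with
   (d₀, s₀²) estimated by moment-matching on log s² (trigamma inversion).
   The three pairwise contrasts are tested with moderated t statistics and
   Benjamini–Hochberg control at FDR 5%.
3. **Sub-network discovery.** Per block, a Gaussian-graphical-model graph
   is estimated by neighborhood selection: each analyte is lasso-regressed
   on all others with penalty λ<sub>j</sub> = K·σ̂<sub>j</sub>·√(2·log p/n),
   edges by AND-symmetrization, sub-networks = connected components. The
   multiplier K sweeps 1 to 6 in 0.5 steps; each sub-network is scored per
   contrast with a signed Stouffer statistic
   S = m<sup>−1/2</sup>·Σ sign(β̂<sub>j</sub>)·Φ⁻¹(1 − p<sub>j</sub>/2)
   against an analyte-resampling permutation null, and the K yielding the
   most significant (sub-network, contrast) pairs is chosen. Chosen
   sub-networks are summarized by PC1, or PC1+PC2 when PC1 explains less
   than 75% of the member variance.
4. **Integration network.** Per contrast, significant single analytes,
   sub-network PC scores, age and sex are pooled; partial correlations
   between every pair given all remaining variables are computed from the
   inverse correlation matrix (R<sub>ij</sub> = −P<sub>ij</sub>/√(P<sub>ii</sub>P<sub>jj</sub>));
   edges are kept where |R| > 0.6 (strict).
5. **Remission trajectories.** Each analyte's age/sex-corrected group-mean
   z-scores (z<sub>h</sub>, z<sub>r</sub>, z<sub>a</sub>) are classified as
   *normalising* (remission back at healthy level), *non-normalising*
   (stuck at the active level), *exceptional* (healthy or active strictly
   between the other two), or *intermediate* — "close to" meaning within
   δ = 1/3 of the healthy↔active span.

Because the cohort data are not freely redistributable, the package ships
a first-class synthetic-study generator (`triomics.synthetic`) with
planted correlation modules, graded group effects, age/sex confounding,
detection-limit censoring and missingness — every downstream stage is
validated against this known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
synthetic reference study (36 samples, 60 proteins with 10% missing
values, 24 eicosanoids with 10% censoring, 90 metabolites; one planted
protein module and one metabolite module with graded 2- to 5-fold
healthy-vs-active shifts):

```sh
cd analysis
python 01_simulate_study.py
python 03_differential_contrasts.py
python 04_subnetwork_selection.py
```

Stage-1 output (excerpt):

```
metabolite: prior df d0 = inf, prior variance s0^2 = 1.006
  healthy_vs_active: 8 significant analytes (top: ['meta_0022', 'meta_0020', 'meta_0021'])
  healthy_vs_remission: 3 significant analytes (top: ['meta_0021', 'meta_0022', 'meta_0010'])
```

— the empirical-Bayes prior concentrates at infinite df (all metabolite
variances consistent with a common value) and the strongest hits are the
planted trajectory markers and the remission-specific metabolites.
Stage-2 K selection:

```
  K  n_significant
1.0              4
1.5              2
2.0              0
...
chosen K = 1.0 with 4 significant pairs
  metabolite:meta_0000+...+meta_0005: 6 members, PC1 explains 82% -> 1 component(s)
```

— the planted 6-metabolite module is recovered as one connected component
whose PC1 (82% of variance ≥ 75%) becomes a single integration variable.
The trajectory driver classifies the planted markers correctly:

```
  meta_0021 (metabolite): z_h=-1.11 z_r=+0.46 z_a=+0.65 -> non_normalising
  meta_0020 (metabolite): z_h=-0.63 z_r=-0.43 z_a=+1.05 -> normalising
  meta_0022 (metabolite): z_h=-0.20 z_r=-0.99 z_a=+1.19 -> exceptional
```

The same pipeline is available as a CLI (`triomics simulate`,
`triomics run --config config.yaml`, `triomics report`) for delimited
input tables.

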