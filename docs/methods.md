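# Methods

## The generative model behind the synthetic cohort

The generator emulates a four-group child cohort measured on a
40-analyte multiplex plasma panel. Subject *i* in group *g* draws a
latent score vector **s**ᵢ ~ N(**a**₍g₎, σ²ₛ I) of length K = 3, where
**a**₍g₎ is the group's mean activation of each planted network. The
latent analyte vector is **x**ᵢ = Λ**s**ᵢ + **ε**ᵢ with Λ the analytes × K
loading matrix (disjoint supports, weights ±1) and εᵢⱼ ~ N(0, σ²ₑ).
Measured concentrations are lognormal,
cᵢⱼ = exp(μⱼ + τⱼ·xᵢⱼ) pg/mL — multiplex cytokine panels are strongly
right-skewed, which is also why the analysis chain rank-normalizes.

Detection censoring is imposed per analyte by deterministic count:
exactly round(rate·n) cells, chosen uniformly under the seed, are set
below the LOD. A deterministic count (rather than per-cell Bernoulli
draws) makes exclusion tests exact. Gross outliers can be injected on
the latent scale at a fixed displacement (> 3.29 SD) so the Winsorization
step has a known target set.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| group sizes | 15 / 12 / 15 / 17 (n = 59) | the target study design |
| K, supports | 3 networks: {IL-2, TNF-β, IL-10, IL-15}, {MIP-1β, MDC, MCP-4, PlGF(−), CRP(−)}, {eotaxin-3, eotaxin, bFGF} | the qualitative finding the pipeline must be able to recover |
| group activations | see `DEFAULT_GROUP_ACTIVATIONS` | sign pattern: network 1 up in C/ND, down under alcohol; network 2 splits A/TD (+) vs A/ND (−); network 3 up in both A groups, down in C/TD |
| σₛ (subject score SD) | 1.0 | unit within-group scatter; activations of ~1.4–1.9 give clearly separated but overlapping groups |
| σₑ (analyte noise SD) | 0.5 | measurement + biological noise at half the subject scatter |
| μ, τ (lognormal link) | 2.0, 0.5 | median ≈ 7.4 pg/mL, a typical mid-panel plasma level |
| LOD | exp(μ − 4τ) | uncensored analytes are essentially fully detected |
| censor rates | 27/49/58/73/73/92% on GM-CSF, IL-1α, IL-4, IL-13, IL-1β, IL-12p70 | the heavily censored analytes of a real V-PLEX child panel |
| covariates | smoking ~ Bern(0.25), BMI ~ N(23.8, 3.5²), sex ~ Bern(0.5), age ~ U(2, 3.5) y | plausible cohort values; independent of group by default |

The activation matrix deserves a note. An orthogonal (Varimax) rotation
can only recover the planted loading columns if the group-activation
columns are uncorrelated across groups: the rotation orbit of the PCA
loadings is {Λ C^½ R} with C the activation covariance, and the sparse
truth Λ lies in that orbit only when C is diagonal. The default
activations are therefore the (group-size-weighted) Löwdin
orthogonalization of the qualitative sign pattern — the signs and
magnitudes of the story are preserved, and the planted structure is
identifiable in principle, so recovery failures measure estimation error
rather than model misspecification.

`covariate_group_effect` is a confounding knob (default 0) that tilts
smoking prevalence across groups, for testing the regression adjustment
under dependence.

### What the generator does not emulate

Plate/batch effects, standard-curve nonlinearity near the LOD,
inter-assay drift, non-lognormal heavy tails, and covariate–outcome
confounding beyond the single smoking knob. Passing tests therefore show
the *pipeline* is correct under its stated assumptions, not that those
assumptions hold for any particular real cohort.

## Preprocessing

Order: below-LOD zeroing → >10%-undetectable exclusion → Winsorization →
Blom. The full panel is forked before exclusion for the heatmap path.
Choices where conventions differ:

- **Zeroing** is strictly below LOD; a value equal to the LOD counts as
  detected.
- **Exclusion** is strictly greater than 10% undetectable.
- **Winsorization** uses the sample SD (n − 1), computed once including
  the prospective outliers, with boundary replacement (mean ± 3.29 SD)
  in a single pass. Single-pass clipping is deliberately not iterated;
  consequently a clipped cell may again exceed |3.29| under the
  *recomputed* moments — re-running the operator is not guaranteed to be
  a no-op, and the report ledger records exactly the one pass applied.
  The boundary-value convention (vs. next-most-extreme observed value)
  is a configuration choice recorded in the report.
- **Blom** uses average ranks, so ties (including the zeros created by
  LOD assignment) map to equal normal scores. Zeros simply occupy the
  bottom ranks; analytes where they would dominate have already been
  excluded. Because Blom is rank-based, Winsorizing first changes
  nothing whenever clipping creates no new ties.

## Univariate models

Reference-cell coding with C/TD as reference yields the pairwise
contrasts directly; the group block is tested by the F statistic on the
R² increment over the covariate-only model. Group-block p values are
reported unadjusted across analytes (a Holm-adjusted column is provided
alongside). For categorical sample characteristics the dispatch rule is
Fisher's exact test when any expected cell count is below 5, chi-square
otherwise, overridable per variable. For tables larger than 2×2 the
Fisher p value is estimated by seeded Monte-Carlo sampling of tables
under fixed margins (Patefield's algorithm via
`scipy.stats.random_table`), with the (1 + count)/(1 + N) estimator;
2×2 tables use the exact routine.

## CPCA

The projection uses all four indicator columns through a pseudoinverse
least-squares solve; the coding is intercept-free and rank-complete, and
the projection (not the coefficients) is the object of interest. The
implementation asserts at run time that the projection equals per-group
means. Eigenvalues use the n − 1 denominator so they sum to the total
sample variance of the centered predicted matrix; loadings carry
correlation-like scaling (eigenvector × √eigenvalue) and scores are
standardized to unit variance (correlations with group indicators are
scale-invariant, so this choice affects only the score files).

Component retention defaults to the tolerance rule — eigenvalues above
10⁻¹⁰ × the largest, i.e. the rank of the group-mean configuration —
because visual scree reading is not reproducible; a maximum-second-
difference elbow heuristic and a manual K override are provided and
logged. For four groups the retained count can never exceed 3.

Varimax is the classic Kaiser pairwise-rotation algorithm: rows are
normalized by their communality square root (zero-communality rows are
excluded from normalization and left in place), planar angles maximize
the criterion pairwise until a full sweep improves it by < 10⁻⁸ (cap
1000 sweeps), and de-normalization is implicit since rotated = L·R holds
exactly. Scores are rotated by the same R, which preserves their unit
variance.

Network membership thresholds |rotated loading| at 0.40 by default on
the Blom-scale pipeline (loadings there are correlation-like). The
threshold is exposed prominently and recorded in every output, as is the
retained-analyte count (34 on the default cohort) — neither is ever
hard-coded. Group–network correlation p values are reported unadjusted,
per-group and per-component; optional Holm adjustment is available.

## Recovery scoring

Planted-truth recovery (`cytonet.evaluate`) is scored on the
log-concentration scale — the exact inverse of the generator's lognormal
link — after applying the heavy-censoring exclusion, because the planted
model is linear and the Blom transform is not: rank-normal scoring
standardizes every analyte (giving null analytes a fixed between-group
variance share of (g − 1)/(n − 1) ≈ 0.05 at n = 59 regardless of noise)
and warps strongly group-separated marginals, which caps loading
congruence against a sparse linear truth near 0.86 irrespective of SNR.
On the linear scale the same estimator recovers the truth cleanly, so
the score isolates estimation error. Matching is one-to-one by maximum
absolute Tucker congruence (Hungarian assignment) with sign alignment;
a replicate counts as recovered when every matched congruence is ≥ 0.90
and the member sets and activation signs agree. The membership threshold
there is 0.25 in log units — the planted weights are ±1 on the latent
scale and τ = 0.5, so this equals 0.5 in latent units, centered in the
empirical gap between member loadings (≥ ~0.30) and null loadings
(≤ ~0.15 at the 99th percentile).

## Numerical choices and degenerate inputs

- Zero-SD analytes: skipped by Winsorization, zero column in the
  heatmap, both with logged warnings.
- All-zero centered predicted matrix (identical group means): zero
  components with a warning rather than an error.
- Constant component scores make group correlations undefined and raise.
- Censoring counts use round-half-even on rate·n; the printed rates at
  n = 59 produce 16/29/34/43/43/54 censored cells with no ties at .5.
- Determinism: every stochastic step draws from a generator seeded from
  the model seed (generation, censoring and outlier placement use
  separate child streams, so toggling one stage does not reshuffle
  another); pipeline outputs are byte-identical under a fixed config.

## Problem sizes

Simulation-based tests use n = 59 cohorts throughout — the design the
pipeline targets. Calibration suites run 2000 null replicates; the
recovery simulation runs 200 cohort replicates; the power check for the
planted 1.5-SD contrast runs 500 replicates with its pilot-fixed 0.80
pass threshold. The whole test suite runs in a few minutes on one CPU.

## Known limitations

- The pipeline zeroes censored values as specified rather than imputing;
  with informative censoring near the exclusion threshold this biases
  analyte means downward (the exclusion rule is the mitigation).
- Single-pass Winsorization is order-dependent with respect to Blom only
  through ties, and is not idempotent (see above).
- CPCA components are linear in the Blom scores; nonlinear group
  structure (e.g. variance differences with equal means) is invisible to
  the projection.
- With four groups the method cannot distinguish more than three
  networks; planted K > 3 folds into three components by construction.
- The r×c Monte-Carlo Fisher p value carries simulation error of order
  1/√N (N = 20 000 by default); it is not a network-algorithm exact p.
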