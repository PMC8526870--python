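# Methods

## The synthetic cohort

The generator emulates the statistical structure of a neonatal imaging
study of cortical development at term-equivalent age; it is the ground
truth against which every downstream stage is validated.

**Parcellation.** Parcels live on the unit sphere, one hemisphere mirrored
from the other. Seven region anchors (frontal, parietal, temporal,
occipital, insula, cingulate, somatosensory) initialise a farthest-point
sampler that adds seed points maximising the minimum chordal distance to
those already chosen, approximating an equal-area Voronoi decomposition;
each parcel takes its nearest anchor's region label. The default is 143
parcels per hemisphere (286 total). Coordinates matter only for region
assignment and export — no surface geometry is simulated.

**Demographics.** Term gestational age (GA) at birth is truncated-normal
(mean 40.1, SD 1.2) on [37, 42.14] weeks; preterm GA (mean 32, SD 3.5) on
[23, 36.86]. PMA at scan is truncated-normal (mean 40.9, SD 1.8) on
[37, 45.14] independent of group — the cohorts are age-matched at scan —
but never before birth. Sex is ~46% female (encoded 0 female / 1 male).
BSID-III-like composite scores are N(100, 15) truncated to [40, 160] and,
by default, *independent* of GA and of the brain, so outcome-association
stages have a testable null.

**Feature model.** For metric m, parcel p (region r), subject i:

    y = baseline[m][r] + slope[m][r]·(PMA_i − 40) + sex[m]·male_i
        + preterm[m][r]·g(GA_i)·1(preterm_i) + extreme + ε,
    ε ~ N(0, noise_sd[m][r]²),   g(GA) = max(0, 37 − GA)/14.

The prematurity grading g is linear in weeks born early (GA 23 → full
effect, GA ≥ 37 → none): the simplest monotone curve consistent with
graded GA associations, without inventing a published dose–response shape.
PMA is centred at 40 weeks so baselines are interpretable at term.

Default baselines are plausible for the neonatal cortex (thickness 1.1 mm,
FA 0.15, MD 1.2 μm²/ms, ODI 0.30, fICVF 0.50, per-parcel SA 140 mm²,
curvature 0.10, sulcation 0.50); no public per-parcel means/SDs exist for
these metrics at this age, so they are configurable, not calibrated.
Directions of the default age slopes and preterm effects follow the known
regional physiology: FA falls posteriorly with age; MD falls in
central/insular/cingulate cortex; ODI rises widely except the
somatosensory strip; fICVF rises in insula and frontal cortex; thickness
grows everywhere; SA grows everywhere and is much the strongest age signal
(5 mm²/week ≈ 3.6%/week of baseline); sulcation deepens in the cingulate;
curvature is static. Preterm birth raises posterior MD, lowers posterior
fICVF, thickens anterior cortex, and raises FA / lowers ODI in the insula.

**Extreme deviations** are injected per (subject, metric) with probability
0.10 (preterm subjects only, by default), at 1–5 uniformly chosen parcels,
with magnitude uniform in 3.5–6 × the local noise SD and sign matching the
metric's typical preterm direction with probability 0.75 (metrics with no
preterm direction get a random sign). This produces both positive and
negative individual deviations with very little spatial overlap between
infants. Every injection is recorded in a `GroundTruth` mask. FA/ODI/fICVF
are clipped to [0, 1] and MD/thickness/SA floored at ~0 afterwards;
clipping events are counted and logged.

**What the generator does not emulate** — and hence what green tests do
not establish about real data: spatial autocorrelation between parcels
(cells are independent given covariates), non-Gaussian or heteroscedastic
noise, nonlinear developmental trajectories, scanner/site effects,
longitudinal repeats, and any coupling between cortical deviations and
later outcome. Recovery and calibration results certify the *machinery*,
not the biology.

## The normative GP

One GP per (parcel, metric) — 2288 cells at full size — with standardized
PMA and binary sex as inputs and kernel RBF + linear + white noise. The
"multioutput" model is deliberately a bank of independent GPs: Z-scores
are defined per cell and nothing in the analysis requires cross-metric
coregionalization, so independence is the minimal faithful structure.
Outputs are standardized per cell; hyperparameters are therefore
comparable across cells and the jitter floor (1e-8) is relative to unit
output variance.

Hyperparameters maximise the log marginal likelihood via L-BFGS-B on log
parameters, bounded (lengthscale in [0.01, 100] standardized units, noise
in [1e-8, 100]). Multi-start: the first start is fixed (σ_r² = 0.5, ℓ = 1,
σ_l² = 0.5, σ_n² = 0.5), later starts perturb log-normally with the
lengthscale cycling through {0.5, 1, 2}; 5 restarts by default. A constant
output falls back to a noise-only model; a covariance that cannot be
factorised after jitter escalation (1e-8 → 1e-4) flags the cell as failed
and the remaining cells continue. Atypicality denominators always count
such parcels (as normative), keeping the 29/286 worked example exact.

**Predictive variance and calibration.** The posterior variance includes
the white-noise term, so Z-scores refer a *new observation* (not the
latent function) to the norm. Two corrections sit on top of the textbook
formula, both driven by the fact that the noise variance is *estimated*
from finitely many training subjects:

1. *Bias.* The ML noise estimate is biased low by the flexibility of the
   fitted mean, E[σ̂_n²] ≈ σ²(n − ν)/n with ν = n − σ_n² tr(K+σ_n²I)⁻¹ the
   effective degrees of freedom of the GP smoother. The noise term in the
   Z-scoring variance is rescaled by n/(n − ν) (capped at 2 near
   interpolation). Without it, pooled held-out Z variance sits near 1.04.
2. *Tail shape.* Even with an unbiased σ̂, the deviation ratio
   (y − μ̂)/σ̂_pred is Student-t with ≈ n − ν degrees of freedom, whose
   3.1-tail (2·sf_t(3.1, 145) ≈ 2.3e-3) is ~20% heavier than the normal
   1.94e-3 the threshold is meant to encode. Z is therefore defined as the
   quantile transform z = Φ⁻¹(T_df(ratio)) per cell, which is exactly
   standard normal under the model; ratios too extreme for the tail
   computation to resolve pass through unchanged, as do predictive
   distributions constructed without df information (for which Z is the
   plain ratio).

The uncorrected posterior variance is kept alongside
(`PredictiveDistribution.variance`) and is the quantity that matches
closed-form Bayesian linear regression exactly when the kernel is
linear-only — the oracle test in the suite.

**Z sign.** Z = (observed − predicted)/SD: positive Z means the infant
sits above the normative curve, so "extreme positive MD deviation" reads
as elevated MD. A `sign_convention` switch flips it.

**Split.** Term subjects are split 75/25 stratified by PMA quartile
(largest-remainder allocation of the rounded holdout quota), so training
and hold-out age distributions match; one shared split serves both the GP
and the age-prediction stages.

## Permutation inference

Freedman–Lane: the data are residualized against the nuisance columns,
residual rows are permuted, and the full model is refitted; the tested
coefficient's t is computed per cell. Implementation uses the
Frisch–Waugh reduction — only projections onto the residualized tested
column and the nuisance basis change per permutation, so a permutation
costs two thin matrix products. Family-wise error is controlled by the
maximum |t| over all parcels × metrics × contrasts per permutation
(t shares its degrees of freedom across cells, so the max is comparable);
the two one-sided contrasts are read off the single max-|t| distribution.
The identity permutation is included: p = (1 + #{max ≥ t_obs})/(1 + B),
always in (0, 1]. Perfect fits cap |t| at 1e6. Pearson r reported with a
result is the simple bivariate correlation between tested covariate and
feature, as conventionally quoted next to significant parcels.

The group × PMA interaction design centres PMA before forming the product
and treats group, PMA and sex main effects as nuisance. At least 100
permutations are required (the corrected tail is unstable below that).

## Age prediction

Random-forest regression on the flattened parcel × metric matrix with the
tuned hyperparameters as defaults (1000 trees, depth 35, min leaf 2, all
features considered at each split — the historical regression meaning of
"auto"; a hyperparameter search is out of scope, the printed optima are
taken as given). Bias correction fits raw = a + b·true on the *training*
predictions and inverts: corrected = (raw − a)/b; the alternative
orientation (regress true on raw) is available as an option. By algebra,
corrected training predictions regress on true age with slope exactly 1
and intercept 0 — a structural identity the suite asserts at 1e-8.
Importance is impurity-based (training-set), top decile = ceil(0.10 · n
features) with stable-order tie-breaking; for 2288 features the decile is
229.

## Outcome associations

Atypicality indices are percentages with many zeros, so rank statistics
with tie handling are used throughout: Kendall τ-b (exact null for n ≤ 50
without ties, tie-corrected normal approximation otherwise) and two-sided
Mann–Whitney U (scipy's automatic exact/asymptotic choice).
Benjamini–Hochberg FDR is applied per analysis family — the metric ×
index-sign grid within one covariate block (GA separate from each BSID
score), mirroring how such results are reported. All-tied indices are
reported as missing with a reason rather than failing the family.

## Problem sizes used in validation

The self-validation experiments (`corticonorm.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) use scaled problem
sizes chosen to make each check statistically meaningful while keeping a
full run to minutes on one CPU:

- **Z calibration**: 150 training / 50 held-out term subjects, 125 parcels
  per hemisphere → 100,000 pooled cells; GP restarts 2 (the optimum for
  these smooth cells is found reliably; 5 restarts change third decimals).
- **FWER**: 200 replicate null cohorts (28 term + 12 preterm, 20 parcels),
  500 permutations each — the binomial 95% band around 0.05 is ±0.03.
- **Extreme recovery**: 100 + 40 subjects, 60 parcels, every preterm
  subject injected (magnitude 5–6 SD), ~900 injected cells. Group-effect
  detection: a constant 1.5-noise-SD shift added to 20 MD parcels of the
  preterm group (constant, not GA-graded, so the injected size is the
  realised size), 1000 permutations.
- **Interaction null**: 20 replicate cohorts (60 + 30 subjects, 30
  parcels), 500 permutations; extremes disabled so residuals are
  homoscedastic across groups — with them, preterm-only heavy tails are a
  *real* model violation, not a bug in the test.
- **Age prediction**: 120 term subjects, 40 parcels, 300 trees for the
  demo-scale run (defaults unchanged in the API).

## Known limitations

Independent GPs ignore spatial and cross-metric correlation, making joint
max-statistic corrections conservative on real data. No sparse/approximate
GPs: full Cholesky per cell limits training samples to a few hundred.
The Freedman–Lane engine supports a single tested coefficient per run and
no exchangeability blocks, TFCE or cluster statistics. The generator's
linear trajectories make the GP's RBF component nearly idle; on real data
the nonlinear share of developmental change would matter more. Atypicality
indices treat failed-fit parcels as normative, slightly deflating burdens
if fits fail (none do on the default configuration).
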