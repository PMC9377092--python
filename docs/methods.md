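# Methods

## Model and procedure

The package implements the analysis chain of a combinatorial drug-dosing
screen on tumor organoid lines against a non-tumorigenic reference line:

1. **Design** (`qpopkit.design`). Coded dose levels −1/0/+1 map to IC0
   (0 µM, drug absent), IC10 and IC20 of each drug. The composite design
   stacks the L27(3^13) orthogonal array — built as the 27 evaluations of
   13 pairwise-independent linear forms over GF(3)³, recoded so digit 0 is
   the centre level — on a regular two-level fraction from a fixed
   generator table (full factorials for k ≤ 4; e.g. the 128-run
   resolution-VI 2^(9−2) fraction with generators 8 = 13467, 9 = 23567 for
   k = 9). The three-level block identifies the pure-quadratic terms, the
   two-level block the linear and interaction terms; the combined
   second-order model matrix is verified full rank at construction.
2. **Surface and ranking** (`qpopkit.qpop`). Per-run replicate
   viabilities are averaged, differenced into Δ = v_normal − v_tumor, and
   fit by OLS to the full quadratic in the coded levels. Pair scoring
   evaluates the surface only at realizable dose corners {0, 1}² (others
   at −1) because each ranked combination must correspond to platable
   concentrations; a continuous search over [−1, 1]² is available as an
   extension. Ranking ties break lexicographically by drug-name pair so
   cohort frequency counts are deterministic.
3. **Validation** (`qpopkit.chou_talalay`). Median-effect curves for the
   two single agents and for the fixed-ratio combination (on total dose)
   give CI(fa) in the mutually exclusive two-term form, the convention of
   the standard Chou–Talalay/CompuSyn workflow; the non-exclusive third
   term is deliberately not added. DRI is the component-wise isoeffective
   dose ratio, and CI = 1/DRI₁ + 1/DRI₂ holds identically.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| dose anchors | IC0/IC10/IC20 | concentrations at coded levels −1/0/+1, from cohort-level median-effect curves |
| `fa` clipping | 1e−4 | fraction-affected window for the logit transform; points clipped at either end are excluded as uninformative |
| fa grid | 0.05…0.95 step 0.05 | effect levels at which CI/DRI are reported |
| combination ratio | QPOP optimum conc. ratio, normalized to sum 1 | fixed dose ratio for the combination series |
| `backward_eliminate` | off | optional stepwise pruning of quadratic-model terms at α = 0.05 |
| `noise_sd` | 0.05 | additive Gaussian viability noise in the simulator, truncated at 0 |
| plate replicates | 5 | simulated wells per combination, matching n = 5 per treatment in 384-well viability assays |
| `heterogeneity_cv` | 0 | log-normal CV of per-line (Dm, m) jitter around the panel values |
| `normal_resistance` | 5 | fold-increase of the normal line's Dm values |
| `gamma_strength` | 2 | planted pairwise interaction in tumor lines |

## What the simulator emulates — and what it does not

`qpopkit.simulate` generates cohorts with known pharmacology: Hill
single-drug survival, a Bliss-independent baseline, and a planted pairwise
interaction acting through the product of fractional effects
(1−sᵢ)(1−sⱼ), so interactions vanish when either drug is absent — a
requirement for IC0-anchored designs to behave sensibly. Noise is additive
Gaussian on viability truncated at zero (multiplicative noise is not
modelled), and the one normal line is measured once, so its plate noise is
shared by every tumor line's Δ, as with a single control line in a real
screen.

The default cohort is pharmacologically homogeneous: the planted
interaction is then the only systematic between-pair signal, which is the
regime in which recovery checks are well-posed. Enumerating the ground
truth directly shows why: with per-line potency jitter of CV ≳ 0.1 at
shared dose anchors, the jitter itself reorders the true pair ranking line
by line, so no estimator could recover a uniform top pair. Real cohorts
are of course heterogeneous — `heterogeneity_cv` in the 0.2–0.4 range
produces that behaviour, and the frequency/clustering stages are designed
for exactly such variation — but passing recovery tests on the homogeneous
default demonstrates estimator correctness, not robustness to biological
heterogeneity.

The planted-synergy recovery checks are stochastic and pinned to a fixed
seed: the planted effect at IC20 anchors changes corner viability by only
a few percentage points, so at measurement noise σ = 0.05 the per-line
rank-1 count fluctuates between noise realizations and can drop below the
pinned-seed value at other seeds.

## Numerical choices

- The median-effect fit is OLS of log(fa/fu) on log D, pooling replicates
  (not pre-averaging) to preserve error degrees of freedom in r². Doses
  with fa outside (1e−4, 1−1e−4) are excluded; at zero dose fa is exactly
  0 and never enters.
- Because doses far above the IC50 measure mostly noise (viability near
  zero) and destabilize the linearized fit, `ci_dose_ladder` provides the
  standard CI protocol: 2-fold serial dilutions bracketing the expected
  median-effect dose (default 7 doses, Dm/8…8·Dm). The wide screen ladder
  (1e−4…100 µM) remains the default for single-agent IC50 tables via the
  4PL fit, which is robust to the tails.
- Constant outputs make the overall F-test undefined; the fit returns an
  intercept-only surface with adjusted R² = 0 and NaN F statistics rather
  than raising.
- In the coded polynomial the product (−1)·(−1) = +1, so an interaction
  coefficient also contributes at the all-absent corner; pair scores of
  uninvolved pairs can therefore tie with the interacting pair on
  interaction-only toy surfaces. Ties are resolved lexicographically.
- Backward elimination is off by default. On planted-synergy cohorts it
  measurably *hurts* pair recovery: the planted interaction coefficient is
  individually weak (t ≈ 2) and is pruned along with the null terms. It is
  retained as an option for dense-signal surfaces.
- γ-comparison simulations (CI versus interaction strength) share the
  noise stream across arms (common random numbers), so the computed trend
  isolates the interaction effect rather than resampling noise.

## Problem sizes

Tests and the acceptance script run the k = 9, 155-run design with
10-line cohorts and 5 replicates, and dose-response series of 7–9 doses ×
5 replicates; the whole suite completes in a few seconds on one core.

## Known limitations

- Two-level generator tables cover k ≤ 10; larger panels need a supplied
  design (the CSV loader accepts any externally constructed layout).
- Only two-drug combinations are ranked and validated; no ≥3-drug CI.
- The simulator is phenomenological (no PK/PD, growth dynamics, or
  mechanistic resistance), and its interaction multiplier is symmetric in
  the two drugs.
- The 4PL fit bounds viability to [0, 1.5] and flags, rather than models,
  non-monotone (hormetic) responses.
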