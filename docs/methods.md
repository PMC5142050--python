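# Methods

This note documents the models implemented in `shoalresp`, the parameter
choices behind the synthetic-data generator, the numerical conventions, and
what the tests do and do not establish about real data.

## 1. Carbonate system (pH_NBS + TA input pair)

The solver mirrors the classic CO2SYS treatment of this input pair.
Equilibrium constants are evaluated from temperature and salinity at surface
pressure:

| constant | formulation | scale as evaluated |
|---|---|---|
| K₁, K₂ | Mehrbach et al. (1973) refit by Dickson & Millero (1987) | seawater |
| KHSO₄ | Dickson (1990) | free |
| K₀ | Weiss (1974) | — |
| KB | Dickson (1990) | total |
| KW | Millero (1995) | seawater |
| KF | Dickson & Riley (1979) | free |
| total boron | Uppström (1974) | — |
| fH | Takahashi et al. (1982, GEOSECS) | — |

Because pH arrives on the NBS scale, the seawater-scale constants are
multiplied by fH and used directly against the measured hydrogen-ion
*activity* 10^(−pH_NBS); the free hydrogen-ion concentration needed for the
HSO₄⁻/HF terms is a_H/(fH·(1 + S_T/K_S + F_T/K_F)). The alkalinity balance
then yields DIC in closed form:

    DIC = CAlk · (H² + K₁H + K₁K₂) / (K₁(H + 2K₂)),
    CAlk = TA − B(OH)₄⁻ − OH⁻ + H⁺_free + HSO₄⁻ + HF,

and pCO₂ = [CO₂*]/K₀. Nutrients are zero (none are measured in this kind of
field study) and the fugacity correction is off by default (~3 µatm at reef
pCO₂, below the reporting precision); both are exposed as options. A forward
pH-from-(DIC, TA) solve (Brent root-finding on pH ∈ [4, 10]) supports
round-trip validation to 1e-10 pH units. Inputs are validated against
0 < S < 45, 0 < T < 45 °C (warning outside 15–35 °C), 7.0 ≤ pH_NBS ≤ 8.6,
TA > 0.

Reproduction of the six published treatment-water pCO₂ values lands within
−1.6% to +1.7% (see `analysis/01_seawater_chemistry.py`). The residual
scatter is two-sided at near-identical inputs, which no constant choice can
reconcile; it is consistent with the published values having been computed
per water sample and then averaged, whereas this package solves from the
printed mean inputs.

## 2. Respirometry

A trial alternates 540 s sealed measurement with 180 s flushing, sampled
every 2 s. Processing:

1. **Segmentation** is clock-based (the apparatus cycles pumps on a fixed
   timer); the first 60 s of each measurement phase are discarded as
   flush-to-seal re-equilibration (configurable; a detection-style QC check
   that windows avoid flush samples is part of the test suite).
2. **Slope fitting** is ordinary least squares of O₂ (mg/L) on time,
   rescaled to mg O₂ L⁻¹ h⁻¹, with r² reported. Fits with r² < 0.9
   (configurable) are excluded as mixing faults, except exact-zero slopes
   (r² undefined) which are kept.
3. **Conversion**: ṀO₂ = |slope| × V_eff where
   V_eff = chamber volume (0.100 L) − fish mass / (1000 × 1 g/ml). The
   body-volume subtraction is conventional (≈1.3% at the mean mass) and can
   be disabled. Oxygen-increasing slopes are flagged and excluded.
4. **Background correction**: microbial respiration is measured in empty
   chambers for three phases before and after each trial; the mean pre and
   post slopes anchor a linear-in-time background whose interpolated value ×
   V_eff is subtracted from every record. Negative corrected values are
   floored at zero and flagged.

## 3. Metabolic statistics

* **MR_min**: mean of the lowest ⌈n/10⌉ ṀO₂ values over all measurements
  (the convention of the SMR-quantification literature; a pure 10% quantile
  is available as an option). The first 5 h are *included*, following the
  protocol's "all measurements" definition — a flag excludes them if wanted.
* **RMR**: arithmetic mean of records with phase midpoints after the first
  5 h (the habituation window the pilot work identified).
* **FS**: the first valid post-transfer phase's ṀO₂.
* **MMR**: maximum ṀO₂ over consecutive non-overlapping 180 s windows of
  the chase-recovery trace (rolling windows available). Note the windowed
  statistic estimates the *first-window mean* of a decaying recovery curve,
  which sits below the instantaneous peak by the closed-form factor
  (τ/w)(1 − e^(−w/τ)).
* **AS** = MMR − MR_min (exact identity, enforced);
  **ISR** = (FS − MR_min)/AS, reported unclamped with an out-of-range flag.
* **Calming effect** = 100 × (MR_min,alone − MR_min,group)/MR_min,alone;
  increases under group testing are negative by this sign convention.
* **Mass correction** (figures only, never inference): residuals of
  log₁₀(rate) on log₁₀(mass) added to the fitted value at the 1.29 g
  reference mass, exponentiated back. Statistical models always use
  whole-animal rates with mass as a covariate.

## 4. Choice-trial scoring

The arena is 90 × 30 cm with a stimulus container (radius 5 cm) centred 6 cm
from each end wall. The association zone is all points within two body
lengths of the container's outer wall, i.e. a circle of radius
5 + 2 × SL cm about its centre (SL = per-fish standard length; 3.22 cm
default). Membership is evaluated per sample in 2-D at the trajectory's
native rate; time in zone weights samples by their sampling interval. A
visit is an entry event into either zone (an optional 2-sample debounce
mimics human video scoring); the initial choice is the first zone entered;
a trial is *informed* only if both zones were entered, otherwise the fish is
listed for retest — no imputation. Scoring is exactly conservative
(prop_familiar + prop_unfamiliar + prop_neutral = 1) and invariant to
mirroring the arena together with the familiar-side label.

The preference analysed against the 0.5 null is the familiar share of
*shoaling* time, prop_familiar/(prop_familiar + prop_unfamiliar): the
whole-trial fractions also contain neutral time, under which a 0.5 null
would be incoherent.

## 5. Inference

* **Preference deviation test** (per CO₂ treatment): response is
  preference − 0.5; intercept-only LMM with a random shoal intercept. For
  the balanced design (2 focal fish per shoal) the containment-df F test of
  the intercept is exactly the one-sample t-test on shoal means, which is
  what the implementation computes — it is exact under the random-intercept
  model at any intraclass correlation. Singular grouping (one fish per
  shoal) falls back to a one-sample t-test over fish, logged.
* **Initial choice**: binomial GEE with exchangeable within-shoal
  correlation; the CO₂ effect is a 2-df Wald χ² using the model-based
  covariance (with ~9 clusters per treatment the sandwich estimator is too
  unstable, and it is exactly singular on balanced data). Complete
  separation triggers a Haldane–Anscombe 0.5-pseudo-count refit with a
  warning.
* **Metabolic endpoints** (MR_min, RMR, ISR, activity): Gaussian mixed
  model, endpoint ~ CO₂ × testing + mass with a random intercept per fish
  (REML); marginal Wald F per term. Denominator df use the containment
  convention — between-fish terms (CO₂, mass): n_fish − rank(between
  design) = 26 at the study's n = 30; within-fish terms (testing,
  interaction): n_obs − n_fish − rank(within design) = 27. The convention
  is recorded in every output row. Fish missing a testing treatment are
  dropped and logged.
* **MMR and AS** (one value per fish): Gaussian fixed-effects model
  (CO₂ + mass) with type-II F tests.
* **Tukey contrasts**: all three pairwise CO₂ contrasts on estimated
  marginal means (mass at its mean, averaged over testing), with
  studentized-range family-wise adjustment; adjusted p ≥ raw p always.

Under permutation-style nulls the preference test and the mixed model's
testing effect hold their nominal 5% size (measured 0.037 and ~0.05 over
1000 replicates each; see the test suite).

## 6. Synthetic-data generator

The generator's defaults are the study conditions; they are fixed, not
tuning knobs.

| parameter | default | rationale |
|---|---|---|
| mass | N(1.29, 0.22²) g | study mean; SD = SEM 0.04 × √30 |
| standard length | N(3.22, 0.16²) cm | same construction |
| allometry | SMR = 0.49·m^0.8 mg O₂/h | gives ≈0.60 mg O₂/h at 1.29 g; b = 0.8 is the canonical teleost exponent |
| between-fish SMR scatter | lognormal, CV 0.15 | positivity; typical inter-individual spread |
| stress elevation | ṀO₂ × (1 + 1.0·e^(−t/1.5 h)) | decays to ~3% by the 5 h stabilization the pilot observed; exponential is the simplest monotone form |
| calming multiplier | 0.772 on group trials | the observed 22.8% mean MR_min reduction |
| aerobic scope multiplier | MMR = 3 × SMR | mid-range factorial scope for small tropical teleosts |
| recovery decay | τ = 600 s toward SMR | post-chase recovery on the minutes scale |
| background drift | 0.005 + 0.002/h mg O₂ L⁻¹ h⁻¹ | small linear microbial growth |
| sensor noise | N(0, 0.01²) mg/L per sample | optode-grade noise |
| trial length | U(17, 19) h; flush reset τ = 30 s | protocol |
| choice p_familiar | 0.65 / 0.50 / 0.50 (control/mid/high) | preference present only at ambient CO₂, mirroring the observed pattern |
| between-shoal spread | SD 0.25 on logit p | modest clustering so the shoal random effect is real |
| uninformed probability | 0.22 | observed retest incidence |
| sojourn / transit means | Exp(14 s) / Exp(6 s) | calibrated once to the observed 44.7 mean visits per 900 s trial (and spanning the 2–133 range) |
| activity | lognormal, mean 9.5 turns/min, CV 0.6 | observed daylight activity |

Oxygen traces integrate the true instantaneous uptake exactly (closed form)
within each sealed phase, so with noise, stress and drift set to zero every
phase slope equals −SMR/V_eff to floating point — the generator-recovery
tests exploit this limit. Chase recoveries are truncated where O₂ would
cross the 2 mg/L floor, as the protocol capped sealed time to keep
saturation high. Choice trials draw an explicit uninformed flag
(single-zone sampling); informed trials that happen to draw one zone only
have one visit flipped so the informed-choice guarantee holds, and retests
re-run with fresh seeds (the final permitted attempt is forced informed,
mirroring retest-until-informed). Determinism is strict: a master seed fans
out per-fish, per-purpose child seeds via `numpy.random.SeedSequence`.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: activity-driven within-trial ṀO₂
fluctuations beyond the stress decay (real traces are burstier, so real
MR_min estimators face more selection bias than measured here); optode
drift and temperature transients; partial chamber mixing (slopes are exactly
linear within a phase up to noise); spatial behaviour richer than the
two-state sojourn model (thigmotaxis, freezing); and any between-day retest
carry-over. Estimator-recovery results (MR_min within 0.4%, RMR within
0.1%, calming within ±0.1 points of the programmed 22.8%) are therefore
upper bounds on real-data performance, not field accuracy claims.

## 7. Numerical conventions and degenerate inputs

* Uptake sign: concentrations fall during measurement; ṀO₂ is stored
  positive. Positive (oxygen-increasing) slopes flag the record.
* Alkalinity solve tolerance: closed form (exact); the forward pH solve
  brackets on [4, 10] with xtol 1e-12. Non-positive implied carbonate
  alkalinity is a domain error.
* MR_min needs ≥ 10 valid records; RMR needs records after the exclusion
  window; MMR needs at least one full 180 s window — each raises an
  insufficient-data error otherwise.
* Zero-variance endpoints in the fixed-effect model return a degenerate-fit
  notice instead of an F statistic; zero-SE contrasts report p = 1.
* Ties/short blips in zone scoring: membership is per sample; the optional
  debounce suppresses sub-threshold residence; direct zone-to-zone teleports
  (possible only in synthetic paths) count as a single entry.

## 8. Known limitations

* The published seawater table is matched to ~1.7%, not arbitrarily closely
  (see §1); the exact averaging behind the printed values is not
  recoverable.
* Mixed-model denominator df follow one declared convention; other software
  prints slightly different df for the same design, so F statistics are
  comparable only qualitatively.
* The binomial choice model is a marginal (GEE) analog of a random-intercept
  logistic model, not a likelihood GLMM.
* MMR from 3-min windows estimates the first-window mean of the recovery
  curve; comparisons across studies with different window lengths or decay
  rates need the closed-form bias factor in §3.
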