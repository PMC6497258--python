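# Methods

## Scope and conventions

`gestphys` models an *average* healthy mother and singleton fetus. The
independent variable everywhere is gestational age *t* in weeks (time since
the last menstrual period); fetal age is gestational age minus exactly
2 weeks, and `convert_age` performs that shift. Conception is therefore at
*t* = 2, and no fetal quantity or product of conception (placenta, amniotic
fluid) is meaningful before that. The nominal domain is 0–42 weeks with
"term" fixed at 40 weeks.

Units are native to each quantity and never converted implicitly: maternal
volumes in L, conceptus volumes in mL, maternal flows in L/h, fetal masses in
g, fetal volumes in mL, fetal flows in mL/min, hematocrits in percent, GFR in
mL/min. A helper (`ml_per_min_to_l_per_h`, factor 0.06) exists but must be
called explicitly. The fetal whole-body density is taken as 1 g/mL, so fetal
mass and volume share one curve.

## Model families

Fourteen candidate forms cover the shapes seen in gestational data:
polynomials of degree 1–3, with "growth" variants lacking an intercept
(used when the quantity must vanish at *t* = 0, e.g. fetal hematocrit);
the Gompertz sigmoid y = θ₀·exp[(θ₁/θ₂)(1 − e^(−θ₂t))] with asymptote
θ₀·e^(θ₁/θ₂); the logistic y = θ₀/(1 + e^(−θ₁(t−θ₂))); allometric power laws
y = θ₀x^θ₁ and the two-exponent form y = θ₀x^(θ₁+θ₂·ln x) on a body-mass
covariate; and "modified" variants of the sigmoids and power laws that add a
baseline offset θ for quantities that start well above zero.

Numerical choices:

- The logistic is evaluated in a sign-split form so exponents beyond ±700 do
  not overflow; user-supplied θ can otherwise push the screen grid into
  overflow even though the shipped parameterisations cannot.
- The Gompertz bracket uses `expm1`, which keeps the θ₂ → 0 limit (pure
  exponential growth θ₀e^(θ₁t)) accurate to ~10⁻⁴ relative at θ₂ = 10⁻⁸.
- Power laws at x = 0 take their continuity extension (0 for a positive
  exponent, plus any offset); a negative or log-divergent exponent at x ≤ 0
  raises a domain error instead of returning NaN.

## Maternal models

The preferred forms are fixed closed-form fits: maternal mass a cubic
(61.103 kg at conception, conceptus included), adipose mass linear
(17.067 kg + 0.14937 kg/week, i.e. 27.9% of body mass at conception), plasma
volume a modified logistic rising to an asymptote of 3.7364 L, hematocrit a
gently falling quadratic (39.192% at conception), cardiac output a cubic
(301.78 L/h at conception), kidney flow a cubic, GFR a quadratic, placenta
volume a cubic growth curve (positive only above ~1.97 weeks) and amniotic
fluid a logistic.

Red-cell volume is derived from hematocrit by default,
V_rbc = H/(1−H)·V_plas, which keeps plasma, RBC and hematocrit mutually
consistent to machine precision; the independently fitted modified-logistic
RBC curve remains available (`rbc_method="modified_logistic"`). The two
differ by up to ~0.2 L around 30 weeks.

Organ flows without time-course data are *linear transition* models: a
percentage of cardiac output interpolated linearly between the non-pregnant
and 40-week reference shares (adipose 8.5→7.8, brain 12.0→8.8, kidneys
17.0→16.6, gut 17.0→12.5, liver 27.0→20.0, thyroid 1.5→1.1, uteroplacental
0.4→12.0). Kidney flow prefers its direct cubic fit. Placental flow is zero
before 3.6 weeks (establishment of the uteroplacental circulation), then
proportional to placenta volume with constant 0.059176 L/h per mL, anchored
to 39 L/h at term; the ramped uteroplacental transition variant is retained
for comparison but underpredicts near term (37.0 vs 39.0 L/h at 40 weeks).

Static compartment volumes (brain, thyroid, kidneys, gut, liver, lungs) are
the non-pregnant body mass times female reference mass percentages divided by
tissue density. Rest-of-body volume is a mass balance: fat-free volume
(density 1.1 kg/L, with the conceptus mass subtracted from 2 weeks onward —
the jump introduced at *t* = 2 by switching the balance on is below 0.01 L)
minus plasma, RBC and the six static volumes. By default the balance uses the
modified-logistic RBC curve; the hematocrit-consistent choice moves the
result by at most ~0.3 L and keeps it within the same 31–34 L band.
Rest-of-body flow is cardiac output minus the seven named flows, so flow
conservation holds by construction.

## Fetal models

Total fetal mass is a Gompertz curve (θ₀ = 0.0018282 g — the model's nominal
"mass" at *t* = 0, not a biological claim). Organ masses are Gompertz curves
screened for positivity; for brain and liver the raw AIC winners were cubic
growth curves that dip negative in early gestation and are kept only as
`variant="lowest_aic"`. For the kidneys the best fit is a power law on fetal
mass and the Gompertz is a near-indistinguishable age-based alternative
(both ≈27 g at term, within 2%); the typeset equations for the kidney models
contain internally inconsistent constants, so the MLE-table values are used
and the literal typeset constants sit behind `as_printed=True`. Organ
volumes divide mass by tissue density (brain 1.04, gut 1.045, others
1.05 g/mL).

Measured flows are logistic fits to Doppler data: right ventricle
(asymptote 2466.5 mL/min, midpoint 43.1 weeks), left ventricle (506.3,
30.2 wk), ductus arteriosus (1125.3, 35.9 wk), umbilical/placental flow
(262.2, 28.8 wk); ductus venosus flow is a slow Gompertz. Derived flows
follow from conservation (see README equations), so the shunt identities are
exact. Organ flows split the non-placental arterial flow in fixed measured
proportions (gut 6.8, kidneys 5.4, brain 14.3, all over 75); liver and
thyroid take adult shares (6.5/54 and 1.5/54) of what remains after
gut+kidneys+brain (26.5/75). Rest-of-body volume and flow are the mass/flow
balances over these components.

Validity flags rather than hard errors mark the limits: everything fetal is
`pre_conception` below 2 weeks; conceptus volume curves are `extrapolated`
below 9 weeks (first calibration observation); fetal flows and rest-of-body
composites are `pre_recommended` below 13 weeks because first-trimester data
are sparse — the rest-of-body volume balance is in fact negative until about
8 weeks, and the DV < placental-flow ordering required by anatomy holds only
above 12 weeks. Strict table evaluation blanks flagged cells; the default
returns raw values plus flags so full-domain tables remain exportable.

## Calibration and selection

Inputs are summary records (covariate, mean, SD, n). Records missing SD or n
(typical of figure-digitised observations) are imputed with a 20%
coefficient of variation and n = 1; a zero mean with missing SD is rejected
as degenerate. Each record contributes a Gaussian likelihood with model mean
y(x; θ) and *known* variance s²; summing sufficient-statistic terms gives

ℓ(θ) = Σᵢ [ −(nᵢ/2)·log(2π sᵢ²) − ((nᵢ−1)sᵢ² + nᵢ(mᵢ − y(xᵢ; θ))²)/(2 sᵢ²) ]

so maximising ℓ is weighted least squares with weights nᵢ/sᵢ², |ℓ| scales
with the number of subjects, and the θ-independent terms cannot move the
argmax (a property the tests assert). The variance is treated as known
rather than as a nuisance parameter: it makes the MLE a convex weighted
regression for linear-in-θ families and matches how per-point dispersion is
usually reported in curated gestational datasets.

Fitting is multi-start local optimisation: a family-specific heuristic
initialisation (exact weighted least squares for polynomials; asymptote/
half-max readings for sigmoids; log-log regression for power laws) plus
seeded Gaussian jitters of it (default 20 starts), each run through
Nelder-Mead and polished with L-BFGS-B. Everything is deterministic given
the seed; failure to converge is reported on the result, never silent.

AIC = 2k − 2ℓ(θ̂) exactly (asserted in the result constructor). The
*preferred* model is the lowest-AIC candidate whose predictions are
nonnegative on an inclusive screen grid, default 0–42 weeks at 0.1-week
steps — fine enough to resolve the known negativity crossings at ~1.97, ~8
and ~12 weeks; body-mass-covariate candidates are screened through the
age → fetal-mass composition so all candidates face the same age window.
AIC gaps below 0.1 are treated as ties, broken toward nonnegativity, then
fewer parameters, then an age-based covariate (which avoids an intermediate
body-mass model at evaluation time). No comparison against externally
published model repositories is performed, and no AICc/BIC or parameter
uncertainty is computed.

## Synthetic data

The generator emulates curated summary-data structure, not any real cohort.
The default design is 16 ages (10–40 weeks, step 2), 25 subjects per age and
a 10% coefficient of variation, chosen to resemble the visible spread of
curated gestational datasets; the digitised style draws one observation per
age with SD and n omitted so the downstream 20%-CV imputation applies. Noise
is Gaussian on the natural scale (the likelihood is Gaussian), with an
optional truncation at zero for early-gestation designs. What passing
recovery tests show is that the estimator and selector behave correctly
under the stated sampling model; they say nothing about inter-study
heterogeneity, non-Gaussian measurement error, or covariate error in real
curated data. A sigmoid midpoint outside the sampled age window (as with the
right-ventricle curve, midpoint ~43 weeks) is weakly identified from sparse
noisy data, and recovery claims are only made for midpoints inside the
window.

## Problem sizes used in tests and reproduction

Grid scans use the inclusive 0.1-week grid (421 points on 0–42 weeks, 401 on
0–40). Stochastic recovery checks use 50 replicate seeds at the default
design for the headline Gompertz-recovery property, 20 seeds for the
digitised-midpoint property and 5 seeds per sample size for the
consistency-with-n property. The brute-force selection oracle uses a
201×201 parameter grid around the truth for a two-parameter family on five
summary points.

## Known limitations

No placental active transport, no population variability (an average
mother-fetus pair only), no serum-protein or tissue-composition models, no
late-pregnancy plasma-volume decline or hematocrit rise (the aggregated
calibration data do not show them even though longitudinal studies do), and
validity below 13 weeks for fetal composites is nominal only. The repository
describes healthy singleton pregnancies from predominantly Caucasian study
populations and a human mother-fetus pair exclusively.
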