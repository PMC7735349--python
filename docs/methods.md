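# Methods

## Isotope washout and dilution space

A subject dosed with ²H₂O equilibrates the label with its body water pool;
enrichment then declines as water is turned over. With a single
well-mixed pool and first-order exchange, excess enrichment above the
pre-dose baseline follows E(t) = E₀·exp(−k_d·t). We fit
ln(E(t) − baseline) against time since dose by OLS (the slope-intercept
method): k_d is the negated slope (units d⁻¹, hence natural log rather
than log₁₀), E₀ the exponentiated intercept. Two points define the line
exactly (R² reported as 1); a configurable equilibration guard can drop
samples earlier than a chosen time after dosing, but the default keeps
everything since first draws in the emulated design occur ≈24 h post-dose
when mixing is complete.

Total body water comes from an exact atom balance rather than an
approximate enrichment ratio: a dose of mass d grams at purity p
(fraction of molecules that are ²H₂O, remainder treated as ordinary
water; molecular masses 20.0276 and 18.0153 g mol⁻¹) carries
2pd/M_dose moles of ²H. Mixing into V litres of water (density
1.000 kg L⁻¹) at the baseline atom fraction and equating the resulting
excess atom fraction to E₀ yields a closed form for V that the package
also runs forward (the generator uses the forward form, the analysis the
inverse, so round-trip identity is a real cross-check, not a tautology).
Enrichment is standardized as ppm ²H of total hydrogen (atom
fraction × 10⁶; natural background ≈155.76 ppm). Any linear unit works if
dose purity, baseline and fit share it and the matching
atom-fraction-per-unit factor is supplied; the dilution space is invariant
under such rescaling and all reported quantities are unit-independent.

QC: post-dose samples at or below baseline signal an uningested or
partial dose and abort that subject-period with a flagged-sample error;
fits with R² below 0.99 (default, configurable; chosen because clean
washout series in this design sit in 0.990–1.000) are reported with
`qc_pass=False` and excluded from downstream composition, never silently
dropped.

## Body composition

FFM = TBW / h with hydration ratio h = 0.746 by default (cross-mammal
mean of TBW:FFM; 0.730 is the common alternative), FM = mass − FFM.
Because live animals carry gut contents hydrated at 80–90 % water versus
the ≈74.6 % assumed for lean tissue, dilution-based FFM is biased upward
by mass × gut_fraction × (gut_hydration − h)/h kilograms, with fat
underestimated by the same amount; the package reports this
first-principles bias for caller-supplied gut parameters rather than a
fixed percentage range, because no single consistent denominator
reproduces commonly quoted summary ranges from their own stated inputs.
Mildly negative fat mass is retained and flagged (it is informative about
measurement error near very low adiposity); fat percent below −5 % raises
a hard QC error since it implies a failed dose or assay. Report output
rounds masses to 1 kg and fat percent to integers; full precision is kept
internally.

## Water budget and temperature model

Daily turnover is r = k_d·TBW (L d⁻¹), also expressed as % of TBW per
day. Weather is aggregated over a 10-calendar-day window starting at and
including the dose day (inclusivity is a package convention): means of
daily mean/max/min temperature and dewpoint, summed precipitation;
missing days are an error listing the gaps.

The temperature response is modelled as ln r ~ z(mass) + z(temperature)
with a subject random intercept, fitted by REML (statsmodels MixedLM).
z-scores use the observation-level mean and SD over all included
subject-periods (global standardization), stored with the fit so
predictions are reproducible. The mass×temperature interaction is fitted
first and dropped when its Wald p ≥ 0.05. Natural log makes coefficients
read as proportional effects per SD of the predictor. Random slopes are
not fitted — identity enters only as an intercept. Optimizer fallback
(lbfgs → powell → nm → bfgs) handles variance components at the zero
boundary. Published coefficient values from any particular cohort require
that cohort's per-period data; the model is validated instead by
parameter recovery: across 200 synthetic cohorts of 20 subjects × 6
periods the 95 % Wald CI covers the generating temperature coefficient in
≥90 % of replicates (the sizes were chosen to make the check precise at
desk scale).

The drinking-interval bound is critical_fraction × mass / net_daily_loss
days. Net loss is deliberately the caller's input: gross turnover
includes preformed and metabolic water gained without drinking, so
feeding gross turnover here gives a conservative (short) interval.

## Allometry

OLS of log₁₀ turnover on log₁₀ mass across terrestrial eutherian mammals;
bats, aquatic mammals, marsupials, and records taken during seasons of
energy stress are excluded, with per-record retention decisions loggable.
Multiple records per species (e.g. horse breeds of different mass) enter
as separate rows. Literature compilations are not redistributed with the
package; a synthetic power-law table generator provides self-contained
fixtures, and a loader reads user-supplied species CSVs. Focal deviation
is 100·(observed/predicted − 1) %.

## Synthetic cohorts

The generator emulates the longitudinal zoo-cohort design and is the
ground truth for every downstream test. Defaults are the study conditions: 5
subjects (40 % male), 6 semi-annual periods, 5 post-dose samples at
nominal days 2–10, doses of 0.04 g kg⁻¹ at 99.8 % purity, baseline
155.76 ppm, enrichment noise CV 0.002. Subject physiology: male masses
uniform on 5200–5900 kg, female 2500–4500 kg (drawn at 0.1 kg scale
precision so written tables reproduce the truth exactly), fat fraction
uniform on 0.05–0.15, base k_d uniform on 0.08–0.13 d⁻¹, gut fill
0.07–0.17 at 0.80–0.90 hydration — ranges matching what is reported for
adult zoo elephants. TBW is exactly h·FFM; the initial excess enrichment
is computed by the forward mixing balance, so zero-noise cohorts are
recovered to machine precision.

Sampling-time jitter is log-normal in minutes (median 40, log-SD 1,
random sign), which reproduces the reported median and a ~1–327 min span
of absolute deviations from 24 h multiples. Enrichment noise is
multiplicative log-normal on the excess (analyzer error scales with
signal); the pre-dose baseline sample reads the baseline exactly.
Temperature forcing: period target temperatures alternate between the
cool and warm halves of 6–24 °C (semi-annual seasonality), daily means
scatter about the target (SD 1.5 °C), and the effective rate constant is
k_eff = k_d·exp(β_T·(T̄ − T_ref)) with β_T = 0.02 °C⁻¹ by default
(consistent with turnover rising ≈1 % of TBW per 4 °C) and T_ref the
midpoint of the configured range, keeping k_d interpretable as the
mid-season rate.

What the generator does not emulate: body-mass change within subjects
across periods, behaviour and diet composition, isotope fractionation,
multi-pool kinetics, dose failures (tests inject those explicitly), and
correlated weather beyond the window scale. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to physiological model violations in real animals.

## Cohort statistics

Group summaries are mean ± SD of subject means (n = subjects, SD with
n−1). Paired first/last t-tests take each subject's chronologically first
and last available (QC-passing) measurements; zero-variance non-zero
differences raise an error rather than report an unbounded statistic.
Pearson correlations are offered pooled (df = n−2) and within subject;
t = r·√(df/(1−r²)). The time-of-day check is a fixed-effects two-way
ANOVA (time of day × identity with interaction), used as QC on dosing
practice. All of these are asserted against hand-rolled textbook
formulas to 1e-10 in the test suite. Note that pooling subject means
rather than all periods changes some group SDs at the integer level;
the package consistently uses subject means.

## Numerical and interface choices

CSV with documented headers is the interchange format (small tabular
series; no domain standard applies): ISO-8601 timestamps, UTF-8, decimal
point, canonical float formatting so rewritten tables round-trip
bit-identically. The CLI (`deutwater`) wraps the library thinly:
`simulate`, `fit`, `compose`, `budget`, `allometry`, `report`; the three
stage subcommands share one pipeline computation and point at their
stage's output file. Configuration is a flat key-value YAML with unknown
keys warned about, mirrored by flags; a run log records versions, seed,
and every QC exclusion.

## Limitations

Single-pool, first-order kinetics only (no plateau or two-pool methods,
no fractionation corrections). The hydration ratio is borrowed from a
cross-species mean, not measured for elephants; the sensitivity operation
quantifies but cannot remove that uncertainty. The drinking-interval
calculation is a bound, not a behavioural prediction. The mixed model
assumes Gaussian errors on the log scale and a common temperature slope
across subjects.
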