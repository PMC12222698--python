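# Methods

This note documents the models, conventions and design choices behind
`indoair`, in the order the pipeline runs them.

## Concentration statistics

A `ConcentrationSeries` holds one (site, environment, pollutant) series in
µg/m³ with strictly increasing timestamps and non-negative values.
Summaries use the arithmetic mean, the sample (n−1) standard deviation, and
quartiles by linear interpolation between order statistics (the "type 7"
convention); this choice makes the Tukey-fence outlier rule
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] deterministic and testable by hand. The modal
bin is the most populated of `bin_count` (default 10) equal-width histogram
bins over [min, max]; the bin rule is a coarse, assumption-light
characterisation, not a density estimate.

Pearson correlations carry t-distribution p-values; `tail="one"` halves the
two-sided p, i.e. tests in the direction of the observed sign — used for
the questionnaire screening where the question is directional.
Size-resolved correlation joins spectrum and BC series by exact timestamp
match (inner join, no interpolation — instruments on a shared clock either
align or the sample is dropped and counted).

Distribution-shape selection fits normal and lognormal candidates by
maximum likelihood and picks the higher log-likelihood; with equal
parameter counts this is AIC selection. The lognormal candidate is marked
infeasible when any value is non-positive.

The annual projection C₄ = C₁·C₂/C₃ assumes the indoor/ambient ratio
observed during the campaign holds year-round — reasonable when the indoor
source profile is dominated by penetration from outside, questionable when
indoor sources are episodic.

## Deterministic risk

The intake chain is the USEPA inhalation model. One unit convention
deserves a paragraph because it is easy to get wrong: exposure-factor
handbooks tabulate inhalation rates **per day** (m³/day) while the intake
equation wants an hourly rate multiplied by exposed hours. `indoair`
prorates the daily rate (IR/24 per exposed hour) inside CDI, but uses the
daily rate unmodified in RfD = RfC·IR/BW — the reference dose converts a
whole-day air-concentration ceiling into a whole-day intake ceiling. Under
AT = ED (the non-carcinogenic convention) IR and BW then cancel in
HQ = CDI/RfD, leaving HQ = (CA/RfC)·(ET/24)·(EF/365), identical for every
cohort; the carcinogenic branch (AT = 70 y) retains the IR/BW dependence,
so LCR ranks cohorts by IR/BW. Both facts are asserted in tests.

Defaults: worker shift ET 8 h/day, EF 313 d/y, ED 35 y; year length 365 d;
ten cohorts (five upper-exclusive age bands × two sexes) with handbook mean
inhalation rates and body weights. The guideline registry ships the Indian
NAAQS (CPCB) 24-h and annual PM limits, the WHO 24-h and annual limits, and
the OSHA/NIOSH 8-h elemental-carbon limit (3.5 mg/m³); all overridable.

Black carbon's carcinogenic assessment applies to its fine (< 2.5 µm)
fraction, taken as 2/3 of the total BC mass (a config scalar) — the size
range that penetrates to the alveoli and the range for which the
diesel-exhaust slope factor (1.1 per mg/kg·day) is borrowed. Risk classes:
LCR < 10⁻⁶ negligible, 10⁻⁶–10⁻⁴ considerable, ≥ 10⁻⁴ high; HQ or HI > 1
flags a significant non-carcinogenic threat.

## Monte Carlo risk

Every variable draws through its quantile function from a shared uniform
stream (sorted variable order, one `numpy` Generator seeded from the run
seed), which makes runs bit-reproducible and lets antithetic pairing work
uniformly across families. Lognormal distributions are parameterised by
natural-scale moment matching (σ² = ln(1 + cv²), µ = ln m − σ²/2); normal
draws are truncated to [max(0, m − 4s), m + 4s] — physiology cannot be
negative — and the truncated probability mass is reported on the result.
Inputs are sampled independently (no input correlation is modelled).

The default spreads are the package's own, chosen as realistic occupational
variability where the campaign design fixes only the means: CA lognormal at
the observed series mean/sd; IR and BW normal with 10% CV; ET uniform
7–9 h around the shift; EF triangular 280/313/346 d/y; ED uniform 25–45 y;
RfD a point (a regulatory constant). Because 1/BW is convex, the Monte
Carlo mean sits slightly above the deterministic value (Jensen); at the
default spreads the gap stays under 2%, and it vanishes as spreads → 0
(both tested). The percent difference between approaches is reported
relative to the probabilistic mean.

Sensitivity uses rank-correlation contribution-to-variance: for each
varying input, sign(ρ)·ρ²/Σρ²·100 with ρ the Spearman correlation against
the target sample. It is a global, monotonic-association measure — adequate
here because the chain is a product of positive factors (monotone in every
input) — and the signed contributions' absolute values sum to 100 by
construction. Exact percentages depend on the configured spreads; the
robust qualitative pattern is concentration dominant, body weight the only
negative contributor. A stepwise-regression alternative was considered and
not implemented; for a monotone product chain it adds nothing.

## Spirometry

Predicted FVC/FEV1/PEFR come from linear sex-specific equations
a·height + b·age + c; the shipped coefficient table is the standard
published ECSC/Quanjer-1993 adult summary set, and any coefficient table
can be supplied via the equation-set registry. Session handling follows
field practice: per-metric maxima across up to three manoeuvres (the
composite may mix manoeuvres), with the ATS repeatability flag raised when
the two best FEV1 values differ by more than 5% of the larger.

Boundary conventions, fixed and grid-tested: FEV1/FVC exactly 70% is *not*
obstructive and FVC exactly 80% predicted is *not* restrictive (strict
inequalities); PEFR exactly 80% of predicted falls in the *mild* asthma
band ("exceeds 80%" is required for no symptoms, and the 50–80% band is
read inclusive). The pattern axis and the asthma axis are independent
screenings; "healthy" in the prevalence table means normal pattern *and* no
asthma symptoms, so the per-axis percentages need not sum to 100 across a
combined report. All outputs are screening labels, not diagnoses.

## Synthetic data

The concentration generator is a Gaussian copula: configured pairwise rank
correlations are mapped to latent Gaussian correlations by the sine
transform 2·sin(πr/6), a latent multivariate normal is drawn (optionally
AR(1) in time; off by default since the emulated campaign data carry no
stated autocorrelation), and coordinates pass through normal or lognormal
marginal quantile functions. Default marginals and correlation targets are
calibrated to an 8-hour industrial campaign: indoor PM10 131.29 ± 12.35,
PM2.5 54.51 ± 1.91, PM1 35.83 ± 3.27 (lognormal), BC 2.94 ± 0.93 µg/m³;
outdoor 115.86 ± 21.87, 52.12 ± 4.98, 39.28 ± 5.90, 3.76 ± 1.04; r targets
include PM10–PM2.5 0.77 indoor / 0.68 outdoor, BC–PM2.5 0.92 indoor and
BC indoor–outdoor 0.52. Cross-environment entries not directly targeted
follow a conditional-independence rule (outdoor pollutants couple to other
indoor series only through their indoor twin), which keeps the default
matrix positive semi-definite; user matrices are validated and rejected
with a nearest-PSD suggestion otherwise.

The 31-channel spectrum distributes each time step's PM1 / PM2.5−PM1 /
PM10−PM2.5 mass (plus a coarse 15% of PM10 above 10 µm) over GRIMM-style
channels with jittered lognormal weights renormalised per size group, so
channel aggregates reproduce the bulk series exactly (tolerance 1e−9) and
sub-micron channels inherit the planted BC correlation. Number
concentrations are derived assuming unit-density spheres at the channel
mid-diameter — a crude but monotone transform sufficient for correlation
structure, not for instrument realism.

The cohort generator plants a ventilatory pattern and an asthma band per
subject (largest-remainder allocation, so realised counts match configured
prevalences exactly; defaults 53.27/4.34/42.39/0% patterns,
46.74/42.61/10.65% asthma bands over 184 subjects), then draws the observed
percentages uniformly inside the label's region of the threshold plane
excluding a δ margin (default 5 points, minimum feasible > 0, maximum < 15
or the mild-asthma band empties). Percentages are converted to litres via
the reference equations and emitted as triplicates jittered ≤ 2% below the
best manoeuvre — classification therefore recovers 100% of planted labels
for any δ ≥ 1 point, the core testable property of the screening stage.
The questionnaire generator plants binary–binary (phi) associations through
the exact 2×2 cell construction p₁₁ = p_b·p_f + r·√(p_b q_b p_f q_f).

What the generators deliberately do not emulate: instrument noise spectra
of specific devices, meteorology-driven diurnal structure, correlated risk
variables, and the covariance between lung function and measured exposure.
Passing tests therefore demonstrate correctness of the statistical
machinery on data with known structure, not epidemiological validity on
real campaigns.

## Problem sizes and numerics

Default problem sizes — 4,800 one-minute samples (10 days × 8 h), 184
subjects, 50,000 Monte Carlo iterations — run the full pipeline in about a
second; tests use smaller series (≈ 2,000 samples) where the assertion is
statistical rather than exact. Degenerate inputs are first-class: constant
series raise on correlation and shape selection, empty series raise on
summary, all-point Monte Carlo specs collapse exactly to the deterministic
value and raise on sensitivity ("nothing to vary"). The pipeline's
`run_pipeline` is bit-reproducible for a fixed config and seed, and the
report bundle carries a provenance block (package version, seed, config
hash excluding the output path).

## Known limitations

Inhalation is the only exposure route (no dermal/oral), the cancer model is
the linear slope factor with no age-dependent adjustment, the annual
projection leans on a single fixed monitor, the ECSC equations are adult
European reference values applied outside their derivation population, and
flow-volume loop shape (FEF25–75 concavity) is not analysed. The default
annual ambient means (C₁ = 183 µg/m³ PM10, 98.6 µg/m³ PM2.5 in the
pipeline config) are calibration constants for the emulated campaign, not
measurements; users with a real regulatory record should supply their own.
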