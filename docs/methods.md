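# Methods

This note documents the statistical machinery, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate.

## Detection processing

Click-train logs carry one row per train: site, start timestamp, the
sequence of inter-click intervals (ICIs, microseconds) and a classifier
quality class (Hi/Med/Low). Only Hi and Med trains enter the analysis;
records with unrecognized labels are rejected and counted. A minute is
detection-positive when at least one train overlaps any part of it, with
the train span taken as start plus the sum of its ICIs — the only
duration derivable from the stored fields. All intervals are half-open
(`[t, t+1)`), so a train ending exactly on a boundary does not occupy
the next unit. Timestamps are fixed-offset EST (UTC-5, no daylight
saving), held as naive datetimes; calendar days and months are taken in
that offset.

Only hours completely covered by recording effort enter any model.
A recording day is a day with at least one complete hour (the
denominator of "proportion of days present"; configurable). Weeks
follow the ISO-8601 week-date standard. "% of hours present" uses
complete hours as its denominator, consistent with the complete-hour
rule.

## GARMA models

The hourly minutes-detected series is fitted with a GARMA(p, q) model:
a log-link regression on sinusoidal harmonics of hour of day (period 24)
and Julian day (period = calendar length of the year, 365 or 366), with
AR and MA feedback on the link scale and y* = max(y, c), default
c = 0.1, guarding g(0). The recursion restarts cold after any recording
gap: lagged terms that would cross a gap contribute zero.

Conditional distributions:

* Poisson;
* Poisson inverse-Gaussian (PIG), parameterized by mean mu and
  dispersion sigma with variance mu(1 + sigma mu). The pmf is evaluated
  through the modified-Bessel closed form with the half-integer-order
  Bessel terms generated by an exponentially scaled upward recurrence on
  the log scale — stable from the Poisson limit (sigma -> 0, handled
  exactly via a cancellation-free expression for 1/sigma - alpha) to
  counts in the thousands;
* zero-inflated Poisson (ZIP) with mixing weight pi.

Estimation is conditional maximum likelihood by L-BFGS-B over (beta,
phi, theta, log sigma or logit pi), with bounds |phi|, |theta| <= 0.95,
one deterministic start (IRLS Poisson GLM coefficients, moment-matched
dispersion) plus seeded random restarts (default 5 starts; the recovery
harnesses use 1, which the deterministic start makes sufficient at their
sample sizes). Standard errors come from a central-difference Hessian
of the negative log-likelihood. AIC = 2k - 2 loglik counts every free
parameter including the dispersion or zero-inflation. Model residuals
are randomized quantile residuals (seed-controlled), the standard choice
for discrete responses; diagnostics report their ACF/PACF against the
+-1.96/sqrt(n) band.

The AR/MA orders are selected by AIC over a small grid (the analysis
drivers use (1,0), which captures the generator's feedback); order
selection is deliberately explicit rather than fixed.

## Cyclic-spline GAM engine

Smooth terms are value-based cubic regression splines on evenly spaced
knots: cyclic (value, first and second derivative matching at the two
ends of the period; k knots give k-1 coefficients) for hour of day and
Julian day, natural (k coefficients, affine null space) for
environmental covariates, plus plain linear terms. The Julian-day
period is fixed at 366 so leap days are valid; day 366 wraps onto day 1.
The integrated squared-second-derivative penalty is assembled from the
same band matrices as the basis. Each smooth absorbs its sum-to-zero
constraint by reparameterizing onto the orthogonal complement of the
constant knot vector, so a fully penalized cyclic term shrinks to zero
(EDF -> 0) rather than to an unidentifiable constant; a natural-spline
term shrinks to its affine null space.

Fitting is penalized IRLS (binomial-logit with step-halving, Gaussian
closed form). Smoothing parameters minimize GCV = n D / (n - EDF)^2
over a 41-point log-spaced grid from 1e-6 to 1e8, coordinate-wise across
terms with two sweeps — reproducible and adequate at these data sizes,
in place of a full REML implementation. EDF per term is the trace of
the corresponding block of the influence matrix. Coefficient
covariances use the Bayesian form scale * (X'WX + S)^-1, giving the
+-2 SE bands on centered response curves.

Model choice among covariate subsets uses the AIC minimum with a 2-unit
parsimony margin (candidates within 2 units are treated as
indistinguishable and the smallest model wins). The weekly
environmental GAM uses the small-sample corrected AICc: with roughly 80
weekly records per site and up to three smooths, plain AIC measurably
over-retains null covariates, and AICc is the standard correction in
that regime. Binary-model goodness of fit is reported as a confusion
matrix at a configurable threshold (default 0.5 — a choice the source
analyses leave unstated) and the ROC AUC computed by the midrank
(Mann-Whitney) statistic, which handles ties exactly.

## Foraging classification

Within each porpoise-positive complete hour, the ICIs of all its
(quality-filtered) trains are pooled; the hour is foraging-positive iff
the minimum pooled ICI is at or below 10 ms (inclusive). The count of
buzz ICIs per hour supports robustness summaries (the proportion of
foraging hours backed by >= 5 buzz ICIs). Serial dependence between
the unevenly spaced foraging hours is deliberately not modelled — hours
are treated as independent — a documented limitation shared with the
standard analysis of such data. Sites with fewer than 24
porpoise-positive hours are not modelled (configurable).

## Weekly environmental association

Chlorophyll is log-transformed daily and weekly medians taken of the
logs (log-then-median; a switch provides median-then-log, which differs
only under within-week skew). Moon illumination is the weekly median of
nightly illuminated fractions. A Gaussian family on the proportion
response mirrors the established practice for this analysis even though
a binomial family would be more orthodox; this is fidelity over
orthodoxy and is isolated behind the module interface.

## Density validation

Spearman's rho is the Pearson correlation of midranks (tie-corrected).
For n <= 8 aligned months the two-sided p-value is exact by full
permutation enumeration; otherwise the t approximation with n - 2
degrees of freedom is used. Metrics constant across months have no rank
ordering and are reported as degenerate (NA), as happens for the median
metric at a near-silent site. Because the density predictions are
climatological 12-month values while deployments span multiple years,
daily data are pooled into calendar months before metric computation by
default (a per-year mode is available). No multiple-testing correction
is applied, matching standard reporting of these 16 correlations; the
output table records that fact.

## Synthetic generator

The generator emulates the study inputs, not the physics: no waveforms,
propagation or classifier internals. Hourly latent means are log-linear
in the configured harmonics (first harmonic of the year; first and
second harmonics of the day, phased to put maxima in the evening and
early morning) with optional GARMA AR(1) feedback; counts come from the
configured conditional law and are generated in a regime where the
60-minute ceiling has probability < 1e-6, so fitters need no truncation
correction. Configurations whose expected mean exceeds 60 minutes are
rejected outright.

Defaults emulate an 18-month, four-site mid-Atlantic deployment:
baseline 0.005 expected positive minutes per hour, seasonal amplitude
2.0 peaking at Julian day 60, diel amplitudes (0.4, 0.25) peaking at
20:00 and 01:00 EST, AR(1) feedback 0.55 and PIG dispersion 15. Those
values put a simulated site at ~3% porpoise-positive hours with bursty
per-hour maxima around 10-20 minutes and a winter-spring concentration —
the regime reported for such deployments. The per-day presence rate
that results (~45%) is higher than the ~30% such studies report; exactly
matching it would need day-scale clustering beyond the hourly AR(1)
model, a known limitation of the generator.

Click trains: every detection-positive minute of an in-effort hour
receives one Hi/Med train (7-24 travel ICIs drawn uniformly from the
configured range, default 20-150 ms); in foraging hours one train
carries a buzz run of 5-15 ICIs from the buzz range (1.5-9.5 ms), so
hour-level classification is exact by construction whenever the two
ranges do not straddle the 10 ms threshold. Low-class trains are
emitted as extra records inside already-positive minutes at a Poisson
rate chosen so the marginal quality-class frequencies match the
configured simplex; this keeps the quality filter from ever erasing a
minute the latent truth counts, giving the exact round-trip identity the
tests rely on. Train starts are whole milliseconds within (0.5 s, 50 s)
of their minute so spans never cross minute boundaries.

Environment: daily SST follows an annual sinusoid (default mean 12.5,
amplitude 8.5 degC, warmest mid-August, so winter minima sit at ~4 degC
— the temperatures at which occupancy peaks); chlorophyll sits at a
0.8 mg m^-3 baseline with a raised-cosine bloom to 6 mg m^-3 from
mid-January to mid-April; the nightly moon fraction is a rectified
cosine of period 29.53 d. One shared daily series stands in for the
per-site satellite extractions, which are out of scope. Density
predictions are an affine transform of the true pooled monthly mean
occupancy (optionally with lognormal noise), so with zero noise their
rank order matches the truth exactly.

The travel-ICI distribution of real porpoise click trains is not
standardized in the literature; the generator exposes it as a
configurable range rather than asserting a biological value.

All randomness derives from a single integer seed through named
substreams; identical seeds give byte-identical output tables.

## What the tests show — and do not

Parameter-recovery, selection and oracle-equivalence tests demonstrate
that the estimators are correct for data generated by the model families
they assume, at the study's sample sizes. They do not demonstrate
robustness to the ways real C-POD data violate those families:
classifier false positives, detection-range variation with noise and
sea state, day-scale animal residency beyond AR(1), or satellite data
gaps. The end-to-end check asserts qualitative structure (winter-spring
peak, midday foraging minimum, exact round-trip and rank identities),
not agreement with any field study's numerical tables.

## Problem sizes

The recovery harnesses use n = 5,000 hours (100 replicates) for
Poisson-GARMA recovery, n = 10,000 (100 replicates) for PIG-vs-Poisson
selection, 1,500-hour foraging series (50 replicates) and 80-week
environmental records (50-100 replicates); the end-to-end demo is the
full four-site, 18-month configuration (~51,000 complete hours). The
acceptance script reuses the same designs at 25-50 replicates.
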