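# Methods

## Data model and aggregation

Acute records carry species taxonomy (genus → phylum), endpoint (LC50 or
EC50), effect (mortality, immobility, respiratory inhibition), exposure
duration and concentration. Concentrations are held in μg/L; mg/L input
is converted on load (× 1000). The acute-duration convention is enforced
at load time: 48 h for daphniids, 96 h for everything else. Species-level
values are geometric means of their records — the standard aggregate for
log-distributed toxicity data — and species are matched by exact
normalized name (trimmed, case-folded); no fuzzy taxonomy resolution is
attempted, so a misspelled species fails loudly rather than silently
merging.

The bundled measured table stores one record per species (each printed
value cites a single study). Genus, order and class ranks absent from the
printed source were completed from standard taxonomic usage; the printed
phylum and family assignments are preserved verbatim, including the
placement of both chlorophytes under Chlorodendraceae.

The bundled predicted table stores the 19 adopted ICE predictions exactly
as printed. Its header in the original source says mg/L, but that reading
is inconsistent with the μg/L surrogate seed values and would put the
derived HC5 three orders of magnitude above the curve the measured data
give; the loader therefore reads it as μg/L by default, with an explicit
`unit` flag to override.

## ICE regression and the adoption screen

`ICERegressor` fits ordinary least squares in log10–log10 space and
reports the diagnostics the screen needs: `mse = RSS/(n−2)`, R² (squared
Pearson correlation), a two-sided t-test of slope = 0 with n−2 df, and a
leave-one-out cross-validation success rate in which a held-out
prediction within a factor `fold` of the observation (|Δlog10| ≤
log10(fold), boundary inclusive) counts as a success. `fold` defaults
to 5, the convention under which published cross-validation-success
columns for such models are computed; it is a parameter.

Taxonomic distance climbs the ladder genus (1), family (2), order (3),
class (4), phylum (5), kingdom (6); 0 means the same species. A missing
rank that would be needed to decide raises rather than guesses.

The six adoption criteria default to MSE ≤ 0.22, distance ≤ 4, CV ≥ 85 %,
df ≥ 8, R² ≥ 0.6, p ≤ 0.01 — *inclusive* comparisons at printed
precision. Published adopted sets contain boundary rows (MSE exactly
0.22), so the inclusive reading is the one that reproduces them; a strict
mode is available and the reproduction report always lists which models
only the strict mode would reject. Diagnostics tables rarely print df and
p; the filter's `allow_unknown` policy passes such rows with a warning
instead of fabricating values, and internally fitted models always carry
both.

## SSD fitting

Ranked log10 values get Weibull plotting positions `i/(N+1)` (Hazen
`(i−0.5)/N` selectable). With 19 species the smallest rank sits exactly
at 0.05, which is what makes an HC5 just below the minimum predicted
value geometrically sensible. The two-parameter fit minimizes the squared
deviation of the logistic curve from these probabilities
(`scipy.optimize.least_squares`, β bounded below at 1e−6, started at
α₀ = median, β₀ = IQR/ln 9); it is invariant to input order, and tied
values receive distinct sequential ranks (the fit only sees the equal X
values, so the assignment is immaterial). Maximum likelihood on the log10
values is available as a secondary method. HC_p inverts the curve in
closed form; HC50 = 10^α, and all work is in log10 with the natural-log
logit appearing only in the inversion, where the base cancels.

### Estimated asymptotes and the reproduction default

`LogLogisticSSD` defaults to the proper CDF (asymptotes pinned at 0
and 1). The *reproduction workflow* defaults instead to
`asymptotes="free"`, a four-parameter sigmoid whose plateaus are
estimated. The reason is empirical: the published hazardous
concentrations this package reproduces cannot be obtained from the
printed data with any fixed-asymptote convention (two-parameter least
squares gives HC5 ≈ 3.5 μg/L on the measured table; MLE, probit/logit
regression and alternative plotting positions were all checked), but the
free-asymptote least-squares fit — the default behavior of the
point-and-click curve-fitting software named in the original analysis —
lands within about 3 % of the published measured HC5. The trade-off is
explicit: an unconstrained sigmoid is not a distribution function (the
fitted upper plateau on the measured data is ≈0.80), so HC_p is defined
by solving Y = p on the absolute scale and only for p between the fitted
plateaus. Every report records which mode produced its numbers, and new
analyses should prefer the constrained fit.

On the bundled predicted table the same free-asymptote procedure yields
an HC5 of ≈228 μg/L, about a third above the published 167.2 μg/L; no
fitting convention tested recovers that figure from the 19 printed
values, and the surrounding text suggests it may derive from a larger
(21-species) prediction set that was not printed. The package reports
what the printed data give.

## Bootstrap intervals

`bootstrap_hcp` resamples species with replacement, refits, re-inverts,
and takes the 2.5/97.5 percentiles of the replicate HC_p values
(nonparametric percentile interval, deterministic per seed). Replicates
that collapse below three distinct values, or whose refitted curve cannot
be inverted at p, are redrawn up to 100 times and then skipped with a
warning; the interval is widened if necessary to bracket the point
estimate so the reported triple is always ordered. In a 100-trial
simulation at n = 200 species with 100 replicates each, the nominal 95 %
interval covered the true HC5 in 92 trials.

## Kolmogorov–Smirnov comparison

D is the sup-distance between right-continuous ECDFs, computed by a
pooled sweep; the scaled statistic Z = D·√(n₁n₂/(n₁+n₂)) is reported
alongside because statistical packages often print Z where reports say
"ks" — reporting both avoids that ambiguity, and conclusions rest on the
p-value. The p-value is exact (network enumeration) for n₁·n₂ ≤ 10⁴ and
otherwise uses the asymptotic Kolmogorov tail Q(z); at the bundled sample
sizes (11 vs 19) the asymptotic version is conservative (null rejection
rate ≈ 0.03 at nominal 0.05 over 1000 simulated replicates).

## Synthetic generators

Two pure-function generators (scenario in, deterministic sample out)
cover the pipeline's assumptions: (a) surrogate/predicted log10 pairs
with the predicted value linear in the surrogate plus Gaussian noise in
log10 space — the assumption behind log–log toxicity regression — and
(b) inverse-transform samples from a log-logistic SSD with known α, β.
Defaults are chosen to look like real acute aquatic data: surrogate
values spanning 10–10⁶ μg/L (the span of the bundled tables), noise 0.2
log10 units (within the 5-fold CV band adopted models must meet), ~30
chemicals per regression, α = 3, β = 0.5. The generators emulate the
*statistical* structure only: they produce no inter-species correlation
structure beyond the single regression, no censoring, no measurement
error in the surrogate, and identical taxonomy templates — so passing
recovery tests demonstrates correctness of the estimators under the
model's own assumptions, not robustness to real-data violations of them.

One recovery property sits exactly on its own threshold: at n = 200 the
probability that the least-squares α̂ lands within ±0.1 of truth is
0.902 (measured over 1000 replicates; ±0.1 ≈ 1.63 standard errors), so a
100-replicate run clears a 90 % bar only about half the time. The suite
runs that experiment with fixed generator seeds 0–99 and reports the
outcome as-is.

## Problem sizes

Simulation-backed tests use the sizes stated with their properties:
100 × n=200 for SSD recovery, 200 bootstrap replicates in unit tests,
1000 replicates for the K-S null-rate check. The whole suite completes in
well under a minute on one core.

## Known limitations

* The free-asymptote mode exists to reproduce legacy analyses; its HC_p
  is not a distribution quantile.
* Chronic data, assessment-factor extrapolation, and alternative SSD
  families (log-normal, Burr III) are out of scope.
* The ICE screen evaluates diagnostics as given for externally fitted
  models; it cannot re-derive coefficients that were never published.
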