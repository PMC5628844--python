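# Methods

## The estimation problem

Opportunistic collection records are presence-only and effort-biased: a year
with many records may simply be a year with many active collectors. The
list-length device converts the records into a pseudo-designed survey. A
*list* — the unique combination of locality, date and collector — is treated
as one finite recording event; whether a focal species appears on a list
(its reporting rate) is a Bernoulli outcome whose probability is modelled
jointly with two within-list effort proxies: the log of the list length
$L$ (species per list) and the total individual count (*records*). The year
coefficient then estimates change in detection probability *conditional on
effort*, which is the quantity interpreted as an occurrence trend. A county
random intercept absorbs unmodelled spatial structure; three bioclimatic
covariates (below) let climate compete with year for explanatory weight.

Assumptions inherited from the design: lists are complete samples of what
the collector kept (hence the exclusion of single-species lists as likely
incomplete), detectability relative to other species on a list is stable
over time, and counties are exchangeable given their random intercept.

## List building and filters

Records missing any of species/year/locality/county/collector are rejected
(counted and logged). The date key uses the full date string when month and
day exist; year-only records form their own key, since museum labels often
lack day precision. Counties match after case-folding and trimming. Filters,
in order: taxon merging (cryptic pairs collapsed before aggregation), the
L ≥ 2 list filter, then the activity-class split. A list belongs to the
diurnal (nocturnal) dataset if it contains at least one diurnal (nocturnal)
species; mixed lists join both — the assignment rule for mixed lists is a
package decision, as published accounts report per-class list counts without
stating one. Within a class, species on fewer than 10 lists are excluded
from the model roster (reported in the log), matching the convergence-driven
inclusion rule used with such data.

## Bioclimatic covariates

Per county-year, from 12 monthly values: **Bio6** = minimum of the monthly
minimum temperatures (°C); the *warmest quarter* is the 3-consecutive-month
calendar window (January–March … October–December, no December wrap) with
the highest mean temperature, ties to the earliest window; **Bio10** = mean
of monthly means over that window (°C); **Bio18** = precipitation summed
over the same window (mm). The calendar (non-wrapping) quarter convention is
a declared decision: for a northern-hemisphere summer quantity the warmest
window never straddles New Year, and record years are calendar years.
Cross-year wrapping would matter only for cold-season quarters, which are
not used here. Grid-to-county aggregation is out of scope — the module
consumes any pre-aggregated monthly county series in °C and mm.

## The GLMM and its likelihood

With counties independent, the marginal likelihood factorizes into one
1-D integral per county. Each integral is evaluated by adaptive
Gauss–Hermite quadrature: the integrand's mode is found by damped Newton
iterations (the conditional log-density is strictly concave in the county
effect), the quadrature grid is centred there and scaled by the local
curvature, and `n_nodes` Hermite nodes are summed in log space. One node
reproduces the Laplace approximation exactly; 15 nodes (the default) agree
with 201-node brute-force integration to better than 1e-6 on datasets of
the size used per county here. `re_sd = 0` short-circuits to the ordinary
logistic log-likelihood.

Optimization is over the fixed effects and log(sd) with L-BFGS-B
(finite-difference gradients; bound log sd ≥ −18). Standard errors come
from the inverse of a central-finite-difference Hessian of the marginal
log-likelihood at the optimum; a non-positive-definite Hessian flags the
fit and yields NaN SEs rather than numbers that look healthy. Convergence
requires optimizer success plus a small final gradient; non-converged fits
are flagged, never silently returned.

Numerical choices worth knowing:

* **Boundary variance.** The marginal likelihood is flat to ~1e-9 over
  sd ∈ [0, 1e-3], so any converged stop below 1e-3 is reported as exactly 0
  and the SEs are computed conditional on sd = 0.
* **Standardization** uses the n−1 SD, is computed once per analysis
  dataset (all species in a class share constants), and the (mean, SD)
  pairs are stored so coefficients can be mapped back to natural units.
  Natural log for log(L).
* **AICc** uses k = fixed effects (incl. intercept) + 1 for the variance,
  and n = rows of the fitted response vector (events in the dataset). Both
  are conventions one could argue; they are applied uniformly so model
  ranking within a species is unaffected by the n choice (all candidates
  share n).

## Multi-model inference

Sixteen candidates: every subset of {year, bio6, bio10, bio18} on top of the
mandatory log L + records + county terms. Weights are the usual
exp(−Δᵢ/2) normalization. If one model reaches weight ≥ 0.9 it is retained
alone; otherwise models within evidence ratio 0.05 of the best (wᵢ ≥ 0.05
max w) are retained. Coefficients are averaged conditionally — only over
retained models containing the term, weights renormalized over those — and
the averaged SE uses the revised unconditional estimator
SE_t = Σ w̃ᵢ √(SEᵢ² + (βᵢ − β̄)²), the standard companion to conditional
averaging. Trend calls use estimate ± 1.96·SE: decline iff the interval is
entirely below zero, increase iff above, no-trend otherwise. When the
retained set happens to contain no year model, the year estimate is averaged
over the year-containing candidates of the full set so a trend estimate is
always defined (a per-species trend display requires one). Non-converged
candidates are dropped before weights are computed. VIFs (1/(1−R²) from OLS
of each predictor on the rest) and pairwise Spearman correlations are
reported per dataset as collinearity diagnostics.

## The synthetic generator

The generator emulates the record-generating process the analysis assumes:
counties with Dirichlet-distributed popularity among collectors; yearly
event totals Poisson around a piecewise effort regime that jumps at 1965
(the mercury-vapor-light era; an exact total can be requested instead, in
which case events are allocated multinomially); per event a list length
L = 1 + Poisson(1) — matching the 1–2 species historical mean — and a
record count = L + Poisson(1.5); monthly county climate as a northeastern-US
seasonal cycle plus county offsets plus noise, fed through the bioclim
module; county intercepts N(0, sd²) with their realized (non-zero) sample
mean retained; and per-species detections drawn from the logistic model on
the standardized realized covariates. One master generator seeds everything;
climate uses an independent substream so it is identical whether simulated
alone or inside `simulate_records`. Default 30 counties, on the scale of the
~80-county northeastern-US study region.

Species detections are drawn *conditionally* on the drawn L and record
count — exactly the conditional observation model the GLMM estimates — so
parameter recovery against the stored ground-truth design is a clean test of
the estimator. The materialized record table then contains rows only for
detected species, so the list length a pipeline recomputes from the table is
an emergent, noisy version of the drawn L. This mirrors real collecting,
where the recorded list is itself the outcome of detection, and it means
pipeline-path effort coefficients are mildly attenuated relative to truth
(errors-in-variables); the year trend, being exogenous to detection, is
robust to this. What the generator does **not** emulate: spatial geography
beyond county labels, within-year phenology beyond a uniform month draw,
collector-specific skill or preferences, taxonomic uncertainty, and
migration. Passing recovery tests therefore demonstrate estimator
correctness under the assumed model, not robustness to these real-data
complications.

## Monte-Carlo verification

`recovery.coefficient_recovery` runs the simulate-and-refit experiment at
the default study conditions (2000 events, 30 counties, county SD 0.5,
100 replicates): per-coefficient 95% CI coverage lands in the nominal band
for every term, a standardized year effect of −0.5 is called a decline in
essentially every replicate, and under a zero year effect false trend calls
stay at the two-sided 5%-test level. With markedly fewer clusters
(~10 counties) the Wald intervals for cluster-level covariates (intercept,
bio terms) drift a few points off nominal — the familiar few-cluster
caveat, worth remembering when applying the model to small study areas.

The test suite pins the implementation to independent references at every
layer: exact rational hypergeometric enumeration for the Fisher test,
201-node and `scipy.integrate.quad` integration for the likelihood, a
hand-coded IRLS solver and statsmodels GLM for the degenerate-variance
case, R lme4::glmer (nAGQ = 15) for the full mixed fit, and an exhaustive
window scan for the bioclim quarters.

## Known limitations

* Single scalar random intercept only — no crossed/nested effects, REML,
  overdispersion or autocorrelation structures.
* Wald (normal-approximation) intervals throughout; no profile likelihood
  or bootstrap, hence the few-cluster caveat above.
* Finite-difference derivatives make a single fit O(hundreds) of likelihood
  evaluations; fine at this problem size, not tuned for much larger ones.
* The trait tests treat species as independent draws; phylogenetic
  non-independence is ignored, as in the source analysis tradition.
* The summer/spring flight classification is a two-bin simplification keyed
  on flight-period end month ≤ June.
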