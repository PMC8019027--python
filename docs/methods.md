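# Methods

This note documents the statistical models implemented in `bearvitals`,
the choices made where a design was genuinely open, and what the bundled
synthetic data can and cannot establish.

## Monitoring model and data layout

The package analyses known-fate telemetry data on female brown bears.
The monitoring year runs den emergence to den emergence and is divided
into **eight intervals**: the seven active-season months April–October
(intervals 1–7) and one pooled November–March denning interval (8).
Monthly mortality cannot be resolved while bears hibernate, so the pooled
winter interval is treated as *one* interval exactly as the data are
coded, not as five months of calendar time. Exposure is counted as
bear-intervals; 8 intervals = 1 bear-year. Ages increment at den
emergence (interval 1), matching spring capture and the definition of cub
ages by emergence year. Age classes: cub (0), yearling (1), subadult
(2–5), adult (6+), with last reproduction at age 24.

An encounter history is one collar span. Re-entry after censoring is not
modelled; a re-collared female starts a new history with the same ID and
an incremented segment index, which is all the risk-interval estimators
need. A `censored` record marks the last interval of known status (collar
drop, or more than eight weeks without contact) and terminates the span.

## Independent-female survival

Because fates are known in every monitored interval, each bear-interval
is a Bernoulli trial and the known-fate likelihood factorizes: an
interval survived contributes *s*, a death contributes 1 − *s*, a
censored record contributes nothing. The three candidate models are
cell-mean models — S(~1), S(~Pop), S(~Age) — whose MLEs are exact
binomial proportions; the implementation uses the closed form and the
tests verify it against a brute-force grid maximizer. Annual survival is
the interval estimate to the 8th power (constant hazard over the coded
intervals).

AICc uses effective sample size = bear-intervals, the known-fate
convention (the source analyses do not state theirs, so this is
documented here as the package's choice). Models within ΔAICc < 2 of the
best are averaged with renormalized Akaike weights; CI bounds are
averaged with the same weights, an approximation that is exact when one
model carries essentially all the weight, as happens in these data.

Interval CIs are profile-likelihood. With zero observed deaths the MLE
sits on the boundary and the interval is the asymmetric (lower, 1.00)
profile bound: with *n* bear-intervals and no deaths the lower interval
bound is exp(−χ²₀.₉₅/2*n*), raised to the 8th power for the annual scale.
The staggered-entry Kaplan–Meier estimator is provided in parallel,
pooling years on the 8-interval cycle, with Greenwood variance on the
log-survival scale; deaths are counted before censors within an interval
(product-limit convention).

## Offspring survival

Cub survival is surviving cubs over cubs counted at emergence, over
litters whose mothers were monitored through autumn; mothers censored
earlier are excluded. Uncertainty is a nonparametric bootstrap (B = 1000,
percentile 2.5/97.5). The default resampling unit is the **individual
cub**, justified by a one-way ANOVA of per-cub binary fate grouped by
litter (a large p-value indicates no within-litter clustering);
litter-level resampling is available as a sensitivity option and shares
the same point estimate. Zero-mortality samples (the yearling data here)
return a point of 1.0 with `variance_defined = False` rather than a fake
interval.

## Age of primiparity and interbirth interval

Both use an availability-weighted discrete-hazard estimator. At each age
*a* (or offset *t* from a birth year) the hazard *h* is events over
females monitored and still available; the event-age distribution is
P(a) = h_a ∏_{a′<a}(1 − h_{a′}) and the mean is Σ a·P(a) / Σ P(a).
Females lost to collar drop or death contribute exposure while monitored,
so the estimate is not biased toward early maturers or short intervals
the way the naive average of completed events is (the test suite
demonstrates the bias ordering under heavy censoring).

Numerical choices: the schedule is truncated at the last age/offset with
an observed event and renormalized — small samples cannot identify the
tail — and the renormalizer Σ P is exposed so truncation is visible.
Bootstraps resample whole females, preserving within-female dependence.
Females first seen already with a litter are left-truncated with unknown
parity and contribute nothing to the primiparity risk sets.

## Reproductive-state Markov chain

Adult females (age ≥ 6) are observed each spring as Alone (A), with cubs
(C), with yearlings (Y) or with 2-year-old-or-older dependents (T). Ten
transitions are biologically possible (A→A, A→C, C→A, C→C, C→Y, Y→A,
Y→C, Y→T, T→A, T→C); observing any other is a data error. Survival and
detection are prerequisites of observing a transition, so the matrix is
the per-row multinomial MLE of the observed tallies.

The stationary distribution is obtained by iterating π ← πT from the
all-Alone start (1,0,0,0) to L1 tolerance 1e-12 (max 100 000 iterations —
4-state chains converge in tens, and the strict tolerance makes the
eigenvector cross-check meaningful). The independent check solves for the
leading left eigenvector. A perfectly periodic chain (e.g. the
deterministic cycle A→C→Y→T→A) never converges pointwise; the iterate
then revisits an earlier point exactly, and the implementation returns
the cycle average — the Cesàro limit, which is the unique stationary
vector of an irreducible periodic chain — flagged `periodic=True`.
Published matrices printed to 2 dp can have row sums off by a cent
(0.63 + 0.38); rows are validated within a 0.02 tolerance and
renormalized exactly.

The mean reproductive rate is m = ½ × mean litter size × π_C, the female
fraction being ½ because cub sex is not determined in the field.
Bootstrap uncertainty resamples females with their complete transition
sets; replicates in which an observed origin state has no transitions are
redrawn and counted.

## Leslie-matrix projection

The 25-class age model (ages 0–24) has survival on the subdiagonal
(S_cub, S_yearling, S_subadult ×4, S_adult ×18) and fecundity m in the
first row for ages 6–24, constant over adult ages. Fecundities are placed
**without a survival discount** by default, giving the characteristic
equation Σ λ^−(x+1) l(x) m = 1; this convention reproduces the published
growth rates from the published point rates, and the pre-breeding
alternative (F = S_cub·m) is available behind the `convention` flag. λ is
the dominant eigenvalue, verified in tests against an independent
bisection root of the Euler–Lotka equation to 1e-6.

R0 = Σ l(x)·F(x) and GenT = ln R0 / ln λ, with the λ→1 limit handled as
the mean age of offspring production. Note that the published R0 and
generation-time values are not exactly recoverable from the published
point rates under any standard assembly convention (Σ l m gives ≈ 3.7 for
the larger population against a reported 3.03); the package reports its
own internally consistent values and does not attempt to force agreement.

The stable stage structure (cub/yearling/subadult/adult) is computed two
ways and asserted equal to 1e-6: aggregation of the age eigenvector over
stage bins, and the eigenvector of a 4-stage matrix collapsed with the
conditional age-group transition rate
P = λ^−(x_j−x_i−1) l(x_j−1) / Σ_{x=x_i}^{x_j−1} λ^−(x−x_i) l(x),
which preserves λ and stable structure exactly at the stable age
distribution (the tests confirm machine-precision agreement on random
rate sets).

Uncertainty propagates by Monte Carlo (1000 iterations): each iteration
draws one replicate per vital rate independently from its bootstrap
distribution, builds the matrix, and records λ, R0, GenT; survival draws
outside [0,1] are rejected and redrawn (tallied). Draws with zero
fecundity (possible when a bootstrap replicate contains no cub
observations) yield a degenerate reducible matrix; λ is recorded but such
draws carry no stable structure and are excluded from the stable-age and
stable-stage averages. Joint resampling across rates is not modelled —
the rates come from separate data — and this is stated rather than
hidden.

## Synthetic-data generator

The simulator is first-class, tested code. It generates true female life
histories (annual birth-pulse state machine A→C→Y→T→A, per-cub
independent first-year survival, per-class annual mortality at a
uniformly drawn interval, weaned daughters recruited binomially at the
half-female rate) and overlays a monitoring layer: Poisson staggered
captures, exponential collar retention, per-flight detection with three
relocation flights per active season, and the 8-week gap rule converting
a missed flight into censoring at the last successful contact. Each
female has her own RNG substream keyed by scenario seed and creation
index, so life histories are invariant to monitoring-schedule changes and
identical seeds give byte-identical output tables.

Interbirth structure is generated **mechanistically** — weaning at age 3
followed by a per-year breeding probability p, giving an emergent mean
interval of 2 + 1/p years — rather than drawn from an assumed interval
distribution, so the interbirth estimator is tested against an emergent
truth. Orphaned cubs die with their mother; older dependents finish
dependency alone.

The default two-population scenario encodes the study conditions: truth
equal to the published point estimates (cub survival 0.85/0.33,
independent-female survival 1.00/0.81, litter-size means 2.33/2.25,
breeding probabilities 0.48/0.40 giving mean interbirth intervals
4.08/4.5 years), 14 years from 2005, and capture effort calibrated so the
expected realized monitoring matches the published effort (~16 and ~9
collared females, ~43 and ~26 bear-years). The relocation frequency of
the later study phase is not precisely published; the default uses three
flights per season with 95% per-flight detection.

What the simulator does *not* emulate: spatial movement and home ranges,
infanticide as a mechanism, density dependence, environmental
stochasticity, age-dependent transition probabilities, and observation
error in offspring counts (a detected mother's dependents are counted
exactly). Parameter-recovery results on synthetic data therefore show
estimator correctness under the stated generating model, not robustness
to these real-data features.

## Problem sizes used in the test suite

Deterministic checks (stationary distributions, eigenvalues, worked
numbers) run on the bundled study-scale data. Parameter-recovery and
model-selection properties use 200 replicate simulated studies at full
study scale (~69 bear-years of exposure per replicate); the
estimator-bias property uses 30 replicates of 120 censored interval
histories; oracle equivalences use 100 random vital-rate sets. The full
suite runs in about a minute on one core.

## Known limitations

* The averaged-CI rule in model averaging is a convenience, not an
  unconditional coverage guarantee.
* The hazard estimators' truncation-at-last-event rule means tail mass is
  unidentified by design; with very sparse events the reported means are
  conditional on the observed event range.
* Bootstrap CIs are percentile intervals; no BCa correction is applied at
  these sample sizes.
* The Monte Carlo projection treats vital-rate distributions as
  independent across rates.
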