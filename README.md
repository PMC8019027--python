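# bearvitals

Demographic analysis of small, telemetry-monitored brown bear
populations: known-fate survival, bias-corrected reproductive parameters,
a reproductive-state Markov chain, and Leslie-matrix population
projection with bootstrap/Monte-Carlo uncertainty.

## The problem

Small carnivore populations (tens of individuals) are exactly the ones
whose vital rates are hardest to estimate: samples are tiny, monitoring
is staggered and interrupted by collar loss, and naive estimators are
biased — toward early-maturing females, toward short interbirth
intervals, toward whatever was easiest to observe. This package
implements the estimator chain used in wildlife demography to get
defensible vital rates and a population growth rate out of a handful of
collared females:

* **Known-fate survival** — each monitored bear-interval is a Bernoulli
  trial, so survival models (S(~1), S(~Pop), S(~Age)) have exact binomial
  MLEs, ranked by AICc and model-averaged within ΔAICc < 2; a
  staggered-entry Kaplan–Meier estimator runs in parallel. Annual
  survival is the interval rate to the 8th power (seven monthly summer
  intervals plus one pooled denning interval).
* **Offspring survival** — cub and yearling survival bootstrapped over
  litter observations, with a litter-independence ANOVA deciding the
  resampling unit.
* **Primiparity and interbirth interval** — availability-weighted
  discrete-hazard estimators: P(a) = h_a ∏_{a′<a}(1 − h_{a′}), mean
  Σ a·P(a)/Σ P(a), unbiased by censoring of late events.
* **Reproductive-state chain** — adult females are Alone / with Cubs /
  with Yearlings / with Two-year-olds; the ten permitted transitions are
  estimated by multinomial MLE and iterated π ← πT to the stationary
  distribution; the reproductive rate is m = ½ · litter size · π_C.
* **Projection** — a 25-age-class Leslie matrix (survival subdiagonal,
  fecundity m for ages 6–24) whose dominant eigenvalue λ is cross-checked
  against the Euler–Lotka root; R0, generation time, and stable
  age/stage structure (the stage collapse uses the conditional
  age-group transition rate and matches the aggregated eigenvector to
  machine precision); Monte-Carlo propagation of the bootstrap
  distributions.

An individual-based simulator with known truth (staggered capture,
exponential collar life, per-flight detection, the 8-week censoring rule)
generates all input tables, so every estimator is testable by parameter
recovery. Bundled example data (`bearvitals.datasets`) reconstruct a
published two-population study in British Columbia: a larger, connected
population (`MM`) and a small, isolated one (`NSN`).

## Worked example

```python
import bearvitals as bv
from bearvitals import datasets

# stationary reproductive-state distribution, larger population
tm = datasets.transition_matrix("MM")          # rows A, C, Y, T
pi = bv.stable_state(tm)
print([round(x, 3) for x in pi.pi], pi.iterations_to_converge)
# [0.399, 0.2, 0.2, 0.2] 57

ls = bv.litter_size(datasets.litters(), "MM", seed=7)
print(round(ls.point, 2), (round(ls.ci_low, 2), round(ls.ci_high, 2)))
# 2.33 (1.89, 2.78)

print(round(bv.reproductive_rate(ls.point, pi["C"]), 3))
# 0.234

L = bv.build_leslie(datasets.vital_rates("MM"))
print(round(bv.growth_rate(L), 3))
# 1.093
```

Reading: about 20% of adult females have cubs in any year at
stationarity; with 2.33 cubs per litter and half of cubs female, an adult
female produces 0.23 female cubs per year, and the resulting Leslie
matrix projects 9% annual growth. The same chain on the small isolated
population (cub survival 0.33, independent-female survival 0.81) projects
a 15% annual decline (λ ≈ 0.85).

The whole analysis runs as one command over CSV tables or a simulated
scenario:

```sh
vitalrates run --seed 7 --out report/        # bundled example data
vitalrates simulate --seed 3 --out sim/      # synthetic study + truth.json
vitalrates survival --encounters sim/encounters.csv
```

## Layout

```
src/bearvitals/
  data.py         domain types, CSV I/O, exposure and crude mortality
  survival.py     staggered-entry KM, known-fate models, AICc, averaging
  offspring.py    bootstrap cub/yearling survival, litter ANOVA
  reproduction.py hazard-weighted primiparity / interbirth, litter size
  transitions.py  4-state Markov chain, stationary distribution, m
  projection.py   Leslie assembly, lambda/R0/GenT, stage collapse, MC
  simulate.py     individual-based monitoring simulator with truth
  datasets.py     bundled two-population example data
  pipeline.py     end-to-end runner
  cli.py          `vitalrates` command group
docs/methods.md   model and estimator documentation
```
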