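# engroflux

Constraint-based analysis of glucose/glutamine-driven cancer cell growth on a
curated core network of human central metabolism.

Proliferating cancer cells ferment most glucose to lactate even with oxygen
around (aerobic glycolysis) while consuming large amounts of glutamine.
`engroflux` is a library for asking *why* that wiring wins, using a compact
stoichiometric model (84 reactions, 67 metabolites: glycolysis, TCA cycle,
oxidative phosphorylation with ROS generation, glutaminolysis and reductive
carboxylation, pentose phosphate pathway, urea cycle, glutathione redox,
fatty-acid and non-essential-amino-acid synthesis feeding a biomass
reaction).  It is aimed at systems-biology researchers who want to reproduce
or extend this style of analysis from Python.

The toolbox implements, over any `MetabolicNetwork`:

* **FBA / FVA** — maximize a weighted flux sum `max c·v` subject to the steady
  state `S·v = 0` and bounds `lb ≤ v ≤ ub`; per-reaction flux ranges at fixed
  optimum (GLPK backend, ~0.2 ms per solve).
* **Alternate-optima enumeration** — a recursive MILP with integer cuts lists
  every directionality-distinct optimal flux pattern of the optimal face.
* **Random-objective ensemble sampling** — `z_j = Σ c_i v_i` with each weight
  zero with probability `τ_j ~ U(0,1]` and otherwise `U(0,1]`; each sampled
  objective is one virtual "wiring".  Responses to glucose/glutamine
  availability scans are classified into ensembles (growers, TCA-damped,
  reductive-carboxylation + lactate-redirection, ...).
* **Metabolite-shift prediction** — virtual efflux reactions let metabolites
  escape steady state; a Z-score
  `Z = (X̄₁ − X̄₂) / sqrt(σ₁²/n + σ₂²/n)` over paired ensembles calls each
  metabolite up/down/unchanged between nutrient conditions.
* **Parameter scans** — growth landscapes over availabilities, critical-oxygen
  detection (the O₂ level where PDH → 0 and lactate secretion peaks),
  constrained TCA-mode classification (branched / cyclic / truncated),
  Complex-I-capacity, pROS and biomass-composition sensitivity.
* **Closed-form yield accounting** — ATP/O₂ ledgers for catabolic routes,
  including the effective NADH P/O under Complex-I electron leak to
  superoxide, `P/O = 3(1 − pROS)/(1 + pROS)`.

The bundled model file (`src/engroflux/data/engro1_synthetic.tsv`) is a
**synthetic reconstruction** of the published ENGRO1 core model, rebuilt from
its documented pathway inventory and calibrated to its documented operating
points (see `docs/methods.md`); the original supplementary files are not
redistributed.

## Worked example

```python
import engroflux as ef

net = ef.load_engro1()                                   # 84 x 67 core model
net = ef.set_availability(net, "glucose_uptake", 10.0)   # mM/h
net = ef.set_availability(net, "glutamine_uptake", 40.0)
net = ef.set_availability(net, "oxygen_uptake", 38.0)    # the critical level

state = ef.fba_optimize(net, net.biomass_reaction_id)
print(state.objective_value)                  # 1.9281
print(state["PDH"], state["ACONT"])           # 0.0   -5.707
print(ef.effective_po(0.25))                  # 1.8
```

At this boundary the growth optimum keeps pyruvate dehydrogenase at zero and
runs aconitase backwards at 5.7 mM/h: every glucose molecule leaves as
lactate while glutamine both fuels respiration and, via reductive
carboxylation, supplies the citrate for lipid synthesis — the
glutamine-driven Warburg wiring.  The `1.8` is the effective P/O ratio of
NADH oxidation when a quarter of Complex I electrons leak to superoxide,
which is what makes partial glutamine oxidation the best use of scarce
oxygen.

The `examples/` directory has one short script per capability (growth and
loop checking, alternate optima, ensemble scans, metabolite shifts, critical
oxygen and landscapes, yields and blood-gas arithmetic); each prints the
numbers it computes with a line on what they mean.  Whole published
experiments can be replayed declaratively through
`engroflux.run_experiment` (see `engroflux.reports`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline analytic quantity from scratch — the
effective NADH P/O ratio at 25% Complex-I electron leak, evaluated through
`engroflux.yields.effective_po` — and writes it as JSON.
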