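# Methods

## The model and its assumptions

`engroflux` analyses a core stoichiometric model of human central metabolism
built to weigh the contributions of glucose and glutamine to growth.  All
species live in one lumped intracellular compartment; only acetyl-CoA keeps
two pools (`accoa` for oxidative metabolism, `accoa_c` devoted to fatty-acid
synthesis).  Flux analysis imposes strict steady state `S·v = 0` with bounds
in mM h⁻¹; nutrient *availability* is the upper bound of an import reaction
(uptake written environment → cell, so a positive flux brings the nutrient
in).  Exchange reactions touch exactly one metabolite.

### The bundled network is a synthetic reconstruction

The original ENGRO1 supplementary model files could not be redistributed, so
`data/engro1_synthetic.tsv` rebuilds the network from its documented
inventory: 84 reactions and 67 metabolites in the published pathway counts
(glycolysis + lactic fermentation 10, TCA 9, oxidative phosphorylation + ROS
2, glutamine/reductive carboxylation 4, glutathione 10, urea cycle 5,
fatty-acid synthesis 2, pentose phosphate 5, NEAA synthesis 13), plus
anaplerosis (PEPCK, pyruvate carboxylase, both malic enzymes), maintenance,
three protein-composition variants, biomass and 15 exchanges.  Reaction
stoichiometry follows standard biochemistry with the lumping a core model
needs (e.g. serine synthesis, palmitate synthesis, the methionine cycle).

Two documented operating points served as calibration targets, treating the
published numbers as inputs that replace the lost file:

* **Complex I** is lumped as
  `nadh + 0.5(1+p) o2 → nad + 3(1−p) atp + p h2o2` with `p = pROS = 0.25`
  (the fraction of electrons diverted to superoxide; superoxide formation
  consumes extra O₂, dismutation returns half, detoxification costs one
  NADPH per H₂O₂ through glutathione peroxidase/reductase).  This is the
  unique lumping that makes the published effective P/O formula
  `3(1−p)/(1+p)` the literal ATP-per-O of the reaction, reproduces the
  published route P/O ledger (2.2, 2.1, 2.07, 2.0), and yields exactly 1.5
  O₂ per glutamine fermented to lactate — hence 63% glutamine usage when
  maximizing ATP at O₂ 38 / Q 40.  It also makes glutathione-based H₂O₂
  removal *oxygen-saving*, so the optimum uses it even though a free H₂O₂
  demand exists — a documented and initially puzzling observation that this
  stoichiometry explains mechanically.
* **The biomass reaction** consumes 6 amino-acid units of protein (50/50
  glycolysis-derived and glutamine-derived NEAA by default, with 80/20 and
  20/80 variants closed), 0.37 palmitate, 0.05 glutathione and 65.206 ATP.
  The ATP coefficient was calibrated so the critical oxygen availability at
  glucose 10 / glutamine 40 mM h⁻¹ is 38.0, as documented.

Properties that were *not* calibrated then emerge on their own: the Complex
I/Complex II respiration ratio at the critical point is 1.20 (documented
"around 1.2"), growth without oxygen is zero, the growth optimum at the
critical point is branched-TCA with a ~14% reductive share of glutamine
(documented ~20%), and blocking lactate secretion forces a cyclic TCA at a
modest growth cost.  Three departures from the original's documented behavior
remain and are inherent to not having the file: the enumeration finds 47
direction-distinct optima rather than 44 (three of which break the
documented IDH direction exclusivity), the ensemble fractions sit a few
points off (B 94% vs 98%, C 6% vs <2%), and five of eighteen metabolite-shift
calls differ (malate/fumarate uncalled, ornithine/putrescine called down,
cysteine up).

Smaller reconstruction choices, made once: glutamate dehydrogenases are
irreversible (oxidative deamination) because reversible GDH + reversible IDH
pairs would form a closed transhydrogenation loop, contradicting the
documented loop-freeness; cysteine synthesis is a lumped serine → cysteine
step (sulfur untracked) because strict transsulfuration would make
methionine uptake the growth-limiting nutrient; glutathione enters biomass
(0.05) so that its synthesis can carry steady-state flux; putrescine,
pyruvate, alanine, glutamate and serine effluxes exist but ship closed,
keeping the exchange set minimal.

## Numerical choices

All LPs go through GLPK (simplex, feasibility/optimality tolerances 1e-9)
on a problem object reused with warm starts; any non-optimal verdict is
re-verified with a fresh basis and once more through the presolver before
being believed (a warm basis occasionally produces a spurious
"infeasible").  A flux below `FLUX_EPSILON = 1e-6` counts as zero for
directionality; the enumeration MILP forces any active direction to carry
at least `ACTIVATION_EPS = 1e-4`.  The alternate-optima count is sensitive
to these two constants; they are single named constants and the count is
stable across activation thresholds 1e-4..5e-2.  Enumeration semantics
follow the recursive-MILP formulation: reversible reactions are split into
non-negative forward/reverse parts, each found pattern adds an integer cut,
and a pattern whose active directions strictly contain an already-found
pattern (that is, one that only adds a redundant sub-cycle) is not
reported.  Found patterns are "polished" by re-solving the LP with the
directions fixed so every reported vertex sits exactly on the optimal face.

Random objectives use counter-based seeding (`default_rng([seed, index])`),
so runs are reproducible bit-for-bit and any subset can be regenerated
independently; all-zero weight draws are rejected and redrawn.  The weight
rule implements the formula reading of the sampling recipe: each weight is
zero with probability τ and otherwise uniform on (0, 1], with τ itself
uniform on (0, 1] per objective.  The relative SEM diagnostic scales each
flux's standard error by its mean absolute flux (a signed mean would blow
up for sign-flipping fluxes); fluxes below solver precision report zero.

## Ensembles and their thresholds

A response enters **B** if the aconitase flux at the highest glutamine grid
point is below its value at the lowest (minus ε); **C** if the aconitase
spread over the grid is below 5% of its peak magnitude (`NEARLY_CONSTANT_TOL`,
the published analysis states no threshold) and the wiring never grows;
**E** if biomass exceeds ε at any point of the glutamine and/or glucose
scan; **D** = B minus growers.  "Redirection of glucose to lactate" (the
F/G split inside E) is scored mechanistically: PDH falls with glutamine, or
glucose is already fully fermentative (PDH ≈ 0 across the grid) while
lactate still climbs.  An AFR-increase rule was considered and rejected: in
this model the oxidative ATP flux is pinned by the fixed O₂ budget, so the
glycolytic-to-oxidative ATP ratio *falls* with glutamine even as glucose is
visibly diverted from PDH to lactate, which would invert the documented
majority split.  The default grid is nine points on [0, 20] mM h⁻¹ with
baseline 20/20/20 (glucose/glutamine/O₂); resolution is a configuration
knob, only the range is documented.

## What the synthetic fixtures establish

`synthetic.make_toy_network` builds chain, diamond, k-branch and loop-pair
topologies whose optimum, optima count and loop membership are known in
closed form; the enumeration is additionally checked pattern-for-pattern
against an exhaustive basic-feasible-solution oracle on these networks, and
FBA/FVA against cobrapy as an independent implementation.
`make_measurement_table` fabricates fold-change tables with a chosen sign
pattern and noise.  A green test on these fixtures certifies the machinery
— solver, enumeration, classification, scoring — not the biological
fidelity of the bundled network, which rests on the calibration above and
is exercised separately by the acceptance suite.  The packaged measurement
table (`glutamine_shift_measurements_synthetic.tsv`) transcribes only the
published *directions* of the glutamine-limitation experiment; its
magnitudes are invented placeholders for sign-agreement scoring.

## Known limitations

* Quantities tied to the exact coefficients of the original model file (the
  44-optima count, the precise ensemble percentages, a handful of
  metabolite-shift signs, the acetyl-CoA rows of the yield ledger whose
  published sign convention could not be reverse-engineered) are
  approximated, not reproduced; the acceptance tests assert the published
  values and document the misses.
* No compartmentalization, no gene-protein-reaction rules, no nucleotide
  synthesis (the pentose phosphate pathway is therefore optional for the
  optimum), no kinetic or regulatory effects — notably the ATP/ADP
  responsiveness of Complex II that explains the succinate misprediction.
* Loop *removal* is out of scope; `verify_loopless` only reports internal
  cycles able to carry flux with all exchanges closed.
* The blood-gas estimate uses the dimensionally consistent hemoglobin
  arithmetic (15 g/dl ÷ 64 kDa = 2.3 mM, ×4 ≈ 9.4 mM O₂); the source text
  prints an exponent that is off by ten and is treated as a typo.
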