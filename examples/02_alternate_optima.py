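"""Enumerate the directionality-distinct optimal flux patterns at the
critical-oxygen boundary (recursive MILP with integer cuts)."""

import engroflux as ef

net = ef.load_engro1()
net = ef.set_availability(net, "glucose_uptake", 10.0)
net = ef.set_availability(net, "glutamine_uptake", 40.0)
net = ef.set_availability(net, "oxygen_uptake", 38.0)

optima = ef.enumerate_alternate_optima(net, net.biomass_reaction_id, max_count=300)
print(f"{optima.count} directionality-distinct optima, objective {optima.shared_objective_value:.4f}")

i_acon = net.reaction_index(net.named_reactions["aconitase"])
i_pdh = net.reaction_index(net.named_reactions["pdh"])
pats = [v.sign_pattern() for v in optima.vertices]
print("all branched-TCA (reverse aconitase, PDH off):",
      all(p[i_acon] < 0 and p[i_pdh] == 0 for p in pats))
# the variability concentrates in a few redox sub-networks
for pair in (("idh_nad", "idh_nadp"), ("gdh_nad", "gdh_nadp")):
    a, b = (net.reaction_index(net.named_reactions[r]) for r in pair)
    both = sum(1 for p in pats if p[a] != 0 and p[b] != 0)
    print(f"  optima using both {pair[0]} and {pair[1]}: {both}")
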