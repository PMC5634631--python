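"""Maintainer tool: regenerates the bundled synthetic core-model files.

Rebuilds src/engroflux/data/engro1_synthetic.tsv and the role map from the
reaction list below.  The biomass PALM/ATP coefficients are the calibration
knobs (ATP tuned so the critical oxygen at glucose 10 / glutamine 40 is
38.0 mM/h; see docs/methods.md).

Usage: python scripts/build_core_model.py [pros prot palm atp]
"""

import sys
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "engroflux" / "data"

PROS_DEFAULT = 0.25  # fraction of Complex-I electrons diverted to superoxide

# biomass composition knobs (calibrated against the documented critical-O2
# operating point; see scratch/calibrate.py)
PROT_COEF = 6.0
PALM_COEF = 0.37
ATP_COEF = 65.206  # calibrated: critical O2 = 38.0 at G 10 / Q 40
AA_ATP = 4.0  # ATP per amino acid polymerized

A_GROUP = ["ser", "gly", "cys", "ala"]          # glycolysis-derived NEAA
B_GROUP = ["asp", "asn", "glu", "gln", "arg", "pro"]  # glutamine-derived NEAA


def protein_eq(frac_a: float, atp: float = AA_ATP) -> str:
    ca = frac_a / len(A_GROUP)
    cb = (1.0 - frac_a) / len(B_GROUP)
    lhs = " + ".join(f"{ca:.10g} {m}" for m in A_GROUP)
    lhs += " + " + " + ".join(f"{cb:.10g} {m}" for m in B_GROUP)
    lhs += f" + {atp:g} atp"
    return f"{lhs} => protein + {atp:g} adp + {atp:g} pi"


def rows(pros=PROS_DEFAULT, prot=PROT_COEF, palm=PALM_COEF, atp=ATP_COEF):
    c1_atp = 3.0 * (1.0 - pros)
    c1_o2 = 0.5 * (1.0 + pros)  # ROS electrons consume extra O2 (SOD returns half)
    R = []
    add = lambda *a: R.append(a)
    # --- glycolysis and lactic fermentation (10)
    add("HEX1", "hexokinase", "glc + atp => g6p + adp", 0, 1000, "glycolysis")
    add("PGI", "phosphoglucose isomerase", "g6p <=> f6p", -1000, 1000, "glycolysis")
    add("PFK", "phosphofructokinase", "f6p + atp => fdp + adp", 0, 1000, "glycolysis")
    add("FBA", "fructose-bisphosphate aldolase", "fdp <=> dhap + g3p", -1000, 1000, "glycolysis")
    add("TPI", "triose-phosphate isomerase", "dhap <=> g3p", -1000, 1000, "glycolysis")
    add("GAPD", "glyceraldehyde-3P dehydrogenase", "g3p + nad + pi <=> 13dpg + nadh", -1000, 1000, "glycolysis")
    add("PGK", "phosphoglycerate kinase", "13dpg + adp <=> 3pg + atp", -1000, 1000, "glycolysis")
    add("ENO", "phosphoglycerate mutase + enolase", "3pg <=> pep", -1000, 1000, "glycolysis")
    add("PYK", "pyruvate kinase", "pep + adp => pyr + atp", 0, 1000, "glycolysis")
    add("LDH", "lactate dehydrogenase", "pyr + nadh <=> lac + nad", -1000, 1000, "glycolysis")
    # --- TCA cycle (9)
    add("PDH", "pyruvate dehydrogenase", "pyr + nad => accoa + co2 + nadh", 0, 1000, "tca")
    add("CS", "citrate synthase", "accoa + oaa => cit", 0, 1000, "tca")
    add("ACONT", "aconitase", "cit <=> icit", -1000, 1000, "tca")
    add("ICDH_NAD", "isocitrate dehydrogenase (NAD)", "icit + nad <=> akg + co2 + nadh", -1000, 1000, "tca")
    add("AKGD", "alpha-ketoglutarate dehydrogenase", "akg + nad => succoa + co2 + nadh", 0, 1000, "tca")
    add("SUCOAS", "succinyl-CoA synthetase", "succoa + adp + pi <=> succ + atp", -1000, 1000, "tca")
    add("SUCD", "succinate dehydrogenase", "succ + fad => fum + fadh2", 0, 1000, "tca")
    add("FUM", "fumarase", "fum <=> mal", -1000, 1000, "tca")
    add("MDH", "malate dehydrogenase", "mal + nad <=> oaa + nadh", -1000, 1000, "tca")
    # --- oxidative phosphorylation + mitochondrial ROS (2)
    add("CPLX1", "NADH oxidation (Complex I chain, ROS-generating)",
        f"nadh + {c1_o2:.10g} o2 + {c1_atp:.10g} adp + {c1_atp:.10g} pi => nad + {c1_atp:.10g} atp + {pros:.10g} h2o2",
        0, 1000, "oxphos")
    add("CPLX2", "FADH2 oxidation (Complex II chain)",
        "fadh2 + 0.5 o2 + 2 adp + 2 pi => fad + 2 atp", 0, 1000, "oxphos")
    # --- glutamine uptake / reductive carboxylation (4)
    add("GLS", "glutaminase", "gln => glu + nh3", 0, 1000, "glutamine")
    add("GDH_NAD", "glutamate dehydrogenase (NAD)", "glu + nad => akg + nh3 + nadh", 0, 1000, "glutamine")
    add("GDH_NADP", "glutamate dehydrogenase (NADP)", "glu + nadp => akg + nh3 + nadph", 0, 1000, "glutamine")
    add("ICDH_NADP", "isocitrate dehydrogenase (NADP)", "icit + nadp <=> akg + co2 + nadph", -1000, 1000, "glutamine")
    # --- urea cycle (5)
    add("CPS1", "carbamoyl-phosphate synthetase", "nh3 + co2 + 2 atp => cbp + 2 adp + pi", 0, 1000, "urea")
    add("OTC", "ornithine transcarbamylase", "orn + cbp => citr + pi", 0, 1000, "urea")
    add("ASS", "argininosuccinate synthase", "citr + asp + atp => argsuc + adp + pi", 0, 1000, "urea")
    add("ASL", "argininosuccinate lyase", "argsuc <=> arg + fum", -1000, 1000, "urea")
    add("ARGN", "arginase", "arg => orn + urea", 0, 1000, "urea")
    # --- glutathione synthesis and redox (10)
    add("GLUCYS_S", "glutamate-cysteine ligase", "glu + cys + atp => glucys + adp + pi", 0, 1000, "glutathione")
    add("GSHS", "glutathione synthetase", "glucys + gly + atp => gsh + adp + pi", 0, 1000, "glutathione")
    add("GPX", "glutathione peroxidase", "2 gsh + h2o2 => gssg", 0, 1000, "glutathione")
    add("GR", "glutathione reductase", "gssg + nadph => 2 gsh + nadp", 0, 1000, "glutathione")
    add("DM_H2O2", "hydrogen peroxide demand", "h2o2 =>", 0, 1000, "glutathione")
    add("METHCY", "methionine demethylation (lumped)", "met => hcys + for", 0, 1000, "glutathione")
    add("CBS", "cystathionine beta-synthase", "hcys + ser => cyst", 0, 1000, "glutathione")
    add("CTH", "cystathionine gamma-lyase", "cyst => cys + nh3 + obut", 0, 1000, "glutathione")
    add("OBDH", "2-oxobutanoate to succinyl-CoA (lumped)", "obut + nad + atp => succoa + nadh + adp + pi", 0, 1000, "glutathione")
    add("MS", "methionine synthase", "hcys + mlthf => met + thf", 0, 1000, "glutathione")
    # --- fatty acid synthesis (2)
    add("ACL", "ATP-citrate lyase", "cit + atp => accoa_c + oaa + adp + pi", 0, 1000, "fatty acid")
    add("FAS", "palmitate synthesis (lumped)", "8 accoa_c + 14 nadph + 7 atp => palm + 14 nadp + 7 adp + 7 pi", 0, 1000, "fatty acid")
    # --- pentose phosphate pathway (5)
    add("G6PD", "oxidative PPP (lumped)", "g6p + 2 nadp => ru5p + co2 + 2 nadph", 0, 1000, "ppp")
    add("RPI", "ribose-5P isomerase", "ru5p <=> r5p", -1000, 1000, "ppp")
    add("RPE", "ribulose-5P epimerase", "ru5p <=> x5p", -1000, 1000, "ppp")
    add("TKT1", "transketolase/transaldolase (lumped 1)", "x5p + r5p <=> f6p + e4p", -1000, 1000, "ppp")
    add("TKT2", "transketolase (lumped 2)", "x5p + e4p <=> f6p + g3p", -1000, 1000, "ppp")
    # --- non-essential amino acid synthesis (13)
    add("SERS", "serine synthesis (lumped)", "3pg + glu + nad => ser + akg + nadh + pi", 0, 1000, "amino acid")
    add("GHMT", "serine hydroxymethyltransferase", "ser + thf <=> gly + mlthf", -1000, 1000, "amino acid")
    add("MTHFD", "methylene-THF dehydrogenase (NADP)", "mlthf + nadp => for + thf + nadph", 0, 1000, "amino acid")
    add("ALT", "alanine transaminase", "pyr + glu <=> ala + akg", -1000, 1000, "amino acid")
    add("AST", "aspartate transaminase", "oaa + glu <=> asp + akg", -1000, 1000, "amino acid")
    add("ASNS", "asparagine synthetase", "asp + gln + atp => asn + glu + adp + pi", 0, 1000, "amino acid")
    add("ASNASE", "asparaginase", "asn => asp + nh3", 0, 1000, "amino acid")
    add("PROS_NADH", "proline synthesis (NADH)", "glu + atp + 2 nadh => pro + adp + pi + 2 nad", 0, 1000, "amino acid")
    add("PROS_NADPH", "proline synthesis (NADPH)", "glu + atp + 2 nadph => pro + adp + pi + 2 nadp", 0, 1000, "amino acid")
    add("CYSS", "cysteine synthesis (lumped; sulfur not tracked)", "ser => cys", 0, 1000, "amino acid")
    add("GLYCL", "glycine cleavage", "gly + thf + nad => mlthf + co2 + nh3 + nadh", 0, 1000, "amino acid")
    add("ORNS", "ornithine synthesis (lumped)", "2 glu + atp + nadh => orn + akg + adp + pi + nad", 0, 1000, "amino acid")
    add("ODC", "ornithine decarboxylase", "orn => ptrc + co2", 0, 1000, "amino acid")
    # --- anaplerosis / cataplerosis (4)
    add("PEPCK", "PEP carboxykinase", "oaa + atp => pep + co2 + adp", 0, 1000, "anaplerosis")
    add("PC", "pyruvate carboxylase", "pyr + co2 + atp => oaa + adp + pi", 0, 1000, "anaplerosis")
    add("ME_NAD", "malic enzyme (NAD)", "mal + nad => pyr + co2 + nadh", 0, 1000, "anaplerosis")
    add("ME_NADP", "malic enzyme (NADP)", "mal + nadp => pyr + co2 + nadph", 0, 1000, "anaplerosis")
    # --- maintenance, protein, biomass
    add("ATPM", "ATP maintenance", "atp => adp + pi", 0, 1000, "maintenance")
    add("PROT_50A50B", "protein synthesis, standard NEAA mix", protein_eq(0.5), 0, 1000, "protein synthesis")
    add("PROT_80A20B", "protein synthesis, 80/20 NEAA mix", protein_eq(0.8), 0, 0, "protein synthesis")
    add("PROT_20A80B", "protein synthesis, 20/80 NEAA mix", protein_eq(0.2), 0, 0, "protein synthesis")
    add("BIOMASS", "biomass assembly",
        f"{prot:.10g} protein + {palm:.10g} palm + 0.05 gsh + {atp:.10g} atp => biomass + {atp:.10g} adp + {atp:.10g} pi",
        0, 1000, "biomass")
    # --- exchanges (15); uptake written as import, availability = upper bound
    add("EX_glc", "glucose uptake", "=> glc", 0, 20, "exchange")
    add("EX_gln", "glutamine uptake", "=> gln", 0, 20, "exchange")
    add("EX_o2", "oxygen uptake", "=> o2", 0, 20, "exchange")
    add("EX_met", "methionine uptake", "=> met", 0, 1, "exchange")
    add("EX_lac", "lactate efflux", "lac =>", 0, 1000, "exchange")
    add("EX_nh3", "ammonia efflux", "nh3 =>", 0, 1000, "exchange")
    add("EX_urea", "urea efflux", "urea =>", 0, 1000, "exchange")
    add("EX_co2", "CO2 efflux", "co2 =>", 0, 1000, "exchange")
    add("EX_pyr", "pyruvate efflux (closed by default)", "pyr =>", 0, 0, "exchange")
    add("EX_ptrc", "putrescine efflux (closed by default)", "ptrc =>", 0, 0, "exchange")
    add("EX_for", "formate efflux", "for =>", 0, 1000, "exchange")
    add("EX_ala", "alanine efflux (closed by default)", "ala =>", 0, 0, "exchange")
    add("EX_glu", "glutamate efflux (closed by default)", "glu =>", 0, 0, "exchange")
    add("EX_ser", "serine efflux (closed by default)", "ser =>", 0, 0, "exchange")
    add("EX_biomass", "biomass efflux", "biomass =>", 0, 1000, "exchange")
    return R


ROLES = [
    ("aconitase", "ACONT"),
    ("pdh", "PDH"),
    ("lactate_efflux", "EX_lac"),
    ("glucose_uptake", "EX_glc"),
    ("glutamine_uptake", "EX_gln"),
    ("oxygen_uptake", "EX_o2"),
    ("ammonia_efflux", "EX_nh3"),
    ("atp_maintenance", "ATPM"),
    ("complex_i", "CPLX1"),
    ("complex_ii", "CPLX2"),
    ("idh_nad", "ICDH_NAD"),
    ("idh_nadp", "ICDH_NADP"),
    ("malic_enzyme_nad", "ME_NAD"),
    ("malic_enzyme_nadp", "ME_NADP"),
    ("malate_dehydrogenase", "MDH"),
    ("pep_carboxykinase", "PEPCK"),
    ("gdh_nad", "GDH_NAD"),
    ("gdh_nadp", "GDH_NADP"),
    ("biomass", "BIOMASS"),
]


def write(pros=PROS_DEFAULT, prot=PROT_COEF, palm=PALM_COEF, atp=ATP_COEF):
    DATA.mkdir(parents=True, exist_ok=True)
    header = (
        "# Synthetic reconstruction of the ENGRO1 core glucose/glutamine network\n"
        "# (84 reactions, 67 metabolites). This file is a stand-in rebuilt from the\n"
        "# published pathway inventory and calibrated to documented operating\n"
        "# points; it is NOT the original supplementary model file.\n"
        f"# pROS (Complex I electron fraction to superoxide) baked into CPLX1: {pros}\n"
    )
    with open(DATA / "engro1_synthetic.tsv", "w") as fh:
        fh.write(header)
        fh.write("id\tname\tequation\tlower_bound\tupper_bound\tpathway\n")
        for rid, name, eq, lb, ub, pw in rows(pros, prot, palm, atp):
            fh.write(f"{rid}\t{name}\t{eq}\t{lb:g}\t{ub:g}\t{pw}\n")
    with open(DATA / "engro1_synthetic_roles.tsv", "w") as fh:
        fh.write("# role\treaction id (synthetic ENGRO1 reconstruction)\n")
        for role, rid in ROLES:
            fh.write(f"{role}\t{rid}\n")
    print("wrote", DATA / "engro1_synthetic.tsv")


if __name__ == "__main__":
    args = [float(a) for a in sys.argv[1:]]
    write(*args)
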