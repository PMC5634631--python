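"""Parameter scans: growth landscapes, critical oxygen, TCA modes,
sensitivity analyses and the blood-gas oxygen arithmetic.

Availability ratios used throughout: O2GR = oxygen/glucose availability,
QGR = glutamine/glucose, CGR = Complex-I capacity/glucose.  The *critical*
oxygen level at a given glucose/glutamine supply is the availability at
which, under growth maximization, pyruvate dehydrogenase flux reaches zero
and lactate secretion peaks: all glucose is fermented and the whole oxygen
budget partially oxidizes glutamine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import FLUX_EPSILON, FluxState, _LPProblem, fba_optimize, fva
from .network import MetabolicNetwork

__all__ = [
    "CriticalPoint",
    "BloodGasParams",
    "growth_landscape",
    "find_critical_o2",
    "constrained_tca_modes",
    "set_pros",
    "set_biomass_atp",
    "set_biomass_variant",
    "sensitivity_scans",
    "blood_oxygen_availability",
    "BIOMASS_VARIANTS",
]

_ROLE = {
    "glucose": "glucose_uptake",
    "glutamine": "glutamine_uptake",
    "oxygen": "oxygen_uptake",
}

#: biomass-variant id -> protein reaction id of the bundled reconstruction
BIOMASS_VARIANTS = {
    "NEAA_STD": "PROT_50A50B",
    "NEAA_80_20": "PROT_80A20B",
    "NEAA_20_80": "PROT_20A80B",
}


# ---------------------------------------------------------------------------
# landscapes


def growth_landscape(
    net: MetabolicNetwork,
    axes: dict[str, list[float]],
    fva_check: bool = False,
) -> pd.DataFrame:
    """Biomass-maximizing FBA over a product grid of availabilities.

    ``axes`` maps nutrient names (glucose/glutamine/oxygen) to value lists.
    Each record carries the optimal biomass plus the tracked fluxes (lactate
    efflux, PDH, aconitase, glutamine uptake, ammonia efflux) and, with
    ``fva_check=True``, the FVA range of each tracked flux at the optimum so
    that only variability-free fluxes are interpreted.  Infeasible points
    are recorded with zero growth.
    """
    for nutrient in axes:
        if nutrient not in _ROLE:
            raise KeyError(f"unknown axis {nutrient!r}")
    tracked = {
        "lactate": "lactate_efflux",
        "pdh": "pdh",
        "aconitase": "aconitase",
        "glutamine_uptake": "glutamine_uptake",
        "ammonia_efflux": "ammonia_efflux",
    }
    work = net.copy()
    lp = _LPProblem(work)
    biomass = work.biomass_reaction_id
    records = []
    names = list(axes)
    for combo in itertools.product(*(axes[n] for n in names)):
        for nutrient, value in zip(names, combo):
            rid = work.named_reactions[_ROLE[nutrient]]
            lp.set_bounds(rid, 0.0, float(value))
        status, opt, flux = lp.solve({biomass: 1.0})
        rec = dict(zip(names, combo))
        if "glucose" in rec and rec["glucose"] > 0:
            rec["o2gr"] = rec.get("oxygen", np.nan) / rec["glucose"]
            rec["qgr"] = rec.get("glutamine", np.nan) / rec["glucose"]
        rec["status"] = status
        rec["biomass"] = opt if status == "optimal" else 0.0
        if status == "optimal":
            for label, role in tracked.items():
                rec[label] = flux[work.reaction_index(work.named_reactions[role])]
        records.append(rec)
    df = pd.DataFrame(records)
    if fva_check:
        ranges = []
        for _, rec in df.iterrows():
            scen = net.copy()
            for nutrient in names:
                scen.set_bounds(
                    scen.named_reactions[_ROLE[nutrient]], upper=float(rec[nutrient])
                )
            if rec["status"] != "optimal":
                ranges.append({f"range_{k}": np.nan for k in tracked})
                continue
            res = fva(
                scen,
                scen.biomass_reaction_id,
                reactions=[scen.named_reactions[r] for r in tracked.values()],
            )
            ranges.append(
                {
                    f"range_{label}": res.range(scen.named_reactions[role])
                    for label, role in tracked.items()
                }
            )
        df = pd.concat([df, pd.DataFrame(ranges)], axis=1)
    return df


# ---------------------------------------------------------------------------
# critical oxygen


@dataclass(frozen=True)
class CriticalPoint:
    glucose: float
    glutamine: float
    critical_oxygen: float
    criterion: str  # lactate-max | pdh-zero

    @property
    def o2gr(self) -> float:
        return self.critical_oxygen / self.glucose


def _solve_at_o2(lp: _LPProblem, net: MetabolicNetwork, o2: float):
    lp.set_bounds(net.named_reactions["oxygen_uptake"], 0.0, float(o2))
    return lp.solve({net.biomass_reaction_id: 1.0})


def find_critical_o2(
    net: MetabolicNetwork,
    glucose: float,
    glutamine: float,
    criterion: str = "pdh-zero",
    resolution: float = 0.1,
    o2_max: float | None = None,
    epsilon: float = 1e-5,
) -> CriticalPoint:
    """Locate the critical oxygen availability at fixed glucose/glutamine.

    ``pdh-zero``: the largest oxygen availability at which the
    growth-maximizing flux keeps PDH at zero (coarse 1 mM/h scan, then
    bisection to ``resolution``).  ``lactate-max``: the availability at
    which lactate secretion under growth maximization peaks (coarse scan,
    then a fine scan at ``resolution`` around the peak).
    """
    if glucose <= 0 or glutamine <= 0:
        raise ValueError("glucose and glutamine must be positive")
    if criterion not in ("pdh-zero", "lactate-max"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if o2_max is None:
        o2_max = 6.0 * glucose + 4.5 * glutamine  # full-respiration ceiling
    work = net.copy()
    work.set_bounds(work.named_reactions["glucose_uptake"], upper=glucose)
    work.set_bounds(work.named_reactions["glutamine_uptake"], upper=glutamine)
    lp = _LPProblem(work)
    i_pdh = work.reaction_index(work.named_reactions["pdh"])
    i_lac = work.reaction_index(work.named_reactions["lactate_efflux"])

    coarse = np.arange(1.0, o2_max + 1.0, 1.0)
    if criterion == "pdh-zero":
        def pdh_at(o2: float) -> float:
            status, _, flux = _solve_at_o2(lp, work, o2)
            return flux[i_pdh] if status == "optimal" else 0.0

        below = [o for o in coarse if pdh_at(o) <= epsilon]
        if not below or below[-1] == coarse[-1]:
            raise RuntimeError(
                f"PDH never activates in [1, {o2_max}]: criterion not met"
            )
        lo, hi = below[-1], below[-1] + 1.0
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if pdh_at(mid) <= epsilon:
                lo = mid
            else:
                hi = mid
        crit = 0.5 * (lo + hi)
    else:
        def lac_at(o2: float) -> float:
            status, _, flux = _solve_at_o2(lp, work, o2)
            return flux[i_lac] if status == "optimal" else -np.inf

        vals = [lac_at(o) for o in coarse]
        k = int(np.argmax(vals))
        if k in (0, len(coarse) - 1):
            raise RuntimeError(
                f"lactate maximum not interior to [1, {o2_max}]: criterion not met"
            )
        fine = np.arange(coarse[k] - 1.0, coarse[k] + 1.0 + resolution / 2, resolution)
        crit = float(fine[int(np.argmax([lac_at(o) for o in fine]))])
    return CriticalPoint(
        glucose=glucose,
        glutamine=glutamine,
        critical_oxygen=round(float(crit), 6),
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# constrained TCA modes


_SCENARIOS = {
    "control": {},
    "no-lactate": {"lactate_efflux": 0.0},
    "no-glucose": {"glucose_uptake": 0.0},
    "no-glucose-no-lactate-pyruvate-allowed": {
        "glucose_uptake": 0.0,
        "lactate_efflux": 0.0,
        "EX_pyr": 1000.0,
    },
}


def constrained_tca_modes(
    net: MetabolicNetwork,
    scenario: str = "control",
    objective: str = "biomass",
    epsilon: float = FLUX_EPSILON,
) -> tuple[FluxState, str]:
    """Solve one constrained optimization and label its TCA flux mode.

    Modes: ``branched`` (reverse aconitase feeding lipogenesis plus a
    clockwise AKG->malate limb), ``cyclic`` (forward aconitase with citrate
    synthase), ``truncated`` (neither: AKG enters mid-cycle and no
    reductive carboxylation runs).
    """
    if scenario not in _SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; one of {sorted(_SCENARIOS)}")
    if objective not in ("biomass", "ATP"):
        raise ValueError("objective must be 'biomass' or 'ATP'")
    work = net.copy()
    for role, ub in _SCENARIOS[scenario].items():
        rid = work.named_reactions.get(role, role)  # role name or raw id
        work.set_bounds(rid, upper=ub)
    target = (
        work.biomass_reaction_id
        if objective == "biomass"
        else work.named_reactions["atp_maintenance"]
    )
    state = fba_optimize(work, target)
    if state.status != "optimal":
        return state, "infeasible"
    acon = state[work.named_reactions["aconitase"]]
    akgd = state["AKGD"] if work.has_reaction("AKGD") else 0.0
    if acon < -epsilon and akgd > epsilon:
        mode = "branched"
    elif acon > epsilon:
        mode = "cyclic"
    else:
        mode = "truncated"
    return state, mode


# ---------------------------------------------------------------------------
# model variants for sensitivity scans


def set_pros(net: MetabolicNetwork, pros: float, inplace: bool = False) -> MetabolicNetwork:
    """Rewrite the Complex I lump for a new superoxide fraction ``pROS``.

    Stoichiometry: ``nadh + 0.5 (1+p) o2 -> nad + 3 (1-p) atp + p h2o2``;
    the ATP-coupled adp/pi terms follow the ATP coefficient.
    """
    if not (0.0 <= pros < 1.0):
        raise ValueError("pROS must be in [0, 1)")
    out = net if inplace else net.copy()
    rxn = out.role("complex_i")
    atp = 3.0 * (1.0 - pros)
    rxn.stoichiometry = {
        "nadh": -1.0,
        "o2": -0.5 * (1.0 + pros),
        "adp": -atp,
        "pi": -atp,
        "nad": 1.0,
        "atp": atp,
        "h2o2": pros,
    }
    if pros == 0.0:
        del rxn.stoichiometry["h2o2"]
    return out


def set_biomass_atp(
    net: MetabolicNetwork, atp_coefficient: float, inplace: bool = False
) -> MetabolicNetwork:
    """Set the growth-associated ATP demand of the biomass reaction."""
    out = net if inplace else net.copy()
    rxn = out.role("biomass")
    for met, sign in (("atp", -1.0), ("adp", 1.0), ("pi", 1.0)):
        rxn.stoichiometry[met] = sign * atp_coefficient
    return out


def set_biomass_variant(
    net: MetabolicNetwork, variant_id: str, inplace: bool = False
) -> MetabolicNetwork:
    """Open exactly one protein-composition variant, closing the others."""
    if variant_id not in BIOMASS_VARIANTS:
        raise KeyError(f"unknown variant {variant_id!r}")
    out = net if inplace else net.copy()
    for vid, rid in BIOMASS_VARIANTS.items():
        out.set_bounds(rid, upper=1000.0 if vid == variant_id else 0.0)
    return out


def sensitivity_scans(
    net: MetabolicNetwork,
    axis: str,
    values: list,
) -> pd.DataFrame:
    """Optimal growth plus FVA lactate range along one model-parameter axis.

    ``axis`` is one of ``pros``, ``atp_biomass_coefficient``,
    ``biomass_variant`` or ``complexI_capacity``.
    """
    builders = {
        "pros": set_pros,
        "atp_biomass_coefficient": set_biomass_atp,
        "biomass_variant": set_biomass_variant,
        "complexI_capacity": lambda n, v: _cap_complex_i(n, v),
    }
    if axis not in builders:
        raise KeyError(f"unknown axis {axis!r}")
    records = []
    for value in values:
        variant = builders[axis](net, value)
        lac = variant.named_reactions["lactate_efflux"]
        state = fba_optimize(variant, variant.biomass_reaction_id)
        rec = {"axis": axis, "value": value, "status": state.status}
        if state.status == "optimal":
            res = fva(variant, variant.biomass_reaction_id, reactions=[lac])
            rec.update(
                biomass=state.objective_value,
                lactate=state[lac],
                lactate_min=res.minimum[lac],
                lactate_max=res.maximum[lac],
                pdh=state[variant.named_reactions["pdh"]],
                aconitase=state[variant.named_reactions["aconitase"]],
            )
        records.append(rec)
    return pd.DataFrame(records)


def _cap_complex_i(net: MetabolicNetwork, capacity: float) -> MetabolicNetwork:
    out = net.copy()
    out.set_bounds(out.named_reactions["complex_i"], upper=float(capacity))
    return out


# ---------------------------------------------------------------------------
# blood-gas arithmetic


@dataclass(frozen=True)
class BloodGasParams:
    """Inputs of the in-vivo oxygen-vs-glucose availability estimate.

    Defaults: 20 ml O2 gas per 100 ml blood at 760 mmHg and 310 K (ideal
    gas law with R = 62 L mmHg K^-1 mol^-1); hemoglobin 15 g/100 ml at
    64 kDa binding 4 O2 at saturation; blood glucose ~5 mmol/L.
    """

    pressure_mmHg: float = 760.0
    gas_volume_l_per_l_blood: float = 0.2
    temperature_K: float = 310.0
    gas_constant: float = 62.0  # L mmHg / (K mol)
    hemoglobin_g_per_dl: float = 15.0
    hemoglobin_mw: float = 64000.0  # g/mol
    o2_per_hemoglobin: float = 4.0
    blood_glucose_mM: float = 5.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def blood_oxygen_availability(params: BloodGasParams = BloodGasParams()) -> dict[str, float]:
    """Blood oxygen content two ways, and the O2:glucose molar ratio.

    Gas-law route: n = PV/(RT) per liter of blood.  Hemoglobin route:
    [Hb] / MW x 4 (dimensionally consistent form; the source text prints a
    10^-4 exponent for the 15 g/dl / 64 kDa quotient, which is a typo for
    10^-3 -- only the latter yields the stated ~9 mmol/L).
    """
    p = params
    gas_mM = 1000.0 * p.pressure_mmHg * p.gas_volume_l_per_l_blood / (
        p.gas_constant * p.temperature_K
    )
    hb_mM = 1000.0 * (10.0 * p.hemoglobin_g_per_dl / p.hemoglobin_mw) * p.o2_per_hemoglobin
    return {
        "oxygen_gas_law_mM": gas_mM,
        "oxygen_hemoglobin_mM": hb_mM,
        "o2_glucose_ratio": gas_mM / p.blood_glucose_mM,
    }
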