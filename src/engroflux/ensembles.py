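"""Nutrient-perturbation scans of sampled wirings and ensemble classification.

A *metabolic response* is the set of flux changes one sampled objective
(wiring) shows across a grid of glucose or glutamine availabilities, with
the other nutrient and oxygen held at baseline.  Responses are filtered into
ensembles with Boolean rules:

========  ==================================================================
A         the whole population
B         forward aconitase flux reduced by glutamine (TCA-as-a-cycle damped)
C         aconitase nearly constant, and no growth anywhere on the grid
D         B members that never grow
E         responses that grow at at least one grid point
F         growing, without redirection of glucose to lactate
G         growing, with glutamine-driven reductive carboxylation plus
          redirection of glucose to lactate (the Warburg-like majority)
========  ==================================================================

AFR is the glycolytic-to-oxidative ATP flux ratio, the aerobic-glycolysis
proxy: substrate-level ATP formed net by the glycolytic reactions over ATP
formed by the respiratory-chain reactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import _LPProblem, FluxState, FLUX_EPSILON
from .network import MetabolicNetwork
from .sampling import RandomObjective

__all__ = [
    "PerturbationGrid",
    "ResponseSet",
    "AFRValue",
    "scan_responses",
    "classify_ensembles",
    "summarize_ensemble",
    "afr",
    "TRACKED_ROLES",
    "NEARLY_CONSTANT_TOL",
]

#: roles whose fluxes every scan records
TRACKED_ROLES = ("aconitase", "biomass", "lactate_efflux", "oxygen_uptake", "pdh")

#: "nearly constant" aconitase: spread below this fraction of the peak |flux|
NEARLY_CONSTANT_TOL = 0.05

_NUTRIENT_ROLE = {
    "glucose": "glucose_uptake",
    "glutamine": "glutamine_uptake",
    "oxygen": "oxygen_uptake",
}


@dataclass(frozen=True)
class PerturbationGrid:
    """Availability grid for one nutrient; the others stay at baseline."""

    varied_nutrient: str = "glutamine"
    values: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)
    baseline: tuple[tuple[str, float], ...] = (
        ("glucose", 20.0),
        ("glutamine", 20.0),
        ("oxygen", 20.0),
    )

    def __post_init__(self) -> None:
        if self.varied_nutrient not in _NUTRIENT_ROLE:
            raise ValueError(f"unknown nutrient {self.varied_nutrient!r}")
        if list(self.values) != sorted(self.values):
            raise ValueError("grid values must be ascending")


@dataclass
class AFRValue:
    """Glycolytic and oxidative ATP fluxes and their ratio (inf when there
    is glycolytic but no oxidative ATP; 0 when there is none glycolytic)."""

    glycolytic_atp: float
    oxidative_atp: float
    ratio: float


def _atp_vectors(net: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Net ATP production coefficient per reaction, split into the glycolytic
    and oxidative-phosphorylation pathway groups."""
    glyc = np.zeros(net.n_reactions)
    oxid = np.zeros(net.n_reactions)
    for j, r in enumerate(net.reactions):
        coef = r.stoichiometry.get("atp", 0.0)
        if r.pathway == "glycolysis":
            glyc[j] = coef
        elif r.pathway == "oxphos":
            oxid[j] = coef
    return glyc, oxid


def _ratio(g: float, o: float, eps: float = FLUX_EPSILON) -> float:
    if o > eps:
        return g / o
    return float("inf") if g > eps else 0.0


def afr(state: FluxState, net: MetabolicNetwork) -> AFRValue:
    """Glycolytic-to-oxidative ATP flux ratio of one flux state."""
    glyc_vec, oxid_vec = _atp_vectors(net)
    flux = np.array([state.fluxes[r.id] for r in net.reactions])
    g = float(glyc_vec @ flux)
    o = float(oxid_vec @ flux)
    return AFRValue(glycolytic_atp=g, oxidative_atp=o, ratio=_ratio(g, o))


@dataclass
class ResponseSet:
    """Tracked fluxes of many wirings across one perturbation grid.

    ``data[i, k, t]`` is the flux of tracked role ``t`` for objective ``i``
    at grid point ``k``; ``afr[i, k]`` the corresponding ATP flux ratio.
    """

    grid: PerturbationGrid
    tracked: tuple[str, ...]
    data: np.ndarray
    afr: np.ndarray
    objectives: list[RandomObjective]
    statuses: np.ndarray  # (n_obj, n_points) of {0 optimal, 1 failed}

    @property
    def n_objectives(self) -> int:
        return self.data.shape[0]

    def role(self, role: str) -> np.ndarray:
        """(n_objectives, n_points) matrix for one tracked role."""
        return self.data[:, :, self.tracked.index(role)]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t, role in enumerate(self.tracked):
            df = pd.DataFrame(self.data[:, :, t], columns=self.grid.values)
            df["role"] = role
            df["objective"] = range(self.n_objectives)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def scan_responses(
    net: MetabolicNetwork,
    objectives: list[RandomObjective],
    grid: PerturbationGrid,
) -> ResponseSet:
    """FBA-solve every objective at every grid point of one nutrient scan."""
    work = net.copy()
    for nutrient, value in grid.baseline:
        rid = work.named_reactions[_NUTRIENT_ROLE[nutrient]]
        work.set_bounds(rid, upper=value)
    varied_rid = work.named_reactions[_NUTRIENT_ROLE[grid.varied_nutrient]]
    lp = _LPProblem(work)
    tracked_idx = [work.reaction_index(work.named_reactions[r]) for r in TRACKED_ROLES]
    glyc_vec, oxid_vec = _atp_vectors(work)

    n_obj, n_pts = len(objectives), len(grid.values)
    data = np.full((n_obj, n_pts, len(TRACKED_ROLES)), np.nan)
    afr_mat = np.full((n_obj, n_pts), np.nan)
    statuses = np.zeros((n_obj, n_pts), dtype=np.int8)
    for k, value in enumerate(grid.values):
        lp.set_bounds(
            work.reaction(varied_rid).id, work.reaction(varied_rid).lower_bound, value
        )
        for i, obj in enumerate(objectives):
            status, _, flux = lp.solve(obj.weights)
            if status != "optimal":
                statuses[i, k] = 1
                continue
            data[i, k, :] = flux[tracked_idx]
            afr_mat[i, k] = _ratio(float(glyc_vec @ flux), float(oxid_vec @ flux))
    return ResponseSet(
        grid=grid,
        tracked=TRACKED_ROLES,
        data=data,
        afr=afr_mat,
        objectives=objectives,
        statuses=statuses,
    )


def classify_ensembles(
    gln_scan: ResponseSet,
    glc_scan: ResponseSet | None = None,
    epsilon: float = FLUX_EPSILON,
    constant_tol: float = NEARLY_CONSTANT_TOL,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign A-G ensemble flags to every response and report fractions.

    ``gln_scan`` must vary glutamine; ``glc_scan`` (optional) extends the
    growth test of Ensemble E to the glucose scan, as in the published
    definition ("grows for at least one of the simulated glutamine and/or
    glucose uptake rates").
    """
    if gln_scan.grid.varied_nutrient != "glutamine":
        raise ValueError("first scan must vary glutamine")
    acon = gln_scan.role("aconitase")
    biomass = gln_scan.role("biomass")
    grows = (biomass > epsilon).any(axis=1)
    if glc_scan is not None:
        grows |= (glc_scan.role("biomass") > epsilon).any(axis=1)

    reduced = acon[:, -1] < acon[:, 0] - epsilon  # B: damped by glutamine
    spread = acon.max(axis=1) - acon.min(axis=1)
    peak = np.abs(acon).max(axis=1)
    nearly_constant = spread <= np.maximum(constant_tol * peak, epsilon)

    rc = acon[:, -1] < -epsilon  # reverse aconitase at highest glutamine
    # redirection of glucose to lactate: PDH collapses as glutamine rises, or
    # glucose is already fully fermentative (PDH ~ 0 on the whole grid) while
    # lactate output still climbs.  (An AFR-increase rule misclassifies here:
    # with the O2 budget saturated, oxidative ATP is pinned and AFR falls with
    # glutamine even as glucose is visibly diverted to lactate.)
    pdh = gln_scan.role("pdh")
    lac = gln_scan.role("lactate_efflux")
    pdh_fall = pdh[:, -1] < pdh[:, 0] - epsilon
    fully_fermentative = np.abs(pdh).max(axis=1) <= 1e-3
    lac_rise = lac[:, -1] > lac[:, 0] + epsilon
    redirect = pdh_fall | (fully_fermentative & lac_rise)

    flags = pd.DataFrame(
        {
            "A": np.ones(len(acon), dtype=bool),
            "B": reduced,
            "C": nearly_constant & ~grows,
            "D": reduced & ~grows,
            "E": grows,
            "F": grows & ~redirect,
            "G": grows & redirect & rc,
        }
    )
    flags.index.name = "objective"
    n = len(flags)
    fractions = {k: float(flags[k].mean()) for k in flags.columns}
    fractions["E_without_redirection"] = (
        float((flags["F"]).sum()) / max(int(flags["E"].sum()), 1)
    )
    fractions["E_with_rc_and_redirection"] = (
        float((flags["G"]).sum()) / max(int(flags["E"].sum()), 1)
    )
    fractions["n"] = float(n)
    return flags, fractions


def summarize_ensemble(
    rs: ResponseSet, member_mask: np.ndarray | pd.Series | None = None
) -> pd.DataFrame:
    """Mean tracked-flux (and AFR) curves over an ensemble, per grid point."""
    mask = (
        np.ones(rs.n_objectives, dtype=bool)
        if member_mask is None
        else np.asarray(member_mask, dtype=bool)
    )
    if mask.sum() == 0:
        raise ValueError("empty ensemble")
    out = {}
    for t, role in enumerate(rs.tracked):
        out[role] = np.nanmean(rs.data[mask, :, t], axis=0)
    finite_afr = np.where(np.isfinite(rs.afr), rs.afr, np.nan)
    out["afr"] = np.nanmean(finite_afr[mask, :], axis=0)
    df = pd.DataFrame(out, index=list(rs.grid.values))
    df.index.name = rs.grid.varied_nutrient
    return df
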