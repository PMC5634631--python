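"""Linear-programming engine: FBA, FVA and alternate-optima enumeration.

All solves go through GLPK (via ``swiglpk``) on a problem object that is
built once per network and then re-used with warm starts, which keeps the
ensemble stage (tens of thousands of solves) fast and bit-reproducible: for
a fixed reaction ordering and solver configuration the returned vertex is
deterministic.

Numerical conventions (single named constants, because the alternate-optima
count is sensitive to them):

* ``FLUX_EPSILON`` -- a flux with absolute value below this is "zero" for
  directionality classification;
* ``ACTIVATION_EPS`` -- the minimum activity a direction indicator enforces
  in the enumeration MILP;
* ``OBJECTIVE_RTOL`` -- relative tolerance on the shared optimal objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import swiglpk as glpk

from .network import MetabolicNetwork, Reaction

__all__ = [
    "Objective",
    "FluxState",
    "FVAResult",
    "OptimaSet",
    "fba_optimize",
    "fva",
    "enumerate_alternate_optima",
    "constrain_biomass_production",
    "add_virtual_efflux",
    "FLUX_EPSILON",
    "ACTIVATION_EPS",
    "OBJECTIVE_RTOL",
]

FLUX_EPSILON = 1e-6
ACTIVATION_EPS = 1e-4
OBJECTIVE_RTOL = 1e-8


@dataclass(frozen=True)
class Objective:
    """A weighted sum of fluxes to maximize."""

    weights: dict[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("objective needs at least one nonzero weight")
        if self.sense != "maximize":
            raise ValueError("only maximization objectives are supported")


@dataclass
class FluxState:
    """One steady-state flux vector with its objective value."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def sign_pattern(self, epsilon: float = FLUX_EPSILON) -> tuple[int, ...]:
        """The -1/0/+1 directionality pattern of the flux vector."""
        return tuple(
            0 if abs(v) <= epsilon else (1 if v > 0 else -1)
            for v in self.fluxes.values()
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed (fraction of) optimum."""

    minimum: dict[str, float]
    maximum: dict[str, float]
    fixed_objective_value: float

    def range(self, rxn_id: str) -> float:
        return self.maximum[rxn_id] - self.minimum[rxn_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"minimum": self.minimum, "maximum": self.maximum})
        df["range"] = df["maximum"] - df["minimum"]
        df.index.name = "reaction"
        return df


@dataclass
class OptimaSet:
    """Directionality-distinct alternate optima sharing one objective value."""

    vertices: list[FluxState]
    shared_objective_value: float
    complete: bool = True

    @property
    def count(self) -> int:
        return len(self.vertices)

    def sign_patterns(self, epsilon: float = FLUX_EPSILON) -> set[tuple[int, ...]]:
        return {v.sign_pattern(epsilon) for v in self.vertices}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([v.fluxes for v in self.vertices]).T


# ---------------------------------------------------------------------------
# GLPK problem wrapper


def _status_name(code: int) -> str:
    if code == glpk.GLP_OPT:
        return "optimal"
    if code == glpk.GLP_UNBND:
        return "unbounded"
    return "infeasible"


class _LPProblem:
    """A reusable GLPK simplex problem for one network.

    Rows 1..m fix ``S v = 0``; an optional extra row pins a linear form (used
    by FVA to hold the base objective at its optimum).  Column bounds can be
    changed in place; the previous basis is re-used.
    """

    def __init__(self, net: MetabolicNetwork) -> None:
        self.net = net
        self.rxn_ids = [r.id for r in net.reactions]
        self._col = {rid: j + 1 for j, rid in enumerate(self.rxn_ids)}
        m, n = net.n_metabolites, net.n_reactions
        self.prob = glpk.glp_create_prob()
        glpk.glp_set_obj_dir(self.prob, glpk.GLP_MAX)
        glpk.glp_add_rows(self.prob, m)
        for i in range(1, m + 1):
            glpk.glp_set_row_bnds(self.prob, i, glpk.GLP_FX, 0.0, 0.0)
        glpk.glp_add_cols(self.prob, n)
        lb, ub = net.bounds()
        for j in range(n):
            self._set_col_bounds(j + 1, lb[j], ub[j])
        S = net.stoichiometric_matrix()
        nz = np.nonzero(S)
        nnz = len(nz[0])
        ia = glpk.intArray(nnz + 1)
        ja = glpk.intArray(nnz + 1)
        ar = glpk.doubleArray(nnz + 1)
        for k, (i, j) in enumerate(zip(nz[0], nz[1]), start=1):
            ia[k] = int(i) + 1
            ja[k] = int(j) + 1
            ar[k] = float(S[i, j])
        glpk.glp_load_matrix(self.prob, nnz, ia, ja, ar)
        self._obj_row: int | None = None
        self.smcp = glpk.glp_smcp()
        glpk.glp_init_smcp(self.smcp)
        self.smcp.msg_lev = glpk.GLP_MSG_OFF
        self.smcp.tol_bnd = 1e-9
        self.smcp.tol_dj = 1e-9
        glpk.glp_std_basis(self.prob)

    def __del__(self) -> None:  # pragma: no cover
        try:
            glpk.glp_delete_prob(self.prob)
        except Exception:
            pass

    def _set_col_bounds(self, j: int, lo: float, hi: float) -> None:
        lo, hi = float(lo), float(hi)
        if lo == hi:
            glpk.glp_set_col_bnds(self.prob, j, glpk.GLP_FX, lo, hi)
        elif np.isinf(lo) and np.isinf(hi):
            glpk.glp_set_col_bnds(self.prob, j, glpk.GLP_FR, 0.0, 0.0)
        elif np.isinf(lo):
            glpk.glp_set_col_bnds(self.prob, j, glpk.GLP_UP, 0.0, hi)
        elif np.isinf(hi):
            glpk.glp_set_col_bnds(self.prob, j, glpk.GLP_LO, lo, 0.0)
        else:
            glpk.glp_set_col_bnds(self.prob, j, glpk.GLP_DB, lo, hi)

    def set_bounds(self, rxn_id: str, lo: float, hi: float) -> None:
        self._set_col_bounds(self._col[rxn_id], lo, hi)

    def sync_bounds(self) -> None:
        lb, ub = self.net.bounds()
        for j in range(len(self.rxn_ids)):
            self._set_col_bounds(j + 1, lb[j], ub[j])

    def set_objective_row(self, weights: dict[str, float], lower: float | None) -> None:
        """Pin ``sum(w_i v_i) >= lower`` as an extra constraint row (FVA)."""
        if self._obj_row is None:
            self._obj_row = glpk.glp_add_rows(self.prob, 1)
        n = len(weights)
        ind = glpk.intArray(n + 1)
        val = glpk.doubleArray(n + 1)
        for k, (rid, w) in enumerate(weights.items(), start=1):
            ind[k] = self._col[rid]
            val[k] = float(w)
        glpk.glp_set_mat_row(self.prob, self._obj_row, n, ind, val)
        if lower is None:
            glpk.glp_set_row_bnds(self.prob, self._obj_row, glpk.GLP_FR, 0.0, 0.0)
        else:
            glpk.glp_set_row_bnds(self.prob, self._obj_row, glpk.GLP_LO, lower, 0.0)

    def clear_objective_row(self) -> None:
        if self._obj_row is not None:
            glpk.glp_set_row_bnds(self.prob, self._obj_row, glpk.GLP_FR, 0.0, 0.0)

    def solve(
        self, weights: dict[str, float], maximize: bool = True
    ) -> tuple[str, float, np.ndarray]:
        glpk.glp_set_obj_dir(self.prob, glpk.GLP_MAX if maximize else glpk.GLP_MIN)
        for j in range(1, len(self.rxn_ids) + 1):
            glpk.glp_set_obj_coef(self.prob, j, 0.0)
        for rid, w in weights.items():
            glpk.glp_set_obj_coef(self.prob, self._col[rid], float(w))
        ret = glpk.glp_simplex(self.prob, self.smcp)
        if ret != 0 or glpk.glp_get_status(self.prob) not in (
            glpk.GLP_OPT,
            glpk.GLP_UNBND,
        ):
            # a stale or ill-conditioned warm basis can yield a spurious
            # failure/infeasibility: rebuild the basis and retry, then once
            # more through the presolver before trusting the verdict
            glpk.glp_std_basis(self.prob)
            ret = glpk.glp_simplex(self.prob, self.smcp)
            if ret != 0 or glpk.glp_get_status(self.prob) not in (
                glpk.GLP_OPT,
                glpk.GLP_UNBND,
            ):
                fresh = glpk.glp_smcp()
                glpk.glp_init_smcp(fresh)
                fresh.msg_lev = glpk.GLP_MSG_OFF
                fresh.presolve = glpk.GLP_ON
                ret = glpk.glp_simplex(self.prob, fresh)
                if ret != 0:
                    return "infeasible", float("nan"), np.full(len(self.rxn_ids), np.nan)
        status = _status_name(glpk.glp_get_status(self.prob))
        if status != "optimal":
            return status, float("nan"), np.full(len(self.rxn_ids), np.nan)
        obj = glpk.glp_get_obj_val(self.prob)
        flux = np.array(
            [glpk.glp_get_col_prim(self.prob, j) for j in range(1, len(self.rxn_ids) + 1)]
        )
        return status, obj, flux


# ---------------------------------------------------------------------------
# public operations


def _as_objective(obj: Objective | dict[str, float] | str, net: MetabolicNetwork) -> Objective:
    if isinstance(obj, Objective):
        return obj
    if isinstance(obj, str):
        return Objective({obj: 1.0})
    return Objective(dict(obj))


def fba_optimize(
    net: MetabolicNetwork,
    obj: Objective | dict[str, float] | str,
    lp: _LPProblem | None = None,
) -> FluxState:
    """Maximize a weighted sum of fluxes subject to ``S v = 0`` and bounds.

    Returns one optimal vertex; which vertex is returned is deterministic for
    a fixed reaction ordering and solver configuration.  An existing
    ``_LPProblem`` can be passed to re-use its warm-started basis.
    """
    objective = _as_objective(obj, net)
    if lp is None:
        lp = _LPProblem(net)
    status, objval, flux = lp.solve(objective.weights)
    fluxes = dict(zip(lp.rxn_ids, flux))
    return FluxState(fluxes=fluxes, objective_value=objval, status=status)


def fva(
    net: MetabolicNetwork,
    obj: Objective | dict[str, float] | str,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
    lp: _LPProblem | None = None,
) -> FVAResult:
    """Per-reaction flux ranges with the objective held at (a fraction of)
    its optimum.  The default fraction 1.0 fixes maximal growth exactly."""
    if not (0.0 < fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    objective = _as_objective(obj, net)
    if lp is None:
        lp = _LPProblem(net)
    status, opt, _ = lp.solve(objective.weights)
    if status != "optimal":
        raise RuntimeError(f"base FBA problem is {status}")
    floor = fraction_of_optimum * opt
    # tiny slack keeps the fixed-optimum face numerically non-empty
    floor -= 1e-9 * max(1.0, abs(opt))
    lp.set_objective_row(objective.weights, floor)
    targets = reactions if reactions is not None else lp.rxn_ids
    vmin: dict[str, float] = {}
    vmax: dict[str, float] = {}
    try:
        for rid in targets:
            _, hi, _ = lp.solve({rid: 1.0}, maximize=True)
            _, lo, _ = lp.solve({rid: 1.0}, maximize=False)
            vmin[rid], vmax[rid] = lo, hi
    finally:
        lp.clear_objective_row()
    return FVAResult(minimum=vmin, maximum=vmax, fixed_objective_value=opt)


def constrain_biomass_production(
    net: MetabolicNetwork, min_flux: float, inplace: bool = False
) -> MetabolicNetwork:
    """Force biomass to be produced at a rate of at least ``min_flux``."""
    if min_flux < 0:
        raise ValueError("min_flux must be non-negative")
    out = net if inplace else net.copy()
    if out.biomass_reaction_id is None:
        raise ValueError("network has no biomass reaction")
    out.set_bounds(out.biomass_reaction_id, lower=min_flux)
    return out


def add_virtual_efflux(
    net: MetabolicNetwork,
    metabolite_ids: list[str],
    upper_bound: float = 1000.0,
    inplace: bool = False,
) -> MetabolicNetwork:
    """Add one irreversible virtual drain ``VEX_<met>`` per metabolite.

    A virtual efflux lets the metabolite escape steady state so that its
    accumulation tendency can be scored; with its upper bound at 0 the
    network behaves exactly as before.
    """
    out = net if inplace else net.copy()
    for met in metabolite_ids:
        if not out.has_metabolite(met):
            raise KeyError(f"unknown metabolite {met!r}")
        out.add_reaction(
            Reaction(
                id=f"VEX_{met}",
                stoichiometry={met: -1.0},
                lower_bound=0.0,
                upper_bound=upper_bound,
                name=f"virtual efflux of {met}",
                is_exchange=True,
                pathway="virtual efflux",
            )
        )
    return out


# ---------------------------------------------------------------------------
# alternate-optima enumeration (recursive MILP)


def enumerate_alternate_optima(
    net: MetabolicNetwork,
    obj: Objective | dict[str, float] | str,
    max_count: int = 1000,
    epsilon: float = FLUX_EPSILON,
    activation: float = ACTIVATION_EPS,
    time_limit_s: float = 600.0,
) -> OptimaSet:
    """Enumerate directionality-distinct optima of an FBA problem.

    The optimal face is explored with a recursive MILP: each reaction
    direction gets a binary indicator; after each solution an integer cut
    excludes every flux pattern whose active-direction set contains the one
    just found.  Because any non-vertex point of the face activates a
    superset of some vertex's directions, minimizing the number of active
    directions enumerates the extreme-point patterns and skips interior
    blends; a pattern whose active directions strictly contain an already
    found pattern (e.g. one that only adds a futile sub-cycle) is likewise
    not reported.  Optima sharing one sign pattern (same path and same
    directionality, different flux values) are collapsed to one entry.
    """
    objective = _as_objective(obj, net)
    base = fba_optimize(net, objective)
    if base.status != "optimal":
        raise RuntimeError(f"base FBA problem is {base.status}")
    zstar = base.objective_value

    rxns = net.reactions
    n = len(rxns)
    m = net.n_metabolites
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()

    prob = glpk.glp_create_prob()
    glpk.glp_set_obj_dir(prob, glpk.GLP_MIN)
    # columns: p_i (forward part), q_i (reverse part), yp_i, ym_i
    ncols = 4 * n
    glpk.glp_add_cols(prob, ncols)
    P, Q, YP, YM = (
        lambda i: i + 1,
        lambda i: n + i + 1,
        lambda i: 2 * n + i + 1,
        lambda i: 3 * n + i + 1,
    )
    for i in range(n):
        pmax = float(max(0.0, ub[i]))
        qmax = float(max(0.0, -lb[i]))
        glpk.glp_set_col_bnds(prob, P(i), glpk.GLP_DB if pmax > 0 else glpk.GLP_FX, 0.0, pmax)
        glpk.glp_set_col_bnds(prob, Q(i), glpk.GLP_DB if qmax > 0 else glpk.GLP_FX, 0.0, qmax)
        for col in (YP(i), YM(i)):
            glpk.glp_set_col_kind(prob, col, glpk.GLP_BV)
        if pmax == 0:
            glpk.glp_set_col_bnds(prob, YP(i), glpk.GLP_FX, 0.0, 0.0)
        if qmax == 0:
            glpk.glp_set_col_bnds(prob, YM(i), glpk.GLP_FX, 0.0, 0.0)
        glpk.glp_set_obj_coef(prob, YP(i), 1.0)
        glpk.glp_set_obj_coef(prob, YM(i), 1.0)

    rows: list[tuple[dict[int, float], int, float, float]] = []
    # steady state: sum_j S_ij (p_j - q_j) = 0
    for i in range(m):
        coefs: dict[int, float] = {}
        for j in range(n):
            if S[i, j] != 0.0:
                coefs[P(j)] = S[i, j]
                coefs[Q(j)] = -S[i, j]
        rows.append((coefs, glpk.GLP_FX, 0.0, 0.0))
    # objective pinned at its optimum
    obj_coefs: dict[int, float] = {}
    for rid, w in objective.weights.items():
        j = net.reaction_index(rid)
        obj_coefs[P(j)] = obj_coefs.get(P(j), 0.0) + w
        obj_coefs[Q(j)] = obj_coefs.get(Q(j), 0.0) - w
    slack = max(1.0, abs(zstar)) * 1e-7
    rows.append((obj_coefs, glpk.GLP_DB, zstar - slack, zstar + slack))
    # indicator linking: activation <= p <= ub * yp   (same for q)
    for i in range(n):
        pmax = max(0.0, ub[i])
        qmax = max(0.0, -lb[i])
        if pmax > 0:
            rows.append(({P(i): 1.0, YP(i): -pmax}, glpk.GLP_UP, 0.0, 0.0))
            rows.append(({P(i): 1.0, YP(i): -activation}, glpk.GLP_LO, 0.0, 0.0))
        if qmax > 0:
            rows.append(({Q(i): 1.0, YM(i): -qmax}, glpk.GLP_UP, 0.0, 0.0))
            rows.append(({Q(i): 1.0, YM(i): -activation}, glpk.GLP_LO, 0.0, 0.0))
        if pmax > 0 and qmax > 0:
            rows.append(({YP(i): 1.0, YM(i): 1.0}, glpk.GLP_UP, 0.0, 1.0))

    glpk.glp_add_rows(prob, len(rows))
    for r, (coefs, kind, lo, hi) in enumerate(rows, start=1):
        ind = glpk.intArray(len(coefs) + 1)
        val = glpk.doubleArray(len(coefs) + 1)
        for k, (col, c) in enumerate(coefs.items(), start=1):
            ind[k] = col
            val[k] = float(c)
        glpk.glp_set_mat_row(prob, r, len(coefs), ind, val)
        glpk.glp_set_row_bnds(prob, r, kind, lo, hi)

    iocp = glpk.glp_iocp()
    glpk.glp_init_iocp(iocp)
    iocp.msg_lev = glpk.GLP_MSG_OFF
    iocp.presolve = glpk.GLP_ON
    iocp.tm_lim = int(time_limit_s * 1000)

    vertices: list[FluxState] = []
    seen: set[tuple[int, ...]] = set()
    complete = True
    try:
        while len(vertices) < max_count:
            ret = glpk.glp_intopt(prob, iocp)
            status = glpk.glp_mip_status(prob)
            if ret == glpk.GLP_ETMLIM or ret == glpk.GLP_EMIPGAP:
                complete = False
                break
            if status not in (glpk.GLP_OPT, glpk.GLP_FEAS):
                break  # no further pattern exists: enumeration complete
            flux = np.array(
                [
                    glpk.glp_mip_col_val(prob, P(i)) - glpk.glp_mip_col_val(prob, Q(i))
                    for i in range(n)
                ]
            )
            yp = [glpk.glp_mip_col_val(prob, YP(i)) > 0.5 for i in range(n)]
            ym = [glpk.glp_mip_col_val(prob, YM(i)) > 0.5 for i in range(n)]
            pattern = tuple(1 if a else (-1 if b else 0) for a, b in zip(yp, ym))
            if pattern not in seen:
                seen.add(pattern)
                # polish: re-solve the LP with directions fixed so the
                # reported vertex sits exactly on the optimal face
                fixed = net.copy()
                for i, sgn in enumerate(pattern):
                    r = fixed.reactions[i]
                    if sgn > 0:
                        r.lower_bound = max(r.lower_bound, 0.0)
                    elif sgn < 0:
                        r.upper_bound = min(r.upper_bound, 0.0)
                    else:
                        r.lower_bound = r.upper_bound = 0.0
                polished = fba_optimize(fixed, objective)
                if polished.status == "optimal":
                    vertices.append(polished)
                else:  # fall back to the raw MILP point
                    fluxes = dict(zip((r.id for r in rxns), flux))
                    zval = sum(
                        objective.weights[rid] * fluxes[rid] for rid in objective.weights
                    )
                    vertices.append(
                        FluxState(fluxes=fluxes, objective_value=zval, status="optimal")
                    )
            # integer cut: at least one active direction must switch off
            active = [YP(i) for i in range(n) if pattern[i] > 0] + [
                YM(i) for i in range(n) if pattern[i] < 0
            ]
            row = glpk.glp_add_rows(prob, 1)
            ind = glpk.intArray(len(active) + 1)
            val = glpk.doubleArray(len(active) + 1)
            for k, col in enumerate(active, start=1):
                ind[k] = col
                val[k] = 1.0
            glpk.glp_set_mat_row(prob, row, len(active), ind, val)
            glpk.glp_set_row_bnds(prob, row, glpk.GLP_UP, 0.0, float(len(active) - 1))
        else:
            complete = False  # hit max_count with patterns possibly remaining
    finally:
        glpk.glp_delete_prob(prob)

    return OptimaSet(vertices=vertices, shared_objective_value=zstar, complete=complete)
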