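import itertools

import numpy as np
import pytest

from engroflux.network import load_engro1, set_availability


@pytest.fixture(scope="session")
def engro1():
    """The bundled core-network reconstruction (immutable; copy to edit)."""
    return load_engro1()


@pytest.fixture(scope="session")
def critical_net(engro1):
    """The critical-oxygen boundary condition: O2 38, glucose 10, glutamine 40."""
    net = set_availability(engro1, "glucose_uptake", 10.0)
    set_availability(net, "glutamine_uptake", 40.0, inplace=True)
    set_availability(net, "oxygen_uptake", 38.0, inplace=True)
    return net


def brute_force_optimal_patterns(net, objective_rxn, epsilon=1e-6):
    """Independent oracle: enumerate every basic feasible solution (vertex)
    of the optimal face *in standard (split) form* -- each reversible
    reaction contributes a forward and a reverse non-negative variable, as
    in the recursive-MILP formulation -- by exhausting bound-fixing
    choices; collapse vertices to directionality sign patterns, and keep
    the containment-minimal patterns (a pattern strictly containing
    another's active directions only adds a redundant sub-cycle and is not
    reported by the recursive MILP either).

    Exponential in the reaction count; intended for networks <= 12 reactions.
    """
    from engroflux.fba import fba_optimize

    base = fba_optimize(net, objective_rxn)
    assert base.status == "optimal"
    zstar = base.objective_value

    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()
    n = S.shape[1]
    # split into non-negative forward/backward parts
    cols, col_lb, col_ub, owner, sign = [], [], [], [], []
    for j in range(n):
        if ub[j] > 0:
            cols.append(S[:, j]); col_lb.append(max(lb[j], 0.0)); col_ub.append(ub[j])
            owner.append(j); sign.append(+1)
        if lb[j] < 0:
            cols.append(-S[:, j]); col_lb.append(max(-ub[j], 0.0)); col_ub.append(-lb[j])
            owner.append(j); sign.append(-1)
        if lb[j] == 0 and ub[j] == 0:
            cols.append(S[:, j]); col_lb.append(0.0); col_ub.append(0.0)
            owner.append(j); sign.append(+1)
    Ssp = np.column_stack(cols)
    lo, hi = np.array(col_lb), np.array(col_ub)
    nn = Ssp.shape[1]
    c = np.zeros(nn)
    for k_, j in enumerate(owner):
        if j == net.reaction_index(objective_rxn):
            c[k_] = sign[k_]
    A = np.vstack([Ssp, c])
    b = np.zeros(A.shape[0])
    b[-1] = zstar
    r = np.linalg.matrix_rank(A)
    k = nn - r  # variables fixed at a bound in a basic solution
    patterns = set()
    for fixed in itertools.combinations(range(nn), k):
        free = [j for j in range(nn) if j not in fixed]
        Af = A[:, free]
        if np.linalg.matrix_rank(Af) < len(free):
            continue
        for choice in itertools.product(*[(lo[j], hi[j]) for j in fixed]):
            rhs = b - A[:, fixed] @ np.array(choice)
            sol, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
            if np.max(np.abs(Af @ sol - rhs)) > 1e-7:
                continue
            w = np.zeros(nn)
            w[list(fixed)] = choice
            w[free] = sol
            if np.any(w < lo - 1e-7) or np.any(w > hi + 1e-7):
                continue
            v = np.zeros(n)
            for k_, j in enumerate(owner):
                v[j] += sign[k_] * w[k_]
            patterns.add(
                tuple(0 if abs(x) <= epsilon else (1 if x > 0 else -1) for x in v)
            )

    def active(p):
        return {(i, s) for i, s in enumerate(p) if s != 0}

    minimal = {
        p
        for p in patterns
        if not any(q != p and active(q) < active(p) for q in patterns)
    }
    return minimal


def to_cobra(net):
    """Convert a MetabolicNetwork into a cobrapy Model (test oracle only)."""
    import cobra

    model = cobra.Model(net.model_id)
    mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in net.metabolites}
    rxns = []
    for r in net.reactions:
        rx = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(rx)
    model.add_reactions(rxns)
    for r in net.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    return model
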