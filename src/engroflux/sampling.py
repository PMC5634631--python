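"""Random-objective ensemble sampling and perturbation Z-scores.

The flux solution space is explored by repeatedly maximizing *multi-weighted
random objective functions*: for objective ``j`` a bias ``tau_j`` is drawn
uniformly in (0, 1], and every eligible reaction weight ``c_i`` is set to 0
with probability ``tau_j`` and otherwise drawn uniformly from (0, 1].  Each
objective lands on one corner of the feasible polytope; a sample of corners
stands in for a population of virtual cells ("wirings") with randomly
altered flux preferences.

Seeding is counter-based: objective ``j`` uses ``default_rng([seed, j])``,
so any subset of the sample can be regenerated independently and the whole
run is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import _LPProblem
from .network import MetabolicNetwork

__all__ = [
    "SamplerConfig",
    "RandomObjective",
    "FluxSample",
    "draw_objectives",
    "evaluate_sample",
    "zscore",
    "sem_diagnostic",
    "Z_SIGNIFICANCE",
]

#: two-sided p < 0.05
Z_SIGNIFICANCE = 1.96


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling parameters.  ``n_samples`` defaults to the published 50,000;
    ``reaction_pool`` limits which reactions may receive weight (default:
    every reaction in the network)."""

    n_samples: int = 50_000
    seed: int = 0
    reaction_pool: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class RandomObjective:
    """One tau-biased random weight vector (zero weights omitted)."""

    tau: float
    weights: dict[str, float]
    sample_index: int
    derived_seed: int


def draw_objectives(
    cfg: SamplerConfig, net: MetabolicNetwork, fixed_tau: float | None = None
) -> list[RandomObjective]:
    """Draw ``cfg.n_samples`` random objectives over the reaction pool.

    All-zero draws are rejected and redrawn from the same stream.  With the
    same config the same objectives are returned, in the same order.
    ``fixed_tau`` pins the zero-bias instead of drawing it per objective
    (diagnostics only; ``fixed_tau=0`` weights every pool reaction).
    """
    pool = (
        list(cfg.reaction_pool)
        if cfg.reaction_pool is not None
        else [r.id for r in net.reactions]
    )
    for rid in pool:
        if not net.has_reaction(rid):
            raise KeyError(f"reaction_pool entry {rid!r} not in network")
    out: list[RandomObjective] = []
    npool = len(pool)
    for j in range(cfg.n_samples):
        rng = np.random.default_rng([cfg.seed, j])
        while True:
            tau = fixed_tau if fixed_tau is not None else 1.0 - rng.random()
            keep = rng.random(npool) >= tau  # weight zero with probability tau
            if keep.any():
                break
        raw = 1.0 - rng.random(npool)  # uniform in (0, 1]
        weights = {rid: float(w) for rid, w, k in zip(pool, raw, keep) if k}
        out.append(
            RandomObjective(tau=float(tau), weights=weights, sample_index=j, derived_seed=j)
        )
    return out


@dataclass
class FluxSample:
    """Optimal flux vectors for a list of objectives (reactions x samples)."""

    fluxes: pd.DataFrame  # index: reaction ids; columns: sample index
    statuses: list[str]

    @property
    def n(self) -> int:
        return self.fluxes.shape[1]

    def flux_matrix(self) -> np.ndarray:
        return self.fluxes.to_numpy()


def evaluate_sample(
    net: MetabolicNetwork,
    objectives: list[RandomObjective],
    lp: _LPProblem | None = None,
) -> FluxSample:
    """Solve one FBA problem per objective (order preserved).

    Solver failures are recorded per objective (NaN column, status string)
    and are not fatal.
    """
    if lp is None:
        lp = _LPProblem(net)
    n = len(objectives)
    mat = np.empty((len(lp.rxn_ids), n))
    statuses: list[str] = []
    for k, obj in enumerate(objectives):
        status, _, flux = lp.solve(obj.weights)
        statuses.append(status)
        mat[:, k] = flux
    return FluxSample(
        fluxes=pd.DataFrame(mat, index=lp.rxn_ids, columns=range(n)),
        statuses=statuses,
    )


def zscore(
    sample1: pd.DataFrame | np.ndarray,
    sample2: pd.DataFrame | np.ndarray,
    significance: float = Z_SIGNIFICANCE,
) -> pd.DataFrame:
    """Per-flux Z of condition 1 vs condition 2.

    ``Z = (X1 - X2) / sqrt(s1^2/n1 + s2^2/n2)`` with population variances.
    Degenerate rows: both variances zero and equal means give ``Z = 0``;
    zero variance with unequal means gives a signed infinity, flagged
    significant.  Swapping the conditions flips every sign.
    """
    s1 = pd.DataFrame(sample1)
    s2 = pd.DataFrame(sample2)
    if s1.shape[0] != s2.shape[0]:
        raise ValueError("flux dimensions differ between conditions")
    x1, x2 = s1.mean(axis=1), s2.mean(axis=1)
    v1, v2 = s1.var(axis=1, ddof=0), s2.var(axis=1, ddof=0)
    n1, n2 = s1.shape[1], s2.shape[1]
    denom = np.sqrt(v1 / n1 + v2 / n2)
    diff = x1 - x2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / denom
    z = z.where(denom > 0, np.sign(diff) * np.inf)
    z = z.mask((denom == 0) & (diff == 0), 0.0)
    out = pd.DataFrame(
        {
            "mean_1": x1,
            "mean_2": x2,
            "var_1": v1,
            "var_2": v2,
            "n_1": n1,
            "n_2": n2,
            "z": z,
        }
    )
    out["significant"] = out["z"].abs() > significance
    out.index.name = "flux"
    return out


def sem_diagnostic(sample: pd.DataFrame | np.ndarray, sizes: list[int]) -> pd.DataFrame:
    """Relative standard error of the mean per flux, per sub-sample size.

    The first ``n`` columns of the sample stand in for a run of size ``n``.
    The SEM is scaled by the mean absolute flux of the full sample (a plain
    mean would blow up for fluxes centred on zero); constant fluxes get 0.
    """
    s = pd.DataFrame(sample)
    if sorted(sizes) != list(sizes):
        raise ValueError("sizes must be ascending")
    if sizes and sizes[-1] > s.shape[1]:
        raise ValueError("largest size exceeds the sample")
    scale = s.abs().mean(axis=1)
    # below solver precision a flux is constant zero; its "variation" is dust
    scale = scale.where(scale > 1e-6, np.inf)
    cols = {}
    for n in sizes:
        sub = s.iloc[:, :n]
        sem = sub.std(axis=1, ddof=0) / np.sqrt(n)
        rel = sem / scale
        cols[n] = rel.fillna(0.0)
    out = pd.DataFrame(cols)
    out.index.name = "flux"
    out.columns.name = "n"
    return out
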