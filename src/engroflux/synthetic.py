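"""Synthetic test fixtures: toy networks with known answers, and synthetic
measurement tables.

Each toy topology has a closed-form FBA optimum, a known count of
directionality-distinct alternate optima and a known set of loop members,
so the flux engine can be certified without any curated model:

``chain``        linear uptake -> conversions -> efflux; optimum = uptake
                 bound, a single optimal pattern, no loops.
``diamond``      two equivalent parallel branches; two optimal patterns.
``parallel``     k equivalent branches; k optimal patterns.
``loop_pair``    a chain plus an internal 2-cycle (forward + reverse
                 reactions between the same metabolites) able to carry flux
                 with exchanges closed; the pair is the loop report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, Reaction, build_network
from .shifts import ExperimentTable

__all__ = [
    "ToyNetworkSpec",
    "ToyAnswers",
    "make_toy_network",
    "SyntheticMeasurementSpec",
    "make_measurement_table",
]


@dataclass(frozen=True)
class ToyNetworkSpec:
    topology: str = "chain"  # chain | diamond | parallel | loop_pair
    length: int = 3          # chain length (number of internal conversions)
    branches: int = 2        # parallel-branch count
    uptake_bound: float = 5.0


@dataclass(frozen=True)
class ToyAnswers:
    """Closed-form expectations for a toy network."""

    optimum: float
    optima_count: int
    loop_members: tuple[str, ...]
    objective_reaction: str


def make_toy_network(spec: ToyNetworkSpec) -> tuple[MetabolicNetwork, ToyAnswers]:
    """Build a toy network together with its analytically known answers."""
    u = float(spec.uptake_bound)
    if spec.topology == "chain":
        if spec.length < 1:
            raise ValueError("chain length must be >= 1")
        rxns = [Reaction("up", {"M0": 1.0}, 0, u)]
        for i in range(spec.length):
            rxns.append(Reaction(f"c{i}", {f"M{i}": -1.0, f"M{i+1}": 1.0}, 0, 1000))
        rxns.append(Reaction("out", {f"M{spec.length}": -1.0}, 0, 1000))
        answers = ToyAnswers(u, 1, (), "out")
    elif spec.topology in ("diamond", "parallel"):
        k = 2 if spec.topology == "diamond" else int(spec.branches)
        if k < 1:
            raise ValueError("need at least one branch")
        rxns = [Reaction("up", {"A": 1.0}, 0, u)]
        rxns += [Reaction(f"b{i}", {"A": -1.0, "B": 1.0}, 0, 1000) for i in range(k)]
        rxns.append(Reaction("out", {"B": -1.0}, 0, 1000))
        answers = ToyAnswers(u, k, (), "out")
    elif spec.topology == "loop_pair":
        rxns = [
            Reaction("up", {"A": 1.0}, 0, u),
            Reaction("fwd", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("back", {"B": -1.0, "A": 1.0}, 0, 1000),
            Reaction("out", {"B": -1.0}, 0, 1000),
        ]
        # fwd+back form an internal cycle able to carry flux with exchanges
        # closed; the loop check must flag exactly this pair.  The optimum is
        # still the uptake bound and the enumeration reports one pattern: the
        # vertex with the cycle spinning activates a strict superset of the
        # loop-free pattern's directions and is excluded by the integer cuts.
        answers = ToyAnswers(u, 1, ("fwd", "back"), "out")
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    net = build_network(rxns, model_id=f"toy_{spec.topology}")
    return net, answers


@dataclass(frozen=True)
class SyntheticMeasurementSpec:
    """Recipe for a synthetic fold-change table (reference condition = 1.0)."""

    metabolites: tuple[str, ...] = ("pyruvate", "citrate", "malate", "glucose")
    directions: tuple[str, ...] = ("increased", "decreased", "decreased", "unchanged")
    effect_size: float = 0.5   # |log2 fold change| of a changed metabolite
    noise_sd: float = 0.0
    seed: int = 0


def make_measurement_table(spec: SyntheticMeasurementSpec) -> ExperimentTable:
    """Generate a reproducible synthetic fold-change table.

    Without noise the direction calls recoverable from the fold changes
    equal the requested pattern exactly.
    """
    if len(spec.metabolites) != len(spec.directions):
        raise ValueError("metabolites and directions must align")
    rng = np.random.default_rng(spec.seed)
    log2 = {"increased": spec.effect_size, "decreased": -spec.effect_size, "unchanged": 0.0}
    rows = []
    for met, direction in zip(spec.metabolites, spec.directions):
        if direction not in log2:
            raise ValueError(f"unknown direction {direction!r}")
        lfc = log2[direction] + rng.normal(0.0, spec.noise_sd)
        rows.append((met, float(2.0**lfc), spec.noise_sd))
    df = pd.DataFrame(rows, columns=["metabolite", "fold_change", "sd"]).set_index(
        "metabolite"
    )
    return ExperimentTable.from_frame(df)
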