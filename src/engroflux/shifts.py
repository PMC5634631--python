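"""Metabolite-shift prediction via virtual-efflux ensemble sampling.

FBA enforces strict steady state, so metabolite *levels* are invisible to
it.  Adding a small irreversible *virtual efflux* per measured metabolite
lets each species leak out of steady state; if, across a random-objective
ensemble, the leak flux is significantly higher in one nutrient condition,
the metabolite is called *increased* there (and vice versa).  Predictions
are compared sign-wise against an experimental fold-change table.

The same objective set is evaluated under both conditions (paired design);
biomass is constrained to a fraction of each condition's own optimum so
that only proliferating wirings are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import add_virtual_efflux, constrain_biomass_production, fba_optimize
from .network import MetabolicNetwork
from .sampling import SamplerConfig, Z_SIGNIFICANCE, draw_objectives, evaluate_sample, zscore

__all__ = [
    "ConditionPair",
    "ShiftPrediction",
    "ExperimentTable",
    "predict_shifts",
    "compare_with_measurements",
    "MEASURED_PANEL",
    "BIOMASS_FRACTION",
]

#: biomass lower bound, as a fraction of the condition-specific optimum
BIOMASS_FRACTION = 0.01

#: GC-MS panel of the glutamine-limitation experiment, mapped to model
#: species (None = not representable in the core network).  Hydrogen
#: peroxide stands in for the ROS measurements.
MEASURED_PANEL: dict[str, str | None] = {
    "glutamine": "gln",
    "glutamate": "glu",
    "aspartate": "asp",
    "glycine": "gly",
    "serine": "ser",
    "alanine": "ala",
    "trehalose": None,
    "methionine": "met",
    "lysine": None,
    "tyrosine": None,
    "cysteine": "cys",
    "ornithine": "orn",
    "putrescine": "ptrc",
    "glucose": "glc",
    "pyruvate": "pyr",
    "lactate": "lac",
    "citrate": "cit",
    "alpha-ketoglutarate": "akg",
    "succinate": "succ",
    "fumarate": "fum",
    "malate": "mal",
    "acetyl-CoA": "accoa",
    "hydrogen peroxide": "h2o2",
}


@dataclass(frozen=True)
class ConditionPair:
    """Two nutrient conditions differing in the declared availabilities.

    ``high`` / ``low`` map availability roles (``glutamine_uptake`` etc.) to
    mM/h upper bounds; unmentioned nutrients stay at the network's values.
    """

    high: tuple[tuple[str, float], ...] = (("glutamine_uptake", 20.0),)
    low: tuple[tuple[str, float], ...] = (("glutamine_uptake", 2.5),)
    shared: tuple[tuple[str, float], ...] = (
        ("glucose_uptake", 20.0),
        ("oxygen_uptake", 20.0),
    )

    def apply(self, net: MetabolicNetwork, which: str) -> MetabolicNetwork:
        out = net.copy()
        for role, value in self.shared + (self.high if which == "high" else self.low):
            out.set_bounds(out.named_reactions[role], upper=value)
        return out


@dataclass
class ShiftPrediction:
    """Per-metabolite Z (low minus high condition) and three-way call."""

    table: pd.DataFrame  # index metabolite name; columns z, call, predictable
    n_samples: int

    def call(self, metabolite: str) -> str:
        return str(self.table.loc[metabolite, "call"])


def predict_shifts(
    net: MetabolicNetwork,
    panel: dict[str, str | None] | list[str],
    pair: ConditionPair,
    cfg: SamplerConfig,
    biomass_fraction: float = BIOMASS_FRACTION,
    significance: float = Z_SIGNIFICANCE,
) -> ShiftPrediction:
    """Predict up/down metabolite shifts in the low vs the high condition.

    Each panel metabolite gets a virtual efflux; the same random objectives
    (drawn over the augmented reaction set, virtual effluxes included) are
    optimized under both conditions with biomass constrained to
    ``biomass_fraction`` of the condition optimum.  The Z-score of the
    virtual-efflux flux (low minus high) makes the call: significant and
    positive = increased, significant and negative = decreased, otherwise
    unchanged.  Panel entries absent from the network are reported
    unpredictable rather than failing.
    """
    if isinstance(panel, list):
        panel = {m: m for m in panel}
    mapped = {name: mid for name, mid in panel.items() if mid and net.has_metabolite(mid)}
    unmapped = [name for name in panel if name not in mapped]

    aug = add_virtual_efflux(net, sorted(set(mapped.values())))
    objectives = draw_objectives(cfg, aug)

    samples = {}
    for which in ("low", "high"):
        cond = pair.apply(aug, which)
        opt = fba_optimize(cond, cond.biomass_reaction_id)
        if opt.status != "optimal":
            raise RuntimeError(f"{which} condition is {opt.status}")
        cond = constrain_biomass_production(
            cond, biomass_fraction * max(opt.objective_value, 0.0), inplace=True
        )
        samples[which] = evaluate_sample(cond, objectives).fluxes

    vex_ids = [f"VEX_{mid}" for mid in mapped.values()]
    z = zscore(samples["low"].loc[vex_ids], samples["high"].loc[vex_ids], significance)
    rows = []
    for name, mid in mapped.items():
        zi = float(z.loc[f"VEX_{mid}", "z"])
        sig = bool(z.loc[f"VEX_{mid}", "significant"])
        call = "unchanged" if not sig else ("increased" if zi > 0 else "decreased")
        rows.append((name, mid, zi, call, True))
    for name in unmapped:
        rows.append((name, None, np.nan, "unpredictable", False))
    table = pd.DataFrame(
        rows, columns=["metabolite", "model_id", "z", "call", "predictable"]
    ).set_index("metabolite")
    return ShiftPrediction(table=table, n_samples=cfg.n_samples)


@dataclass
class ExperimentTable:
    """Measured fold-changes, high-condition reference normalized to 1.0."""

    table: pd.DataFrame  # index metabolite; columns fold_change, sd, direction

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tol: float = 0.05) -> "ExperimentTable":
        df = df.copy()
        if "direction" not in df.columns:
            df["direction"] = np.where(
                df["fold_change"] > 1.0 + tol,
                "increased",
                np.where(df["fold_change"] < 1.0 - tol, "decreased", "unchanged"),
            )
        return cls(table=df)

    @classmethod
    def from_tsv(cls, path, **kw) -> "ExperimentTable":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("metabolite")
        return cls.from_frame(df, **kw)


def compare_with_measurements(
    pred: ShiftPrediction, expt: ExperimentTable
) -> pd.DataFrame:
    """Three-way sign comparison of predictions against measurements.

    Returns one row per shared metabolite with the predicted and measured
    calls and a ``match`` flag; summary counts live in ``df.attrs``
    (``agree`` / ``disagree`` / ``uncalled``).
    """
    shared = pred.table.index.intersection(expt.table.index)
    if len(shared) == 0:
        raise ValueError("prediction and measurements share no metabolites")
    rows = []
    for met in shared:
        p = pred.table.loc[met, "call"]
        m = expt.table.loc[met, "direction"]
        rows.append((met, p, m, p == m))
    out = pd.DataFrame(rows, columns=["metabolite", "predicted", "measured", "match"])
    out = out.set_index("metabolite")
    called = out[out["predicted"].isin(["increased", "decreased", "unchanged"])]
    out.attrs["agree"] = int(called["match"].sum())
    out.attrs["disagree"] = int((~called["match"]).sum())
    out.attrs["uncalled"] = int(len(out) - len(called))
    return out
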