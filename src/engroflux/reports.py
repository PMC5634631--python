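"""Config-driven experiment runner tying the analysis stages together.

``run_experiment`` takes a :class:`RunConfig` (or a YAML file describing
one), executes one named experiment deterministically, and writes an output
bundle: delimited tables, a machine-readable ``summary.json`` with
provenance (seed, tolerances, solver identity), and a plain-text log.  The
library API is the primary interface; this module exists so whole published
experiments can be replayed from a single declarative description.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ensembles import PerturbationGrid, classify_ensembles, scan_responses, summarize_ensemble
from .fba import FLUX_EPSILON, enumerate_alternate_optima, fba_optimize, fva
from .network import MetabolicNetwork, load_engro1, load_network, set_availability
from .sampling import SamplerConfig, draw_objectives
from .scans import (
    BloodGasParams,
    blood_oxygen_availability,
    constrained_tca_modes,
    find_critical_o2,
    growth_landscape,
)
from .shifts import ConditionPair, ExperimentTable, MEASURED_PANEL, compare_with_measurements, predict_shifts
from .yields import route_yield_table

__all__ = ["RunConfig", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = (
    "ensemble-scan",
    "glutamine-shift",
    "landscape",
    "critical-o2",
    "alternate-optima",
    "tca-modes",
    "yield-table",
    "blood-gas",
)


@dataclass
class RunConfig:
    """Everything one experiment needs; no hidden state.

    ``model`` is a path to a tabular model file or ``None`` for the bundled
    core network; ``params`` holds experiment-specific settings (grids,
    boundary conditions, pROS, ...).
    """

    experiment: str
    model: str | None = None
    seed: int = 0
    n_samples: int = 50_000
    out_dir: str = "results"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        errors = []
        if self.experiment not in EXPERIMENTS:
            errors.append(f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}")
        if self.n_samples < 1:
            errors.append("n_samples must be >= 1")
        if not isinstance(self.params, dict):
            errors.append("params must be a mapping")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_model(cfg: RunConfig) -> MetabolicNetwork:
    if cfg.model is None:
        return load_engro1()
    return load_network(cfg.model, dialect=cfg.params.get("dialect", "tabular"),
                        roles=cfg.params.get("roles"))


def _apply_availability(net: MetabolicNetwork, params: dict) -> MetabolicNetwork:
    for nutrient, role in (
        ("glucose", "glucose_uptake"),
        ("glutamine", "glutamine_uptake"),
        ("oxygen", "oxygen_uptake"),
    ):
        if nutrient in params:
            net = set_availability(net, role, float(params[nutrient]))
    return net


def run_experiment(cfg: RunConfig | str | Path) -> dict:
    """Execute one experiment; returns (and writes) the summary dict."""
    if not isinstance(cfg, RunConfig):
        cfg = RunConfig.from_yaml(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"engroflux {__version__} experiment={cfg.experiment} seed={cfg.seed}"]
    t0 = time.time()
    net = _load_model(cfg)
    summary: dict = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "solver": "GLPK (swiglpk)",
        "flux_epsilon": FLUX_EPSILON,
        "engroflux_version": __version__,
    }
    p = cfg.params

    if cfg.experiment == "ensemble-scan":
        objs = draw_objectives(SamplerConfig(cfg.n_samples, cfg.seed), net)
        gln = scan_responses(net, objs, PerturbationGrid("glutamine"))
        glc = scan_responses(net, objs, PerturbationGrid("glucose"))
        flags, fractions = classify_ensembles(gln, glc)
        flags.to_csv(out / "ensemble_flags.tsv", sep="\t")
        for name, scan in (("glutamine", gln), ("glucose", glc)):
            for ens in ("A", "E"):
                mask = flags[ens].to_numpy()
                if mask.any():
                    summarize_ensemble(scan, mask).to_csv(
                        out / f"mean_curves_{name}_{ens}.tsv", sep="\t"
                    )
        summary["ensemble_fractions"] = fractions
    elif cfg.experiment == "glutamine-shift":
        pair = ConditionPair(
            high=(("glutamine_uptake", float(p.get("high", 20.0))),),
            low=(("glutamine_uptake", float(p.get("low", 2.5))),),
        )
        pred = predict_shifts(net, MEASURED_PANEL, pair, SamplerConfig(cfg.n_samples, cfg.seed))
        pred.table.to_csv(out / "shift_predictions.tsv", sep="\t")
        expt_path = p.get("measurements")
        if expt_path is None:
            expt_path = Path(__file__).parent / "data" / "glutamine_shift_measurements_synthetic.tsv"
        expt = ExperimentTable.from_tsv(expt_path)
        comparison = compare_with_measurements(pred, expt)
        comparison.to_csv(out / "shift_comparison.tsv", sep="\t")
        summary["calls"] = pred.table["call"].to_dict()
        summary["agreement"] = dict(comparison.attrs)
    elif cfg.experiment == "landscape":
        axes = p.get("axes") or {
            "glucose": [1, 2, 5, 10, 20],
            "oxygen": [0, 5, 10, 20, 40, 60],
        }
        base = _apply_availability(net, {"glutamine": p.get("glutamine", 1.0)})
        df = growth_landscape(base, axes, fva_check=bool(p.get("fva_check", False)))
        df.to_csv(out / "landscape.tsv", sep="\t", index=False)
        summary["n_points"] = int(len(df))
        summary["max_biomass"] = float(df["biomass"].max())
    elif cfg.experiment == "critical-o2":
        g, q = float(p.get("glucose", 10.0)), float(p.get("glutamine", 40.0))
        points = {
            crit: find_critical_o2(net, g, q, criterion=crit).critical_oxygen
            for crit in ("pdh-zero", "lactate-max")
        }
        summary["critical_oxygen"] = points
        summary["glucose"], summary["glutamine"] = g, q
    elif cfg.experiment == "alternate-optima":
        scen = _apply_availability(net, {**{"glucose": 10, "glutamine": 40, "oxygen": 38}, **p})
        optima = enumerate_alternate_optima(
            scen, scen.biomass_reaction_id, max_count=int(p.get("max_count", 500))
        )
        optima.to_frame().to_csv(out / "alternate_optima.tsv", sep="\t")
        summary["count"] = optima.count
        summary["complete"] = optima.complete
        summary["objective_value"] = optima.shared_objective_value
    elif cfg.experiment == "tca-modes":
        scen = _apply_availability(net, {**{"glucose": 10, "glutamine": 40, "oxygen": 38}, **p})
        modes = {}
        for scenario in ("control", "no-lactate", "no-glucose",
                         "no-glucose-no-lactate-pyruvate-allowed"):
            for objective in ("biomass", "ATP"):
                state, mode = constrained_tca_modes(scen, scenario, objective)
                modes[f"{scenario}/{objective}"] = {
                    "mode": mode,
                    "objective_value": state.objective_value,
                }
        summary["modes"] = modes
    elif cfg.experiment == "yield-table":
        df = route_yield_table(net, pros=float(p.get("pros", 0.25)))
        df.to_csv(out / "yield_table.tsv", sep="\t")
        summary["po"] = df["po"].round(6).to_dict()
    elif cfg.experiment == "blood-gas":
        summary["blood_gas"] = blood_oxygen_availability(BloodGasParams())

    summary["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    log_lines.append(f"done in {summary['runtime_s']}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
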