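"""Closed-form ATP/O2 yield accounting for catabolic routes.

Routes are fixed linear combinations of the *non-respiratory* reactions of
the core network (a delimited route file: route id, reaction id,
multiplier), so the accounting stays independent of the LP solver.  For a
route with net production of ``N`` mol NAD(P)H, ``F`` mol FADH2 and ``A``
mol substrate-level ATP per mole of substrate:

* a fraction ``pROS`` of Complex I electrons is lost to superoxide, whose
  dismutation and glutathione-dependent reduction cost one NAD(P)H per two
  superoxide anions, so only ``N / (1 + pROS)`` of the pool is respired;
* the effective P/O of NADH oxidation is ``3 (1 - pROS) / (1 + pROS)``
  (against a fixed 2 for FADH2), and the respiratory ATP is
  ``N * effective_po + 2 F``;
* oxygen consumption is ``(N + F) / 2`` mol O2 -- independent of pROS,
  because the electrons diverted to superoxide consume O2 too;
* ``P/O = total ATP / (2 * O2)``; a route that consumes no oxygen at all
  (pure fermentation) reports the sentinel value 100.

Difference rows ("route A rather than route B") subtract the two ledgers
entry-wise before forming the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import MetabolicNetwork

__all__ = [
    "effective_po",
    "RouteYield",
    "load_routes",
    "route_ledger",
    "route_yield_table",
    "PO_SENTINEL",
    "FADH2_PO",
    "STANDARD_ROWS",
]

PO_SENTINEL = 100.0
FADH2_PO = 2.0

#: currency species whose net production a route may leave unbalanced
_CURRENCY = {"atp", "adp", "pi", "nad", "nadh", "nadp", "nadph", "fad", "fadh2", "o2", "h2o2"}

#: species a route may legitimately excrete or secrete
_PRODUCTS = {"lac", "pyr", "co2", "nh3", "accoa", "accoa_c", "urea"}

#: species a route may consume as substrate
_SUBSTRATES = {"glc", "gln"}


def effective_po(pros: float) -> float:
    """Effective P/O ratio of NADH oxidation, ``3 (1-pROS) / (1+pROS)``."""
    if not (0.0 <= pros < 1.0):
        raise ValueError(f"pROS must be in [0, 1), got {pros}")
    return 3.0 * (1.0 - pros) / (1.0 + pros)


@dataclass
class RouteYield:
    """One row of the yield table (per mole of substrate)."""

    route_id: str
    substrate: str
    substrate_moles: float
    nadh: float            # net NAD(P)H produced by the route reactions
    fadh2: float
    o2: float              # mol O2 needed to reoxidize the carriers
    substrate_atp: float
    respiratory_atp: float
    total_atp: float
    po: float              # ATP per O atom; PO_SENTINEL when no O2 is used
    accoa_yield: float     # mol acetyl-CoA per mole of substrate


def load_routes(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a route file (route id, reaction id, multiplier) into a map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    routes: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        routes.setdefault(str(row["route_id"]), {})[str(row["reaction_id"])] = float(
            row["multiplier"]
        )
    return routes


def _default_routes() -> dict[str, dict[str, float]]:
    return load_routes(Path(__file__).parent / "data" / "routes.tsv")


def route_ledger(net: MetabolicNetwork, multipliers: dict[str, float]) -> dict[str, float]:
    """Net metabolite production of a route; validates mass balance.

    Every metabolite other than currency, substrates and excretable products
    must balance to zero, otherwise the route is not an elementary
    conversion of the network and an error is raised.
    """
    net_prod: dict[str, float] = {}
    for rid, mult in multipliers.items():
        rxn = net.reaction(rid)
        if rxn.pathway == "oxphos":
            raise ValueError(
                f"route includes respiratory reaction {rid!r}; respiration is "
                "accounted analytically"
            )
        for met, coef in rxn.stoichiometry.items():
            net_prod[met] = net_prod.get(met, 0.0) + coef * mult
    net_prod = {m: c for m, c in net_prod.items() if abs(c) > 1e-9}
    for met, coef in net_prod.items():
        if met in _CURRENCY:
            continue
        if coef > 0 and met in _PRODUCTS:
            continue
        if coef < 0 and met in _SUBSTRATES:
            continue
        raise ValueError(
            f"route leaves non-currency metabolite {met!r} unbalanced ({coef:+g})"
        )
    return net_prod


def _yield_from_ledger(
    route_id: str, ledger: dict[str, float], pros: float
) -> RouteYield:
    n = ledger.get("nadh", 0.0) + ledger.get("nadph", 0.0)
    f = ledger.get("fadh2", 0.0)
    a = ledger.get("atp", 0.0)
    o2 = (n + f) / 2.0 - ledger.get("o2", 0.0)
    resp = n * effective_po(pros) + FADH2_PO * f
    total = a + resp
    po = total / (2.0 * o2) if abs(o2) > 1e-9 else PO_SENTINEL
    consumed = [m for m in _SUBSTRATES if ledger.get(m, 0.0) < 0]
    substrate = consumed[0] if len(consumed) == 1 else "+".join(consumed) or "none"
    moles = -ledger.get(substrate, 0.0) if substrate in ledger else 0.0
    return RouteYield(
        route_id=route_id,
        substrate=substrate,
        substrate_moles=moles,
        nadh=n,
        fadh2=f,
        o2=o2,
        substrate_atp=a,
        respiratory_atp=resp,
        total_atp=total,
        po=po,
        accoa_yield=ledger.get("accoa", 0.0) + ledger.get("accoa_c", 0.0),
    )


#: rows of the standard yield table; an entry is either a route id or a
#: pair (route A, route B) meaning "A rather than B"
STANDARD_ROWS: list[tuple[str, str | tuple[str, str]]] = [
    ("glc_to_lactate", "glc_to_lactate"),
    ("glc_respiration_vs_fermentation", ("glc_respiration", "glc_to_lactate")),
    ("glc_to_pyruvate_vs_lactate", ("glc_to_pyruvate", "glc_to_lactate")),
    ("gln_to_lactate", "gln_to_lactate"),
    ("gln_to_pyruvate", "gln_to_pyruvate"),
    ("gln_respiration", "gln_respiration"),
    ("glc_to_accoa_vs_lactate", ("glc_to_accoa", "glc_to_lactate")),
    ("gln_to_accoa_reductive", "gln_to_accoa_reductive"),
    ("gln_to_accoa_clockwise", "gln_to_accoa_clockwise"),
    ("gln_to_two_accoa_combined", "gln_to_two_accoa_combined"),
]


def route_yield_table(
    net: MetabolicNetwork,
    pros: float = 0.25,
    routes: dict[str, dict[str, float]] | None = None,
    rows: list[tuple[str, str | tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Compute the analytic yield table over the standard (or given) rows."""
    routes = routes if routes is not None else _default_routes()
    rows = rows if rows is not None else STANDARD_ROWS
    ledgers = {rid: route_ledger(net, mult) for rid, mult in routes.items()}
    records = []
    for row_id, spec in rows:
        if isinstance(spec, tuple):
            a, b = ledgers[spec[0]], ledgers[spec[1]]
            ledger = {m: a.get(m, 0.0) - b.get(m, 0.0) for m in set(a) | set(b)}
        else:
            ledger = ledgers[spec]
        records.append(_yield_from_ledger(row_id, ledger, pros).__dict__)
    df = pd.DataFrame(records).set_index("route_id")
    df.attrs["pros"] = pros
    return df
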