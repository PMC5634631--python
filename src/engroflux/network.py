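r"""Stoichiometric network container and model IO.

The central object is :class:`MetabolicNetwork`: an ordered collection of
metabolites and reactions carrying a stoichiometric matrix ``S`` (one row per
metabolite, one column per reaction), flux bounds in mM h\ :sup:`-1`, and a
role map that names the reactions the downstream analyses need (aconitase,
PDH, the uptake reactions, ...).  Steady-state analysis imposes
``S @ v == 0`` with ``lb <= v <= ub``.

Two on-disk dialects are supported:

* ``tabular`` -- a delimited-text model table (one reaction per row with an
  equation string, bounds and a pathway label), in the spirit of the
  RAVEN-style spreadsheet exports used for core models;
* ``sbml`` -- SBML Level 2/3 with bounds stored as kinetic-law parameters
  (``LOWER_BOUND`` / ``UPPER_BOUND``), the legacy COBRA/FAME convention.

Exchange convention: an exchange reaction touches exactly one metabolite.
Uptake is written as an import (``-> glc``) so that a *positive* flux brings
the nutrient in and the *upper bound* of the import reaction is the nutrient
availability.  Effluxes are written ``lac ->``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "BiomassVariant",
    "NetworkValidationError",
    "ModelParseError",
    "load_network",
    "write_network",
    "load_engro1",
    "stoichiometric_matrix",
    "set_availability",
    "verify_loopless",
    "ROLE_NAMES",
]

#: Roles that the downstream analyses expect a curated model to resolve.
ROLE_NAMES = (
    "aconitase",
    "pdh",
    "lactate_efflux",
    "glucose_uptake",
    "glutamine_uptake",
    "oxygen_uptake",
    "ammonia_efflux",
    "atp_maintenance",
    "complex_i",
    "complex_ii",
    "idh_nad",
    "idh_nadp",
    "malic_enzyme_nad",
    "malic_enzyme_nadp",
    "malate_dehydrogenase",
    "pep_carboxykinase",
    "gdh_nad",
    "gdh_nadp",
    "biomass",
)


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending row."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.  ``is_boundary`` marks species exchanged with the
    environment (i.e. touched by at least one exchange reaction)."""

    id: str
    name: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    """One column of ``S``.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  An irreversible reaction has ``lower_bound >= 0``.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""
    is_exchange: bool = False
    pathway: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass(frozen=True)
class BiomassVariant:
    """One of the alternative biomass (protein-composition) reactions.

    ``NEAA_STD`` is the 50/50 split between glycolysis-derived and
    glutamine-derived non-essential amino acids; the 80/20 and 20/80 variants
    skew the protein composition either way.  Exactly one variant is open at
    a time.
    """

    variant_id: str  # NEAA_STD | NEAA_80_20 | NEAA_20_80
    reaction_id: str


class MetabolicNetwork:
    """An ordered stoichiometric model with named reaction roles."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str | None = None,
        named_reactions: Mapping[str, str] | None = None,
        model_id: str = "model",
    ) -> None:
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.named_reactions: dict[str, str] = dict(named_reactions or {})
        self.model_id = model_id
        self._validate()

    # -- indexing ---------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )
        if self.biomass_reaction_id is not None and (
            self.biomass_reaction_id not in self._rxn_index
        ):
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in network"
            )
        for role, rid in self.named_reactions.items():
            if rid not in self._rxn_index:
                raise NetworkValidationError(
                    f"named reaction for role {role!r} not in network: {rid!r}"
                )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def role(self, role: str) -> Reaction:
        """Resolve a named role (e.g. ``"aconitase"``) to its reaction."""
        try:
            return self.reaction(self.named_reactions[role])
        except KeyError:
            raise KeyError(f"role {role!r} is not mapped in this network") from None

    def reactions_in_pathway(self, pathway: str) -> list[Reaction]:
        return [r for r in self.reactions if r.pathway == pathway]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- matrix -----------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense ``S`` with entry ``(i, j)`` = coefficient of metabolite ``i``
        in reaction ``j`` (zero elsewhere)."""
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[self._met_index[met], j] = coef
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- editing ----------------------------------------------------------

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites,
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            self.biomass_reaction_id,
            dict(self.named_reactions),
            self.model_id,
        )

    def set_bounds(self, rxn_id: str, lower: float | None = None, upper: float | None = None) -> None:
        rxn = self.reaction(rxn_id)
        if lower is not None:
            rxn.lower_bound = float(lower)
        if upper is not None:
            rxn.upper_bound = float(upper)
        if rxn.lower_bound > rxn.upper_bound:
            raise NetworkValidationError(
                f"reaction {rxn_id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise NetworkValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._validate()


# ---------------------------------------------------------------------------
# equation strings


_ARROWS = ("<=>", "=>", "<->", "->")


def _parse_side(side: str, rxn_label: str) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$", term)
        if m is None:
            raise ModelParseError(f"reaction {rxn_label!r}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(equation: str, rxn_label: str = "?") -> dict[str, float]:
    """Parse ``"1 a + 2 b => c"`` into ``{"a": -1, "b": -2, "c": 1}``.

    Coefficients on both sides of the arrow are merged; a metabolite appearing
    on both sides keeps its *net* coefficient unless it cancels exactly, in
    which case it is dropped.
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelParseError(f"reaction {rxn_label!r}: no arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}
    for met, coef in _parse_side(left, rxn_label).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(right, rxn_label).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_equation(stoich: Mapping[str, float]) -> str:
    def fmt(met: str, coef: float) -> str:
        return met if coef == 1.0 else f"{coef:.12g} {met}"

    lhs = " + ".join(fmt(m, -c) for m, c in stoich.items() if c < 0)
    rhs = " + ".join(fmt(m, c) for m, c in stoich.items() if c > 0)
    return f"{lhs} => {rhs}"


# ---------------------------------------------------------------------------
# tabular dialect


_TAB_COLUMNS = ("id", "name", "equation", "lower_bound", "upper_bound", "pathway")


def _finalize(
    metabolite_names: Mapping[str, str],
    reactions: list[Reaction],
    biomass_reaction_id: str | None,
    named_reactions: Mapping[str, str] | None,
    model_id: str,
) -> MetabolicNetwork:
    """Assemble a network, detecting exchanges and boundary metabolites."""
    seen: dict[str, None] = {}
    for r in reactions:
        for met in r.stoichiometry:
            seen.setdefault(met, None)
    boundary = {
        met
        for r in reactions
        if len(r.stoichiometry) == 1
        for met in r.stoichiometry
    }
    for r in reactions:
        r.is_exchange = len(r.stoichiometry) == 1
    mets = [
        Metabolite(m, metabolite_names.get(m, m), is_boundary=m in boundary)
        for m in seen
    ]
    return MetabolicNetwork(mets, reactions, biomass_reaction_id, named_reactions, model_id)


def _read_tabular(path: Path) -> tuple[list[Reaction], str | None]:
    reactions: list[Reaction] = []
    biomass_id: str | None = None
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = [c for c in _TAB_COLUMNS if c not in header]
                if missing:
                    raise ModelParseError(
                        f"{path.name}: header misses columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            rid = row["id"].strip()
            try:
                stoich = parse_equation(row["equation"], rid)
                lb = float(row["lower_bound"])
                ub = float(row["upper_bound"])
            except (ModelParseError, ValueError) as exc:
                raise ModelParseError(f"{path.name} line {lineno} ({rid!r}): {exc}") from exc
            if any(r.id == rid for r in reactions):
                raise NetworkValidationError(
                    f"{path.name} line {lineno}: duplicate reaction id {rid!r}"
                )
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    name=row.get("name", "").strip(),
                    pathway=row.get("pathway", "").strip(),
                )
            )
            if row.get("pathway", "").strip().lower() == "biomass" and biomass_id is None:
                biomass_id = rid
    if not reactions:
        raise ModelParseError(f"{path.name}: no reactions found")
    return reactions, biomass_id


def _write_tabular(net: MetabolicNetwork, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for r in net.reactions:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        format_equation(r.stoichiometry),
                        f"{r.lower_bound:g}",
                        f"{r.upper_bound:g}",
                        r.pathway,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SBML dialect (Level 2, legacy kinetic-law bounds)


def _read_sbml(path: Path) -> tuple[list[Reaction], str | None]:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path.name}: SBML error: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ModelParseError(f"{path.name}: no model element")
    reactions: list[Reaction] = []
    biomass_id: str | None = None
    def _unmangle(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    for rxn in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rxn.getListOfReactants():
            met = _unmangle(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for sr in rxn.getListOfProducts():
            met = _unmangle(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        lb, ub = (-1000.0 if rxn.getReversible() else 0.0), 1000.0
        kl = rxn.getKineticLaw()
        pathway = ""
        if kl is not None:
            for i in range(kl.getNumParameters()):
                p = kl.getParameter(i)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        if rxn.isSetNotes():
            notes = rxn.getNotesString()
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", notes)
            if m:
                pathway = m.group(1).strip()
        reactions.append(
            Reaction(
                id=_unmangle(rxn.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName() or "",
                pathway=pathway,
            )
        )
        if pathway.lower() == "biomass" and biomass_id is None:
            biomass_id = _unmangle(rxn.getId(), "R_")
    if not reactions:
        raise ModelParseError(f"{path.name}: no reactions found")
    return reactions, biomass_id


def _write_sbml(net: MetabolicNetwork, path: Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(net.model_id)
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    for met in net.metabolites:
        sp = model.createSpecies()
        sp.setId(f"M_{met.id}")  # SBML SIds may not start with a digit
        sp.setName(met.name or met.id)
        sp.setCompartment("cell")
        sp.setInitialConcentration(0.0)
    for r in net.reactions:
        rxn = model.createReaction()
        rxn.setId(f"R_{r.id}")
        rxn.setName(r.name or r.id)
        rxn.setReversible(r.reversible)
        if r.pathway:
            rxn.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'><p>SUBSYSTEM: {r.pathway}</p></body>"
            )
        for met, coef in r.stoichiometry.items():
            sr = rxn.createReactant() if coef < 0 else rxn.createProduct()
            sr.setSpecies(f"M_{met}")
            sr.setStoichiometry(abs(coef))
        kl = rxn.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", r.lower_bound),
            ("UPPER_BOUND", r.upper_bound),
            ("FLUX_VALUE", 0.0),
        ):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setUnits("dimensionless")
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# public IO


def _read_roles(path: Path) -> tuple[dict[str, str], str | None]:
    roles: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            role, rid = line.split("\t")[:2]
            roles[role.strip()] = rid.strip()
    return roles, roles.get("biomass")


def load_network(
    path: str | Path,
    dialect: str = "tabular",
    roles: str | Path | None = None,
) -> MetabolicNetwork:
    """Load a model from ``path``.

    Parameters
    ----------
    path : file path
    dialect : {"tabular", "sbml"}
    roles : optional path to a two-column role-map file (role, reaction id);
        the ``biomass`` role also sets ``biomass_reaction_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tabular":
        reactions, biomass_id = _read_tabular(path)
    elif dialect == "sbml":
        reactions, biomass_id = _read_sbml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    named: dict[str, str] = {}
    if roles is not None:
        named, role_biomass = _read_roles(Path(roles))
        if role_biomass is not None:
            biomass_id = role_biomass
    return _finalize({}, reactions, biomass_id, named, model_id=path.stem)


def write_network(net: MetabolicNetwork, path: str | Path, dialect: str = "tabular") -> None:
    """Write a model; round-trips matrix, bounds and reversibility."""
    path = Path(path)
    if dialect == "tabular":
        _write_tabular(net, path)
    elif dialect == "sbml":
        _write_sbml(net, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_engro1() -> MetabolicNetwork:
    """Load the bundled core glucose/glutamine network.

    The bundled file is a *synthetic reconstruction* of the published ENGRO1
    core model (84 reactions, 67 metabolites), rebuilt from its documented
    pathway inventory and calibrated to its documented operating points; the
    original supplementary model files are not redistributed here.
    """
    data = Path(__file__).parent / "data"
    return load_network(
        data / "engro1_synthetic.tsv",
        dialect="tabular",
        roles=data / "engro1_synthetic_roles.tsv",
    )


def build_network(
    reactions: list[Reaction],
    biomass_reaction_id: str | None = None,
    named_reactions: Mapping[str, str] | None = None,
    model_id: str = "model",
) -> MetabolicNetwork:
    """Assemble a network from reactions alone (metabolites inferred)."""
    return _finalize({}, reactions, biomass_reaction_id, named_reactions, model_id)


# ---------------------------------------------------------------------------
# operations


def stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    return net.stoichiometric_matrix()


#: Roles eligible for `set_availability` (uptake / efflux reactions).
_AVAILABILITY_ROLES = {
    "glucose_uptake",
    "glutamine_uptake",
    "oxygen_uptake",
    "lactate_efflux",
    "ammonia_efflux",
}


def set_availability(
    net: MetabolicNetwork,
    nutrient: str,
    value: float,
    fix: bool = False,
    inplace: bool = False,
) -> MetabolicNetwork:
    """Set the availability of a nutrient (upper bound of its import).

    With ``fix=True`` the flux is pinned to ``value`` (both bounds), i.e. a
    prescribed uptake flux instead of a maximal rate.
    """
    if value < 0:
        raise ValueError(f"availability must be non-negative, got {value}")
    if nutrient not in _AVAILABILITY_ROLES:
        raise KeyError(
            f"unknown availability role {nutrient!r}; expected one of "
            f"{sorted(_AVAILABILITY_ROLES)}"
        )
    out = net if inplace else net.copy()
    rid = out.named_reactions[nutrient]
    out.set_bounds(rid, lower=value if fix else None, upper=value)
    return out


def verify_loopless(net: MetabolicNetwork, flux_epsilon: float = 1e-6) -> list[str]:
    """Report internal reactions able to carry flux with every exchange closed.

    All exchange reactions are bounded to zero; for each remaining reaction
    the maximal absolute steady-state flux is computed.  Any reaction with a
    nonzero maximum belongs to a thermodynamically infeasible internal cycle.
    Returns the (possibly empty) list of implicated reaction ids.
    """
    from .fba import _LPProblem  # local import to avoid a cycle

    closed = net.copy()
    for r in closed.reactions:
        if r.is_exchange:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    lp = _LPProblem(closed)
    members: list[str] = []
    for r in closed.reactions:
        if r.is_exchange:
            continue
        hit = False
        for sense in (+1.0, -1.0):
            status, obj, _ = lp.solve({r.id: sense}, maximize=True)
            if status == "optimal" and obj > flux_epsilon:
                hit = True
                break
        if hit:
            members.append(r.id)
    return members
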