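"""Constraint-based metabolic model container and steady-state FBA solver.

A :class:`MetabolicModel` is a stoichiometric matrix S with flux bounds and a
biomass objective.  Flux balance analysis (FBA) maximizes the biomass flux
subject to the steady-state constraint S·v = 0 and lb ≤ v ≤ ub.  Exchange
reactions follow the secretion-positive sign convention: an exchange reaction
consumes exactly one external metabolite with coefficient −1, so positive flux
secretes the metabolite into the medium and negative flux takes it up.

Units are fixed package-wide: flux in mmol·gDW⁻¹·h⁻¹, biomass in pg
(1 pg = 1e−12 gDW), time in h.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Compartment",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxStatus",
    "FluxSolution",
    "ModelValidationError",
    "SolverError",
    "solve_fba",
    "find_blocked_reactions",
    "blocked_percentage",
    "check_balances",
    "read_model",
    "write_model",
]

#: feasibility/optimality tolerance handed to the LP solver
LP_TOLERANCE = 1e-9
#: bound magnitude used when an exchange is "fully open"
OPEN_BOUND = 1000.0
#: flux magnitudes below this are treated as zero (solver noise)
ZERO_FLUX_TOL = 1e-8


class ModelValidationError(ValueError):
    """Raised when a model or an override violates the structural contract."""


class SolverError(RuntimeError):
    """Raised when the LP solver fails for a reason other than infeasibility."""


class Compartment(str, Enum):
    internal = "internal"
    external = "external"


class FluxStatus(str, Enum):
    optimal = "optimal"
    infeasible = "infeasible"
    unbounded = "unbounded"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.internal
    formula: str | None = None
    charge: int | None = None


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed, positive = produced).  Exchange reactions have
    exactly one metabolite, external, with coefficient −1.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    is_exchange: bool = False
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def exchanged_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id!r} is not an exchange reaction")
        (met,) = self.stoichiometry
        return met


@dataclass
class MetabolicModel:
    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, met_id: str) -> Reaction | None:
        """Exchange reaction moving ``met_id``, or None if the model has none."""
        for r in self.exchange_reactions:
            if r.exchanged_metabolite == met_id:
                return r
        return None

    # -- structure ---------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites × reactions)."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_pos[met], j] = coef
        return S

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

        if self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        if self._rxn_index[self.biomass_reaction_id].objective_coefficient != 1:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} must carry "
                "objective_coefficient 1"
            )
        for rxn in self.reactions:
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            for met in rxn.stoichiometry:
                if met not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            if rxn.is_exchange:
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r} must have exactly one metabolite"
                    )
                met, coef = next(iter(rxn.stoichiometry.items()))
                if coef != -1:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r}: coefficient must be −1 "
                        "(positive flux = secretion)"
                    )
                if self._met_index[met].compartment is not Compartment.external:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r}: metabolite {met!r} must be external"
                    )


@dataclass(frozen=True)
class FluxSolution:
    status: FluxStatus
    growth_rate: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status is FluxStatus.optimal


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

_INFEASIBLE = FluxSolution(status=FluxStatus.infeasible, growth_rate=0.0, fluxes={})


def _effective_bounds(
    model: MetabolicModel,
    bound_overrides: Mapping[str, tuple[float, float]] | None,
) -> list[tuple[float, float]]:
    overrides = dict(bound_overrides or {})
    for rid, (lb, ub) in overrides.items():
        if rid not in model._rxn_index:
            raise ModelValidationError(f"bound override references unknown reaction {rid!r}")
        if lb > ub:
            raise ModelValidationError(
                f"bound override for {rid!r}: lb {lb} > ub {ub}"
            )
    return [
        overrides.get(r.id, (r.lower_bound, r.upper_bound)) for r in model.reactions
    ]


def _linprog(c: np.ndarray, S: np.ndarray, bounds: Sequence[tuple[float, float]]):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(bounds),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )


def solve_fba(
    model: MetabolicModel,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    minimize_total_flux: bool = False,
) -> FluxSolution:
    """Maximize biomass flux under S·v = 0 and bounds.

    Parameters
    ----------
    bound_overrides
        Per-reaction ``(lb, ub)`` replacing the model bounds for this solve
        (used by the arena to impose local substrate availability).
    minimize_total_flux
        When True, a secondary LP fixes the biomass optimum and minimizes the
        total absolute flux (parsimonious FBA), giving a unique, stable flux
        report on degenerate optimal faces.  Off by default.

    Infeasible problems return ``status=infeasible`` with zero growth and no
    fluxes — in the simulation such an agent neither grows nor exchanges.
    """
    bounds = _effective_bounds(model, bound_overrides)
    S = model.stoichiometric_matrix()
    c = -np.array([r.objective_coefficient for r in model.reactions])
    res = _linprog(c, S, bounds)
    if res.status == 2:  # infeasible
        return _INFEASIBLE
    if res.status == 3:
        return FluxSolution(status=FluxStatus.unbounded, growth_rate=float("inf"))
    if not res.success:
        raise SolverError(
            f"LP solver failed (status {res.status}) on model {model.species_id!r}; "
            f"reactions: {model.reaction_ids}"
        )
    growth = float(-res.fun)
    v = res.x
    if minimize_total_flux:
        v = _parsimonious(model, S, bounds, growth)
    fluxes = {
        r.id: (0.0 if abs(x) < ZERO_FLUX_TOL else float(x))
        for r, x in zip(model.reactions, v)
    }
    return FluxSolution(
        status=FluxStatus.optimal,
        growth_rate=growth if growth > 0 else 0.0,
        fluxes=fluxes,
    )


def _parsimonious(
    model: MetabolicModel,
    S: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    optimum: float,
) -> np.ndarray:
    """Minimize Σ|v| subject to S·v = 0, bounds, and biomass fixed at optimum.

    Split-variable formulation v = p − q, p,q ≥ 0; small relaxation of the
    fixed optimum guards against tolerance-level infeasibility.
    """
    n = S.shape[1]
    bio = model.reaction_ids.index(model.biomass_reaction_id)
    slack = max(1e-9, abs(optimum)) * 1e-9
    fixed = list(bounds)
    fixed[bio] = (optimum - slack, bounds[bio][1])
    lo = np.array([b[0] for b in fixed])
    hi = np.array([b[1] for b in fixed])
    # p in [max(lo,0), max(hi,0)], q in [max(-hi,0), max(-lo,0)]
    p_bounds = [(max(l, 0.0), max(h, 0.0)) for l, h in zip(lo, hi)]
    q_bounds = [(max(-h, 0.0), max(-l, 0.0)) for l, h in zip(lo, hi)]
    A = np.hstack([S, -S])
    res = linprog(
        np.ones(2 * n),
        A_eq=A,
        b_eq=np.zeros(S.shape[0]),
        bounds=p_bounds + q_bounds,
        method="highs",
        options={"presolve": True},
    )
    if not res.success:
        raise SolverError(
            f"parsimonious refinement failed on model {model.species_id!r}"
        )
    return res.x[:n] - res.x[n:]


def find_blocked_reactions(model: MetabolicModel) -> set[str]:
    """Reactions that carry zero flux in every feasible state with all
    exchanges fully open (per-reaction flux maximization and minimization)."""
    bounds = []
    for r in model.reactions:
        if r.is_exchange:
            bounds.append((-OPEN_BOUND, OPEN_BOUND))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    S = model.stoichiometric_matrix()
    blocked: set[str] = set()
    n = len(model.reactions)
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = -1.0
        hi = _linprog(c, S, bounds)
        if hi.success and -hi.fun > ZERO_FLUX_TOL:
            continue
        c[j] = 1.0
        lo = _linprog(c, S, bounds)
        if lo.success and lo.fun < -ZERO_FLUX_TOL:
            continue
        blocked.add(rxn.id)
    return blocked


def blocked_percentage(model: MetabolicModel) -> float:
    """Blocked reactions as a percentage of the model's reaction count."""
    return 100.0 * len(find_blocked_reactions(model)) / len(model.reactions)


# ---------------------------------------------------------------------------
# Mass / charge balance
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula like ``C6H12O6``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"unparseable formula {formula!r}")
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_TOKEN.findall(formula):
        if elem:
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


@dataclass(frozen=True)
class BalanceReport:
    reaction_id: str
    checked: bool
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float | None = None
    note: str = ""

    @property
    def balanced(self) -> bool:
        return (
            self.checked
            and not self.element_imbalance
            and not self.charge_imbalance
        )


def check_balances(model: MetabolicModel) -> list[BalanceReport]:
    """Net elemental and charge imbalance per non-exchange reaction.

    Exchange reactions are boundary passages and excluded by definition.
    Reactions touching a metabolite without a formula (or with an
    unparseable one) are reported as unchecked rather than failing.
    """
    reports = []
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.biomass_reaction_id:
            continue
        elems: dict[str, float] = {}
        charge = 0.0
        have_charge = True
        try:
            for met_id, coef in rxn.stoichiometry.items():
                met = model.metabolite(met_id)
                if met.formula is None:
                    raise ValueError(f"metabolite {met_id!r} has no formula")
                for elem, count in parse_formula(met.formula).items():
                    elems[elem] = elems.get(elem, 0.0) + coef * count
                if met.charge is None:
                    have_charge = False
                else:
                    charge += coef * met.charge
        except ValueError as exc:
            reports.append(BalanceReport(rxn.id, checked=False, note=str(exc)))
            continue
        imbalance = {e: v for e, v in elems.items() if abs(v) > 1e-9}
        charge_imb = charge if have_charge and abs(charge) > 1e-9 else (
            None if not have_charge else 0.0
        )
        reports.append(
            BalanceReport(
                rxn.id,
                checked=True,
                element_imbalance=imbalance,
                charge_imbalance=charge_imb if charge_imb else None,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# I/O — toy_json dialect and SBML L3/FBC
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    mets = []
    for m in model.metabolites:
        entry: dict = {"id": m.id, "name": m.name, "compartment": m.compartment.value}
        if m.formula is not None:
            entry["formula"] = m.formula
        if m.charge is not None:
            entry["charge"] = m.charge
        mets.append(entry)
    rxns = [
        {
            "id": r.id,
            "stoich": dict(r.stoichiometry),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "exchange": r.is_exchange,
            "objective": int(r.objective_coefficient),
        }
        for r in model.reactions
    ]
    return {
        "species_id": model.species_id,
        "metabolites": mets,
        "reactions": rxns,
        "biomass": model.biomass_reaction_id,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    if "biomass" not in data or not data["biomass"]:
        raise ModelValidationError("model file has no biomass/objective entry")
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=Compartment(m["compartment"]),
            formula=m.get("formula"),
            charge=m.get("charge"),
        )
        for m in data["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoich"].items()},
            lower_bound=float(r["lb"]),
            upper_bound=float(r["ub"]),
            is_exchange=bool(r["exchange"]),
            objective_coefficient=float(r.get("objective", 0)),
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(
        species_id=data["species_id"],
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=data["biomass"],
    )


def _read_sbml(path: str) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cm = read_sbml_model(str(path))
    objective_rxns = [
        r for r in cm.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if not objective_rxns:
        raise ModelValidationError(f"SBML model {path!r} declares no objective")
    biomass = objective_rxns[0].id
    external = {m.id for r in cm.exchanges for m in r.metabolites}
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=(
                Compartment.external if m.id in external else Compartment.internal
            ),
            formula=m.formula or None,
            charge=m.charge,
        )
        for m in cm.metabolites
    ]
    exchange_ids = {r.id for r in cm.exchanges}
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        is_ex = r.id in exchange_ids
        if is_ex and len(stoich) == 1:
            # normalize boundary stoichiometry to the −1 secretion-positive form
            met, coef = next(iter(stoich.items()))
            if coef != -1:
                scale = -coef
                stoich = {met: -1.0}
                lb, ub = sorted((r.lower_bound * scale, r.upper_bound * scale))
            else:
                lb, ub = r.lower_bound, r.upper_bound
        else:
            lb, ub = r.lower_bound, r.upper_bound
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                is_exchange=is_ex,
                objective_coefficient=1.0 if r.id == biomass else 0.0,
            )
        )
    return MetabolicModel(
        species_id=cm.id or "sbml_model",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass,
    )


def read_model(path, format: str = "toy_json") -> MetabolicModel:
    """Read a model from ``toy_json`` (the package's JSON dialect) or SBML."""
    if format == "toy_json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "toy_json") -> None:
    if format == "toy_json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    raise ValueError(f"unsupported write format {format!r}")
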