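"""Constraint-based metabolic models and flux balance analysis.

This module is a thin, opinionated layer over COBRApy.  A model is a
:class:`cobra.Model` with two compartments (``c`` cytosol, ``e``
extracellular), a single biomass objective reaction, and boundary
exchange reactions named ``EX_<met>_e`` that each move exactly one
extracellular metabolite with coefficient -1.  Flux units are
mmol·gDW⁻¹·h⁻¹; negative exchange flux is uptake, positive is
secretion.  The biomass reaction flux is interpreted as the specific
growth rate µ in h⁻¹ (one flux unit of biomass metabolite ≡ 1 gDW).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
from cobra import Model

__all__ = [
    "FluxSolution",
    "read_model",
    "write_model",
    "fba",
    "uptake_metabolites",
    "reaction_union",
    "check_mass_balance",
    "validate_model",
    "exchange_for",
]

VALID_COMPARTMENTS = {"c", "e"}

#: primal feasibility tolerance used when asserting S·v = 0 and bounds
FEASIBILITY_TOL = 1e-9


@dataclass
class FluxSolution:
    """Result of one linear-programming flux optimization."""

    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    status: str = "optimal"  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class ModelValidationError(ValueError):
    """A model violates the structural contract of this pipeline."""


def validate_model(model: Model) -> Model:
    """Check the structural invariants a pipeline model must satisfy.

    Raises :class:`ModelValidationError` naming the offending reaction or
    metabolite; returns the model unchanged when valid.
    """
    for met in model.metabolites:
        if met.compartment not in VALID_COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
            )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
    objective_rxns = [
        r for r in model.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective_rxns) != 1:
        raise ModelValidationError(
            f"model {model.id!r}: expected exactly one objective (biomass) "
            f"reaction, found {len(objective_rxns)}"
        )
    for rxn in model.exchanges:
        mets = list(rxn.metabolites.items())
        if len(mets) != 1 or mets[0][1] != -1 or mets[0][0].compartment != "e":
            raise ModelValidationError(
                f"exchange {rxn.id!r} must consume exactly one extracellular "
                "metabolite with coefficient -1"
            )
    return model


def read_model(path: str, format: str | None = None) -> Model:
    """Read a model from SBML (Level 3 + FBC) or the COBRA JSON dialect.

    ``format`` may be ``"sbml"`` or ``"json"``; when omitted it is inferred
    from the file extension.  The returned model has been validated.
    """
    if format is None:
        format = "json" if str(path).endswith(".json") else "sbml"
    if format == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    elif format == "json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")
    return validate_model(model)


def write_model(model: Model, path: str, format: str | None = None) -> None:
    """Write a model as SBML Level 3 + FBC or COBRA JSON."""
    if format is None:
        format = "json" if str(path).endswith(".json") else "sbml"
    if format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif format == "json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def fba(
    model: Model,
    objective: str | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Maximize a reaction flux subject to S·v = 0 and the flux bounds.

    ``bound_overrides`` maps reaction ids to temporary ``(lb, ub)`` pairs;
    the model's own bounds (and objective) are restored before returning,
    so a single model instance can be shared across many solves.
    """
    saved_bounds: dict[str, tuple[float, float]] = {}
    saved_objective = None
    try:
        if bound_overrides:
            for rxn_id, (lb, ub) in bound_overrides.items():
                rxn = model.reactions.get_by_id(rxn_id)
                saved_bounds[rxn_id] = rxn.bounds
                rxn.bounds = (lb, ub)
        if objective is not None:
            saved_objective = model.objective
            model.objective = model.reactions.get_by_id(objective)
        solution = model.optimize()
        if solution.status != "optimal":
            status = (
                "infeasible" if solution.status == "infeasible" else solution.status
            )
            return FluxSolution(objective_value=None, fluxes={}, status=status)
        return FluxSolution(
            objective_value=float(solution.objective_value),
            fluxes={r: float(v) for r, v in solution.fluxes.items()},
            status="optimal",
        )
    finally:
        if saved_objective is not None:
            model.objective = saved_objective
        for rxn_id, bounds in saved_bounds.items():
            model.reactions.get_by_id(rxn_id).bounds = bounds


def uptake_metabolites(model: Model) -> set[str]:
    """Extracellular metabolite ids the model can take up (exchange lb < 0)."""
    taken_up: set[str] = set()
    for rxn in model.exchanges:
        if rxn.lower_bound < 0:
            (met,) = rxn.metabolites
            taken_up.add(met.id)
    return taken_up


def uptake_union(models: Iterable[Model]) -> set[str]:
    """Union of uptake metabolites over a model set (the rich-medium basis)."""
    union: set[str] = set()
    for model in models:
        union |= uptake_metabolites(model)
    return union


def reaction_union(models: Iterable[Model]) -> set[str]:
    """Union of reaction ids over a model set (reaction-content signature)."""
    union: set[str] = set()
    for model in models:
        union |= {r.id for r in model.reactions}
    return union


def exchange_for(model: Model, metabolite_id: str) -> cobra.Reaction | None:
    """The exchange reaction moving ``metabolite_id``, or None if absent."""
    rxn_id = f"EX_{metabolite_id}"
    if rxn_id in model.reactions:
        return model.reactions.get_by_id(rxn_id)
    return None


def check_mass_balance(model: Model) -> None:
    """Assert pseudo-element balance of every internal reaction.

    Boundary reactions (exchanges, demands, and the biomass drain — all
    single-metabolite by construction) are exempt, as is standard.  Raises
    :class:`ModelValidationError` naming the first unbalanced reaction.
    """
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        imbalance = rxn.check_mass_balance()
        # tolerate float dust from fractional stoichiometric coefficients
        imbalance = {k: v for k, v in imbalance.items() if abs(v) > 1e-9}
        if imbalance:
            raise ModelValidationError(
                f"reaction {rxn.id!r} in model {model.id!r} is not "
                f"mass-balanced: {imbalance}"
            )
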