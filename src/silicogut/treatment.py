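"""Personalized dietary supplement prediction and community validation.

The screening logic mirrors how a dietitian would reason over the
models: find diet metabolites that feed the depleted SCFA producers
(Clostridia, Bacteroidia) but not the overrepresented classes
(Gammaproteobacteria, Bacilli); for each such candidate, ask every
present single-species model whether raising that metabolite's uptake
ceiling from the rich-medium 1 mmol·gDW⁻¹·h⁻¹ to 1000 mmol·gDW⁻¹·h⁻¹
increases its maximal secretion of any SCFA; collect the candidates
with a positive gain as the personalized supplement plan.  The plan is
then validated at community level: a paired 24-h simulation with the
supplements added at 100× the rich-medium concentration must raise an
SCFA's final concentration by at least 25 % for the individual to count
as a responder for that SCFA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .abundance import AbundanceProfile
from .community_sim import DietSpec, SimConfig, simulate
from .flux_analysis import (
    SCFA_METABOLITES,
    MissingMetaboliteWarning,
    scfa_signature,
)
from .models import exchange_for, fba, uptake_metabolites, uptake_union

__all__ = [
    "BENEFICIAL_CLASSES",
    "DETRIMENTAL_CLASSES",
    "CandidateMetabolite",
    "TreatmentPlan",
    "ResponseReport",
    "load_catalog",
    "select_candidates",
    "screen_metabolite",
    "predict_treatment",
    "apply_and_validate",
]

BENEFICIAL_CLASSES = frozenset({"Clostridia", "Bacteroidia"})
DETRIMENTAL_CLASSES = frozenset({"Gammaproteobacteria", "Bacilli"})

BASE_UPTAKE = 1.0      # mmol/gDW/h, rich-medium screening bound
BOOST_UPTAKE = 1000.0  # mmol/gDW/h, supplemented screening bound
GAIN_EPSILON = 1e-6    # mmol/gDW/h, minimum gain to call a screen positive
TREATMENT_FACTOR = 100.0   # concentration multiplier for validation
RESPONSE_THRESHOLD = 0.25  # relative SCFA increase defining a responder


def load_catalog() -> dict[str, str]:
    """Metabolite id → broad dietary category, from the shipped catalog."""
    path = resources.files("silicogut").joinpath(
        "data/metabolite_categories.tsv"
    )
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    return dict(zip(table["metabolite_id"], table["category"]))


@dataclass(frozen=True)
class CandidateMetabolite:
    """A diet metabolite preferentially usable by beneficial classes."""

    metabolite_id: str
    category: str = "other"
    beneficial_uptakers: frozenset = frozenset()
    detrimental_uptakers: frozenset = frozenset()


@dataclass
class TreatmentPlan:
    """Per-individual supplement list with per-SCFA screening gains."""

    sample_id: str
    supplements: list[CandidateMetabolite] = field(default_factory=list)
    #: SCFA name → (baseline, supplemented) best single-model secretion
    #: optima in mmol/gDW/h over all positive screens
    gains: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def metabolite_ids(self) -> list[str]:
        return [c.metabolite_id for c in self.supplements]

    @property
    def empty(self) -> bool:
        return not self.supplements


@dataclass
class ResponseReport:
    """Community-level outcome of a plan: per-SCFA concentration change."""

    sample_id: str
    #: SCFA name → (baseline mM, treated mM, relative increase, responder)
    responses: dict[str, tuple[float, float, float, bool]]
    reason: str | None = None  # e.g. "empty_plan"

    @property
    def responders(self) -> dict[str, bool]:
        return {k: v[3] for k, v in self.responses.items()}


def select_candidates(
    present_models: dict,
    taxonomy: dict | pd.DataFrame,
    diet_metabolites=None,
    beneficial_classes=BENEFICIAL_CLASSES,
    detrimental_classes=DETRIMENTAL_CLASSES,
    mode: str = "strict",
    catalog: dict[str, str] | None = None,
) -> list[CandidateMetabolite]:
    """Diet metabolites that feed beneficial classes over detrimental ones.

    ``strict`` (default): uptakeable by at least one present
    beneficial-class model and by no present detrimental-class model.
    ``majority``: beneficial uptakers strictly outnumber detrimental
    ones.  Returns an empty list when no beneficial-class species is
    present (the untreatable-patient case).
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if isinstance(taxonomy, pd.DataFrame):
        class_of = dict(zip(taxonomy["strain_id"], taxonomy["class"]))
    else:
        class_of = dict(taxonomy)
    if catalog is None:
        catalog = load_catalog()
    if diet_metabolites is None:
        diet_metabolites = uptake_union(present_models.values())
    uptakers = {
        species: uptake_metabolites(model)
        for species, model in present_models.items()
    }
    candidates = []
    for met in sorted(diet_metabolites):
        beneficial = frozenset(
            s for s, mets in uptakers.items()
            if met in mets and class_of.get(s) in beneficial_classes
        )
        detrimental = frozenset(
            s for s, mets in uptakers.items()
            if met in mets and class_of.get(s) in detrimental_classes
        )
        if mode == "strict":
            selected = bool(beneficial) and not detrimental
        else:
            selected = len(beneficial) > len(detrimental)
        if selected:
            candidates.append(CandidateMetabolite(
                metabolite_id=met,
                category=catalog.get(met, "other"),
                beneficial_uptakers=beneficial,
                detrimental_uptakers=detrimental,
            ))
    return candidates


def screen_metabolite(
    model,
    candidate_id: str,
    scfa_metabolite: str,
    diet_metabolites,
    base_uptake: float = BASE_UPTAKE,
    boost_uptake: float = BOOST_UPTAKE,
):
    """Gain in a model's maximal SCFA secretion from boosting one uptake.

    Both LPs run on the same model: the baseline allows every diet
    metabolite at uptake ``base_uptake``; the boosted problem relaxes
    only the candidate's uptake to ``boost_uptake``.  Returns
    ``(baseline, boosted, gain)`` in mmol·gDW⁻¹·h⁻¹, or ``None`` when
    the baseline LP is infeasible (candidate skipped with a warning).
    The boosted problem is a relaxation, so the gain is non-negative.
    """
    scfa_ex = exchange_for(model, scfa_metabolite)
    if scfa_ex is None:
        return 0.0, 0.0, 0.0  # model cannot secrete this SCFA at all
    overrides = {}
    for met in diet_metabolites:
        rxn = exchange_for(model, met)
        if rxn is not None:
            overrides[rxn.id] = (-base_uptake, rxn.upper_bound)
    baseline = fba(model, objective=scfa_ex.id, bound_overrides=overrides)
    if not baseline.optimal:
        warnings.warn(
            f"baseline screen infeasible for {model.id}; "
            f"skipping {candidate_id}",
            stacklevel=2,
        )
        return None
    cand_rxn = exchange_for(model, candidate_id)
    if cand_rxn is None:
        return baseline.objective_value, baseline.objective_value, 0.0
    boosted_overrides = dict(overrides)
    boosted_overrides[cand_rxn.id] = (-boost_uptake, cand_rxn.upper_bound)
    boosted = fba(model, objective=scfa_ex.id,
                  bound_overrides=boosted_overrides)
    if not boosted.optimal:
        return None
    gain = boosted.objective_value - baseline.objective_value
    assert gain >= -1e-6, (
        "boosted LP must relax the baseline; got a negative gain"
    )
    return baseline.objective_value, boosted.objective_value, max(0.0, gain)


def predict_treatment(
    profile: AbundanceProfile,
    models: dict,
    taxonomy,
    scfas=tuple(SCFA_METABOLITES),
    gain_epsilon: float = GAIN_EPSILON,
    mode: str = "strict",
    catalog: dict[str, str] | None = None,
) -> TreatmentPlan:
    """Personalized supplement plan for one individual.

    Candidates are screened independently (one at a time) against every
    present model and every SCFA; a candidate joins the plan when any
    screen gains more than ``gain_epsilon``.  The outcome is
    deterministic and invariant to screening order.
    """
    present_models = {s: models[s] for s in sorted(profile.abundances)}
    diet_metabolites = sorted(uptake_union(present_models.values()))
    candidates = select_candidates(
        present_models, taxonomy, diet_metabolites, mode=mode, catalog=catalog
    )
    plan = TreatmentPlan(sample_id=profile.sample_id)
    best_gains: dict[str, tuple[float, float]] = {}
    for candidate in candidates:
        positive = False
        for species in sorted(candidate.beneficial_uptakers):
            model = present_models[species]
            for scfa_name in scfas:
                met = SCFA_METABOLITES.get(scfa_name, scfa_name)
                screen = screen_metabolite(
                    model, candidate.metabolite_id, met, diet_metabolites
                )
                if screen is None:
                    continue
                baseline, boosted, gain = screen
                if gain > gain_epsilon:
                    positive = True
                    prev = best_gains.get(scfa_name)
                    if prev is None or boosted - baseline > prev[1] - prev[0]:
                        best_gains[scfa_name] = (baseline, boosted)
        if positive:
            plan.supplements.append(candidate)
    plan.gains = best_gains
    return plan


def response_tuple(
    baseline_mm: float,
    treated_mm: float,
    threshold: float = RESPONSE_THRESHOLD,
) -> tuple[float, float, float, bool]:
    """(baseline, treated, relative increase, responder) for one SCFA.

    Responder ⇔ relative increase ≥ threshold; with a zero baseline any
    positive treated concentration counts as a response.
    """
    if baseline_mm > 0:
        rel = (treated_mm - baseline_mm) / baseline_mm
        return baseline_mm, treated_mm, rel, rel >= threshold
    rel = float("inf") if treated_mm > 0 else 0.0
    return baseline_mm, treated_mm, rel, treated_mm > 0


def apply_and_validate(
    profile: AbundanceProfile,
    models: dict,
    plan: TreatmentPlan,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    factor: float = TREATMENT_FACTOR,
    response_threshold: float = RESPONSE_THRESHOLD,
) -> ResponseReport:
    """Validate a plan with paired community simulations.

    Baseline: the rich medium.  Treated: the rich medium plus the plan's
    supplements at ``factor`` × the rich-medium concentration, same
    seed.  Per SCFA the individual responds when the relative increase
    of the final concentration is at least ``response_threshold``; with
    a zero baseline any positive treated concentration counts.
    """
    if plan.empty:
        responses = {name: (0.0, 0.0, 0.0, False)
                     for name in SCFA_METABOLITES}
        return ResponseReport(profile.sample_id, responses,
                              reason="empty_plan")
    baseline_run = simulate(profile, models, config=config, seed=seed)
    supplement = DietSpec(
        {m: factor * config.medium_conc_um for m in plan.metabolite_ids},
        unit="uM",
    )
    treated_run = simulate(profile, models, config=config, seed=seed,
                           extra_diet=supplement)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingMetaboliteWarning)
        base_sig = scfa_signature(baseline_run, profile.sample_id)
        treat_sig = scfa_signature(treated_run, profile.sample_id)
    responses = {
        name: response_tuple(
            base_sig.concentrations.get(name, 0.0),
            treat_sig.concentrations.get(name, 0.0),
            response_threshold,
        )
        for name in SCFA_METABOLITES
    }
    return ResponseReport(profile.sample_id, responses)
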