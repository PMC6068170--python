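"""Candidate selection, single-model screening, plan prediction, and
community-level validation of personalized supplements."""

import numpy as np
import pytest

from silicogut.abundance import AbundanceProfile, bray_curtis, class_abundances
from silicogut.community_sim import simulate
from silicogut.flux_analysis import SCFA_METABOLITES
from silicogut.synthetic_data import cohort_models, universe_taxonomy
from silicogut.treatment import (
    apply_and_validate,
    predict_treatment,
    response_tuple,
    screen_metabolite,
    select_candidates,
)
from silicogut.workflow import simulation_seed


@pytest.fixture(scope="module")
def universe():
    return cohort_models(), universe_taxonomy()


def profile_for(universe, weights):
    """Abundance profile over one representative strain per class."""
    strains = {
        "Bacteroidia": "Bacteroides_sp_000",
        "Clostridia": "Faecalibacterium_sp_005",
        "Bacilli": "Lactobacillus_sp_010",
        "Gammaproteobacteria": "Escherichia_sp_015",
        "Other": "Bifidobacterium_sp_020",
    }
    total = sum(weights.values())
    return AbundanceProfile(
        "fixture", {strains[c]: w / total for c, w in weights.items()}
    )


RESPONDER_WEIGHTS = {"Bacteroidia": 0.30, "Clostridia": 0.20,
                     "Bacilli": 0.25, "Gammaproteobacteria": 0.25}
UNTREATABLE_WEIGHTS = {"Bacilli": 0.5, "Gammaproteobacteria": 0.5}


def present_models(universe, prof):
    models, _ = universe
    return {s: models[s] for s in prof.abundances}


def test_select_candidates_strict_rule(universe):
    models, taxonomy = universe
    prof = profile_for(universe, RESPONDER_WEIGHTS)
    candidates = select_candidates(present_models(universe, prof), taxonomy)
    ids = {c.metabolite_id for c in candidates}
    # fiber feeds only the Bacteroidia fermenter among present uptakers
    assert "fiber_e" in ids
    # glucose feeds every class, including the detrimental ones
    assert "glc_e" not in ids
    fiber = next(c for c in candidates if c.metabolite_id == "fiber_e")
    assert fiber.category == "plant_polysaccharide"
    assert not fiber.detrimental_uptakers


def test_select_candidates_empty_without_beneficial_species(universe):
    models, taxonomy = universe
    prof = profile_for(universe, UNTREATABLE_WEIGHTS)
    assert select_candidates(present_models(universe, prof), taxonomy) == []


def test_select_candidates_majority_mode(universe):
    models, taxonomy = universe
    prof = profile_for(universe, RESPONDER_WEIGHTS)
    strict = select_candidates(present_models(universe, prof), taxonomy)
    relaxed = select_candidates(present_models(universe, prof), taxonomy,
                                mode="majority")
    # every strict candidate also passes the majority rule
    assert {c.metabolite_id for c in strict} <= {
        c.metabolite_id for c in relaxed}
    with pytest.raises(ValueError):
        select_candidates(present_models(universe, prof), taxonomy,
                          mode="bogus")


def test_screen_fiber_boost_gain(universe):
    """Hand LP: fiber → 3 propionate; relaxing fiber uptake 1 → 1000
    raises the propionate optimum 3 → 3000 (gain 2997)."""
    models, _ = universe
    model = models["Bacteroides_sp_000"]
    baseline, boosted, gain = screen_metabolite(
        model, "fiber_e", "ppa_e", ["glc_e", "fiber_e"]
    )
    assert baseline == pytest.approx(3.0)
    assert boosted == pytest.approx(3000.0)
    assert gain == pytest.approx(2997.0)


def test_screen_unconnected_candidate_gains_nothing(universe):
    models, _ = universe
    # the lactate producer has no fiber pathway at all
    baseline, boosted, gain = screen_metabolite(
        models["Lactobacillus_sp_010"], "fiber_e", "lac_e", ["glc_e"]
    )
    assert gain == 0.0
    # an SCFA the model cannot secrete screens as 0 throughout
    assert screen_metabolite(
        models["Lactobacillus_sp_010"], "glc_e", "but_e", ["glc_e"]
    ) == (0.0, 0.0, 0.0)


def test_screen_gains_are_nonnegative(universe):
    models, taxonomy = universe
    diet = ["glc_e", "fiber_e", "ac_e"]
    for model in models.values():
        for candidate in diet:
            for met in SCFA_METABOLITES.values():
                screen = screen_metabolite(model, candidate, met, diet)
                assert screen is None or screen[2] >= 0.0


def test_predict_treatment_deterministic_and_order_invariant(universe):
    models, taxonomy = universe
    prof = profile_for(universe, RESPONDER_WEIGHTS)
    plan1 = predict_treatment(prof, models, taxonomy)
    plan2 = predict_treatment(prof, models, taxonomy)
    plan3 = predict_treatment(prof, models, taxonomy,
                              scfas=tuple(reversed(tuple(SCFA_METABOLITES))))
    assert plan1.metabolite_ids == plan2.metabolite_ids == plan3.metabolite_ids
    assert not plan1.empty


def test_plans_differ_between_patients(cohort_run):
    """Across dysbiotic patients, supplement plans track which species
    are present rather than being one-size-fits-all."""
    plans = {
        sid: tuple(predict_treatment(
            cohort_run.profiles[sid], cohort_run.models, cohort_run.taxonomy
        ).metabolite_ids)
        for sid in cohort_run.group("cd")
    }
    assert len(set(plans.values())) > 1


@pytest.mark.parametrize("baseline,treated,expected", [
    (10.0, 13.0, True),   # +30 %
    (10.0, 12.0, False),  # +20 %
    (0.0, 0.5, True),     # zero-baseline rule
    (0.0, 0.0, False),
])
def test_response_threshold_arithmetic(baseline, treated, expected):
    *_, responder = response_tuple(baseline, treated)
    assert responder is expected


def test_responder_fixture_recovers_propionate(universe):
    """End-to-end: the dysbiotic patient that still harbors a fiber
    fermenter gets a non-empty plan whose 100× supplementation raises
    propionate by ≥ 25 %."""
    models, taxonomy = universe
    prof = profile_for(universe, RESPONDER_WEIGHTS)
    plan = predict_treatment(prof, models, taxonomy)
    assert not plan.empty
    report = apply_and_validate(prof, models, plan, seed=5)
    assert report.responses["propionate"][3] is True
    assert report.responses["propionate"][2] >= 0.25


def test_untreatable_fixture_yields_empty_plan(universe):
    models, taxonomy = universe
    prof = profile_for(universe, UNTREATABLE_WEIGHTS)
    plan = predict_treatment(prof, models, taxonomy)
    assert plan.empty
    report = apply_and_validate(prof, models, plan, seed=5)
    assert report.reason == "empty_plan"
    assert not any(report.responders.values())


def test_treatment_barely_shifts_abundances(universe, cohort_run):
    """Class-level Bray-Curtis between baseline and treated final
    abundances stays well below the healthy/dysbiotic between-group
    distance: supplements change metabolite output, not who is there."""
    models, taxonomy = universe
    prof = profile_for(universe, RESPONDER_WEIGHTS)
    plan = predict_treatment(prof, models, taxonomy)
    class_of = dict(zip(taxonomy["strain_id"], taxonomy["class"]))

    def class_vector(counts):
        sums = {}
        for species, n in counts.items():
            cls = class_of[species]
            sums[cls] = sums.get(cls, 0) + n
        total = sum(sums.values())
        return np.array([
            sums.get(c, 0) / total
            for c in ("Bacteroidia", "Clostridia", "Bacilli",
                      "Gammaproteobacteria", "Other")
        ])

    base = simulate(prof, models, seed=5)
    from silicogut.community_sim import DietSpec
    supplement = DietSpec(
        {m: 100 * 0.2 for m in plan.metabolite_ids}, unit="uM")
    treated = simulate(prof, models, seed=5, extra_diet=supplement)
    shift = bray_curtis(class_vector(base.abundance_series[-1]),
                        class_vector(treated.abundance_series[-1]))
    table = class_abundances(cohort_run.profiles.values())
    healthy_mean = table.loc[cohort_run.group("healthy")].mean()
    cd_mean = table.loc[cohort_run.group("cd")].mean()
    group_distance = bray_curtis(healthy_mean.to_numpy(),
                                 cd_mean.to_numpy())
    assert shift < group_distance
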