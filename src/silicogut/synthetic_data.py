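"""Synthetic cohort and toy metabolic models.

Everything downstream — abundance estimation, agent-based community
simulation, SCFA signatures, and treatment prediction — is exercised on
a miniature synthetic world generated here:

* **Toy models.**  One small, carbon-balanced metabolic network per
  ecological role.  Each metabolite carries an integer pseudo-element
  vector (``C<n>`` in its formula) so that stoichiometric mass balance
  is checkable without real chemistry.  The roles encode the division of
  labor observed in gut communities: Bacteroidia-type fiber fermenters
  secrete propionate (plus acetate and a little isobutyrate), Clostridia
  cross-feed on acetate to make butyrate, Bacilli ferment glucose to
  L-lactate, Gammaproteobacteria overflow acetate, and a generalist
  competes for every substrate while secreting only isobutyrate and an
  inert waste product.

* **Cohort.**  A two-group cohort (healthy vs dysbiotic/CD) of per-sample
  genome-coverage tables.  Healthy samples are dominated by Bacteroidia
  and Clostridia and are more diverse; dysbiotic samples are dominated
  by Bacilli and Gammaproteobacteria with fewer species.  Tables include
  sub-threshold "noise" strains so the 1 %-breadth filter has work to do.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the cohort spec, so regeneration is byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .models import check_mass_balance, validate_model

__all__ = [
    "TAXON_CLASSES",
    "ROLES",
    "ToyModelSpec",
    "CohortSpec",
    "STRAIN_UNIVERSE",
    "generate_toy_models",
    "generate_cohort",
    "cohort_models",
    "universe_taxonomy",
]

TAXON_CLASSES = (
    "Bacteroidia",
    "Clostridia",
    "Bacilli",
    "Gammaproteobacteria",
    "Other",
)

ROLES = (
    "fiber_propionate",
    "butyrate_crossfeeder",
    "lactate_producer",
    "acetate_producer",
    "generalist",
)

#: roles whose models secrete at least one tracked fermentation product
SCFA_PRODUCING_ROLES = frozenset(ROLES) - {"generalist"}

#: carbon pseudo-element content of the shared metabolite namespace
METABOLITE_CARBONS = {
    "glc": 6,     # glucose — universal carbon source
    "fiber": 24,  # polysaccharide fiber — Bacteroidia substrate
    "ac": 2,      # acetate
    "ppa": 3,     # propionate
    "but": 4,     # butyrate
    "ibut": 4,    # isobutyrate
    "lac": 3,     # L-lactate
    "waste": 1,   # inert fermentation waste (not an SCFA)
}

# Default exchange lower bounds (mmol gDW^-1 h^-1).  Glucose uptake is
# generous so communities grow and divide early; fiber and acetate uptake
# are slow enough that over 24 h the community is capacity-limited, which
# makes substrate allocation track species abundance and leaves headroom
# for dietary supplementation to raise consumption.
GLC_UPTAKE_LB = -10.0
SLOW_UPTAKE_LB = -0.05

# Secretion is effectively uncapped (well above the 1000 mmol/gDW/h
# boosted-uptake screening bound, so exports never clip a screen).
SECRETION_BOUNDS = (0.0, 1e6)
INTERNAL_UB = 1e6


@dataclass(frozen=True)
class ToyModelSpec:
    """Specification of one toy organism.

    ``yield_params`` optionally replaces the stoichiometry of a named
    reaction (map reaction id → {metabolite id: coefficient}); replacements
    must stay carbon-balanced or model construction fails hard.
    """

    species_id: str
    taxon_class: str
    role: str
    yield_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(f"unknown taxon class {self.taxon_class!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


# Each role template is a list of internal (non-boundary) reactions:
# (reaction id, {metabolite id: coefficient}, lb, ub).  Metabolite ids end
# in _c (cytosol) or _e (extracellular); "bm_c" is the biomass metabolite,
# whose carbon content is declared per role so every internal reaction is
# balanced.  Exchanges and transports are generated from the reaction set.
ROLE_TEMPLATES: dict[str, dict] = {
    # fiber -> 3 propionate + 0.5 isobutyrate + 4 acetate + biomass(C5)
    # glucose -> biomass(C5) + 0.5 acetate
    "fiber_propionate": {
        "biomass_carbons": 5,
        "reactions": [
            ("R_fiber_ferment",
             {"fiber_c": -1, "ppa_c": 3, "ibut_c": 0.5, "ac_c": 4, "bm_c": 1}),
            ("R_glc_growth", {"glc_c": -1, "bm_c": 1, "ac_c": 0.5}),
        ],
        "uptake_bounds": {"glc": GLC_UPTAKE_LB, "fiber": SLOW_UPTAKE_LB},
    },
    # glucose -> biomass(C12); 8 acetate -> biomass(C12) + butyrate
    "butyrate_crossfeeder": {
        "biomass_carbons": 12,
        "reactions": [
            ("R_glc_growth", {"glc_c": -2, "bm_c": 1}),
            ("R_ac_to_but", {"ac_c": -8, "bm_c": 1, "but_c": 1}),
        ],
        "uptake_bounds": {"glc": GLC_UPTAKE_LB, "ac": SLOW_UPTAKE_LB},
    },
    # 2 glucose -> 3 L-lactate + biomass(C3)
    "lactate_producer": {
        "biomass_carbons": 3,
        "reactions": [
            ("R_glc_to_lac", {"glc_c": -2, "lac_c": 3, "bm_c": 1}),
        ],
        "uptake_bounds": {"glc": GLC_UPTAKE_LB},
    },
    # glucose -> 2 acetate + biomass(C2)  (overflow metabolism)
    "acetate_producer": {
        "biomass_carbons": 2,
        "reactions": [
            ("R_glc_to_ac", {"glc_c": -1, "ac_c": 2, "bm_c": 1}),
        ],
        "uptake_bounds": {"glc": GLC_UPTAKE_LB},
    },
    # 2 glucose -> biomass(C6) + 1.5 isobutyrate; also burns fiber and
    # acetate to waste, competing without boosting SCFA pools
    "generalist": {
        "biomass_carbons": 6,
        "reactions": [
            ("R_glc_growth", {"glc_c": -2, "bm_c": 1, "ibut_c": 1.5}),
            ("R_fiber_burn", {"fiber_c": -1, "bm_c": 1, "waste_c": 18}),
            ("R_ac_burn", {"ac_c": -6, "bm_c": 1, "waste_c": 6}),
        ],
        "uptake_bounds": {
            "glc": GLC_UPTAKE_LB,
            "fiber": SLOW_UPTAKE_LB,
            "ac": SLOW_UPTAKE_LB,
        },
    },
}


def _carbon_formula(met_id: str, biomass_carbons: int) -> str:
    base = met_id.rsplit("_", 1)[0]
    if base == "bm":
        return f"C{biomass_carbons}"
    return f"C{METABOLITE_CARBONS[base]}"


def build_role_model(spec: ToyModelSpec) -> Model:
    """Construct, balance-check, and validate one toy model."""
    template = ROLE_TEMPLATES[spec.role]
    bm_carbons = template["biomass_carbons"]
    model = Model(spec.species_id)
    model.name = f"{spec.species_id} ({spec.role})"

    reactions = {rid: dict(stoich) for rid, stoich in template["reactions"]}
    for rid, stoich in spec.yield_params.items():
        if rid not in reactions:
            raise ValueError(f"yield_params names unknown reaction {rid!r}")
        reactions[rid] = dict(stoich)

    mets: dict[str, Metabolite] = {}

    def met(met_id: str) -> Metabolite:
        if met_id not in mets:
            mets[met_id] = Metabolite(
                met_id,
                compartment=met_id.rsplit("_", 1)[1],
                formula=_carbon_formula(met_id, bm_carbons),
            )
        return mets[met_id]

    cobra_rxns = []
    extracellular_bases: set[str] = set()
    for rid, stoich in reactions.items():
        rxn = Reaction(rid, lower_bound=0.0, upper_bound=INTERNAL_UB)
        rxn.add_metabolites({met(m): c for m, c in stoich.items()})
        cobra_rxns.append(rxn)
        for m in stoich:
            base, comp = m.rsplit("_", 1)
            if comp == "c" and base != "bm":
                extracellular_bases.add(base)

    uptake_bounds = template["uptake_bounds"]
    for base in sorted(extracellular_bases):
        transport = Reaction(f"T_{base}", lower_bound=-INTERNAL_UB,
                             upper_bound=INTERNAL_UB)
        transport.add_metabolites({met(f"{base}_e"): -1, met(f"{base}_c"): 1})
        lb = uptake_bounds.get(base, SECRETION_BOUNDS[0])
        exchange = Reaction(f"EX_{base}_e", lower_bound=lb,
                            upper_bound=SECRETION_BOUNDS[1])
        exchange.add_metabolites({met(f"{base}_e"): -1})
        cobra_rxns.extend([transport, exchange])

    biomass = Reaction("BIOMASS", lower_bound=0.0, upper_bound=INTERNAL_UB)
    biomass.add_metabolites({met("bm_c"): -1})
    cobra_rxns.append(biomass)

    model.add_reactions(cobra_rxns)
    model.objective = "BIOMASS"
    check_mass_balance(model)
    return validate_model(model)


def generate_toy_models(specs, seed: int = 0) -> dict[str, Model]:
    """Build one validated toy model per spec, keyed by species id.

    The role templates are deterministic; ``seed`` is accepted for
    interface stability and recorded in each model's notes.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    out: dict[str, Model] = {}
    for spec in specs:
        model = build_role_model(spec)
        model.notes["seed"] = seed
        model.notes["role"] = spec.role
        model.notes["taxon_class"] = spec.taxon_class
        out[spec.species_id] = model
    return out


# ---------------------------------------------------------------------------
# strain universe and cohort generation
# ---------------------------------------------------------------------------

_GENERA = {
    "Bacteroidia": ["Bacteroides", "Prevotella", "Alistipes",
                    "Parabacteroides", "Odoribacter"],
    "Clostridia": ["Faecalibacterium", "Roseburia", "Eubacterium",
                   "Coprococcus", "Anaerostipes"],
    "Bacilli": ["Lactobacillus", "Enterococcus", "Streptococcus",
                "Lactococcus", "Pediococcus"],
    "Gammaproteobacteria": ["Escherichia", "Klebsiella", "Enterobacter",
                            "Citrobacter", "Proteus"],
    "Other": ["Bifidobacterium", "Akkermansia", "Collinsella",
              "Fusobacterium", "Desulfovibrio"],
}

_CLASS_ROLE = {
    "Bacteroidia": "fiber_propionate",
    "Clostridia": "butyrate_crossfeeder",
    "Bacilli": "lactate_producer",
    "Gammaproteobacteria": "acetate_producer",
    "Other": "generalist",
}


def _build_universe():
    universe = []
    i = 0
    for cls in TAXON_CLASSES:
        for genus in _GENERA[cls]:
            universe.append(
                {
                    "strain_id": f"{genus}_sp_{i:03d}",
                    "genus": genus,
                    "class": cls,
                    "role": _CLASS_ROLE[cls],
                    "genome_length_bp": 2_500_000 + 150_000 * i,
                }
            )
            i += 1
    return tuple(universe)


#: the fixed 25-strain reference universe (5 strains per taxon class)
STRAIN_UNIVERSE = _build_universe()


def universe_taxonomy() -> pd.DataFrame:
    """Taxonomy table (strain_id, genus, class) for the strain universe."""
    return pd.DataFrame(
        [(s["strain_id"], s["genus"], s["class"]) for s in STRAIN_UNIVERSE],
        columns=["strain_id", "genus", "class"],
    )


@dataclass
class CohortSpec:
    """Configuration of the synthetic two-group cohort.

    Defaults encode the study contrast: healthy samples rich in
    Bacteroidia + Clostridia with higher diversity, dysbiotic (CD)
    samples rich in Bacilli + Gammaproteobacteria with lower diversity.
    """

    n_healthy: int = 10
    n_cd: int = 10
    seed: int = 7
    class_mix_healthy: dict = field(default_factory=lambda: {
        "Bacteroidia": 0.35, "Clostridia": 0.35, "Bacilli": 0.10,
        "Gammaproteobacteria": 0.10, "Other": 0.10})
    class_mix_cd: dict = field(default_factory=lambda: {
        "Bacteroidia": 0.05, "Clostridia": 0.05, "Bacilli": 0.35,
        "Gammaproteobacteria": 0.35, "Other": 0.20})
    diversity_healthy: tuple[int, int] = (12, 18)
    diversity_cd: tuple[int, int] = (6, 10)
    #: Dirichlet concentration scaling abundance noise (higher = tighter)
    dirichlet_concentration: float = 60.0
    #: summed per-sample mapping depth in reads per genome bp
    total_depth: float = 0.05
    read_length_bp: int = 150
    #: per-sample count range of absent strains with sub-threshold coverage
    noise_strains: tuple[int, int] = (2, 4)

    def __post_init__(self):
        for mix in (self.class_mix_healthy, self.class_mix_cd):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("class mix must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError("class mix must be non-negative")
            scfa_mass = sum(
                v for c, v in mix.items()
                if _CLASS_ROLE.get(c) in SCFA_PRODUCING_ROLES
            )
            if scfa_mass == 0:
                warnings.warn(
                    "class mix places no mass on SCFA-producing roles; "
                    "treatment prediction will find no candidates",
                    stacklevel=3,
                )
        if max(self.diversity_cd) >= max(self.diversity_healthy):
            raise ValueError(
                "dysbiotic diversity range must lie below the healthy range"
            )
        if self.n_healthy < 1 or self.n_cd < 1:
            raise ValueError("both groups need at least one sample")


def _sample_community(rng, mix, diversity):
    n_species = int(rng.integers(diversity[0], diversity[1] + 1))
    weights = np.array(
        [mix[s["class"]] for s in STRAIN_UNIVERSE], dtype=float
    )
    weights /= weights.sum()
    n_species = min(n_species, int((weights > 0).sum()))
    idx = rng.choice(len(STRAIN_UNIVERSE), size=n_species, replace=False,
                     p=weights)
    return sorted(int(i) for i in idx)


def generate_cohort(spec: CohortSpec):
    """Generate the synthetic cohort.

    Returns ``(coverage, taxonomy, metadata)``: a tidy coverage table
    (sample_id, strain_id, genome_length_bp, mapped_reads,
    covered_fraction), the strain taxonomy, and per-sample group labels.
    Coverage breadth follows a Lander–Waterman saturation curve of the
    per-strain read depth; absent noise strains receive depths that keep
    their breadth below the 1 % detection threshold.
    """
    rng = np.random.default_rng(spec.seed)
    tau = spec.dirichlet_concentration
    rows = []
    meta = []
    groups = [("H", "healthy", spec.n_healthy, spec.class_mix_healthy,
               spec.diversity_healthy),
              ("CD", "cd", spec.n_cd, spec.class_mix_cd, spec.diversity_cd)]
    for prefix, group, n, mix, diversity in groups:
        for k in range(1, n + 1):
            sample_id = f"{prefix}{k:02d}"
            meta.append((sample_id, group))
            present = _sample_community(rng, mix, diversity)
            alpha = np.array(
                [tau * mix[STRAIN_UNIVERSE[i]["class"]] / 5.0 for i in present]
            )
            alpha = np.clip(alpha, 0.3, None)
            abund = rng.dirichlet(alpha)
            for i, a in zip(present, abund):
                strain = STRAIN_UNIVERSE[i]
                depth = a * spec.total_depth
                breadth = 1.0 - np.exp(-spec.read_length_bp * depth)
                rows.append((
                    sample_id,
                    strain["strain_id"],
                    strain["genome_length_bp"],
                    int(round(depth * strain["genome_length_bp"])),
                    round(float(breadth), 6),
                ))
            absent = [i for i in range(len(STRAIN_UNIVERSE))
                      if i not in present]
            n_noise = int(rng.integers(spec.noise_strains[0],
                                       spec.noise_strains[1] + 1))
            noise_idx = rng.choice(len(absent), size=min(n_noise, len(absent)),
                                   replace=False)
            for j in sorted(int(i) for i in noise_idx):
                strain = STRAIN_UNIVERSE[absent[j]]
                depth = float(rng.uniform(5e-7, 4e-5))
                breadth = 1.0 - np.exp(-spec.read_length_bp * depth)
                rows.append((
                    sample_id,
                    strain["strain_id"],
                    strain["genome_length_bp"],
                    int(round(depth * strain["genome_length_bp"])),
                    round(float(breadth), 6),
                ))
    coverage = pd.DataFrame(
        rows,
        columns=["sample_id", "strain_id", "genome_length_bp",
                 "mapped_reads", "covered_fraction"],
    )
    metadata = pd.DataFrame(meta, columns=["sample_id", "group"])
    return coverage, universe_taxonomy(), metadata


def cohort_models(strain_ids=None, seed: int = 0) -> dict[str, Model]:
    """Toy models for the given strains (default: the whole universe)."""
    wanted = set(strain_ids) if strain_ids is not None else None
    specs = [
        ToyModelSpec(s["strain_id"], s["class"], s["role"])
        for s in STRAIN_UNIVERSE
        if wanted is None or s["strain_id"] in wanted
    ]
    if wanted is not None and len(specs) != len(wanted):
        missing = wanted - {s.species_id for s in specs}
        raise KeyError(f"unknown strain ids: {sorted(missing)}")
    return generate_toy_models(specs, seed=seed)
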