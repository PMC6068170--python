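"""Agent-based community simulation of flux-balance-optimized microbes.

Each microbe is an individual agent on a 100×100 grid (10,000 cells,
0.025 cm² declared area) sharing a single well-mixed pool of
extracellular metabolites.  One simulated step is one hour: agents are
visited in seeded random order, each solves an FBA problem maximizing
its biomass reaction under uptake bounds tightened by the remaining
pools, the pools are updated immediately (sequential — later agents see
what earlier agents consumed or secreted), biomass grows linearly as
m ← m·(1 + µ·dt), and agents above twice the founder biomass divide
onto a random free cell.  Because the environment is declared
well-mixed, position carries no metabolic meaning; random placement at
division stands in for random movement.

Units: pools are stored in mmol (exposed in µmol where the arena
geometry is described); exchange fluxes are mmol·gDW⁻¹·h⁻¹; biomass is
gDW; concentrations are mM = mmol / arena volume in liters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .abundance import AbundanceProfile
from .models import fba, uptake_union

__all__ = [
    "assert_mass_conservation",
    "SimConfig",
    "Agent",
    "Arena",
    "DietSpec",
    "SimulationResult",
    "seed_population",
    "build_rich_medium",
    "apply_diet",
    "uptake_bounds",
    "step",
    "simulate",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation constants.

    Defaults realize the reference configuration: 100 cells per side
    (10,000 grid cells) over 0.025 cm², 500 founder microbes, 24 hourly
    steps, and a rich medium at 0.2 µM per metabolite.  The arena depth
    (0.01 cm, giving a volume of 2.5e-4 mL) and the founder biomass
    (5e-13 gDW, the order of one bacterial cell dry weight) are
    package choices required to convert concentrations to amounts and
    to anchor the division threshold; both are configurable.
    """

    side_cells: int = 100
    area_cm2: float = 0.025
    depth_cm: float = 0.01
    base_count: int = 500
    steps: int = 24
    dt_h: float = 1.0
    founder_biomass_gdw: float = 5e-13
    medium_conc_um: float = 0.2
    #: consecutive zero-growth steps before an agent is removed;
    #: None disables death entirely (the default: no death rule)
    death_after_steps: int | None = None

    @property
    def grid_cells(self) -> int:
        return self.side_cells ** 2

    @property
    def volume_l(self) -> float:
        # cm² × cm = cm³ = mL; /1000 → L
        return self.area_cm2 * self.depth_cm / 1000.0


@dataclass
class Agent:
    """One microbe individual."""

    species_id: str
    biomass: float
    position: tuple[int, int]
    alive: bool = True
    zero_growth_streak: int = 0


@dataclass(frozen=True)
class DietSpec:
    """Metabolite concentrations with a unit tag (``mM`` or ``uM``)."""

    concentrations: dict[str, float]
    unit: str = "mM"

    def __post_init__(self):
        if self.unit not in ("mM", "uM"):
            raise ValueError(f"unknown concentration unit {self.unit!r}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("diet concentrations must be non-negative")

    def in_mm(self) -> dict[str, float]:
        factor = 1.0 if self.unit == "mM" else 1e-3
        return {m: c * factor for m, c in self.concentrations.items()}

    def scaled(self, factor: float) -> "DietSpec":
        return DietSpec(
            {m: c * factor for m, c in self.concentrations.items()}, self.unit
        )

    def merged_with(self, other: "DietSpec") -> "DietSpec":
        merged = dict(self.in_mm())
        for m, c in other.in_mm().items():
            merged[m] = merged.get(m, 0.0) + c
        return DietSpec(merged, "mM")


class Arena:
    """Grid environment: agents plus one shared well-mixed metabolite pool."""

    def __init__(self, config: SimConfig = SimConfig(), seed: int = 0):
        self.config = config
        self.pools: dict[str, float] = {}  # mmol
        self.agents: list[Agent] = []
        self.occupied: dict[tuple[int, int], Agent] = {}
        self.t: float = 0.0
        self.rng = np.random.default_rng(seed)
        self.overflow_events: int = 0  # divisions lost to a full grid

    @property
    def volume_l(self) -> float:
        return self.config.volume_l

    def pool_amounts_umol(self) -> dict[str, float]:
        return {m: v * 1000.0 for m, v in self.pools.items()}

    def concentrations_mm(self) -> dict[str, float]:
        return {m: v / self.volume_l for m, v in self.pools.items()}

    def live_agents(self) -> list[Agent]:
        return [a for a in self.agents if a.alive]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for agent in self.agents:
            if agent.alive:
                counts[agent.species_id] = counts.get(agent.species_id, 0) + 1
        return counts

    def _random_free_cell(self) -> tuple[int, int] | None:
        n = self.config.grid_cells
        if len(self.occupied) >= n:
            return None
        side = self.config.side_cells
        while True:  # occupancy stays low; rejection sampling terminates fast
            flat = int(self.rng.integers(n))
            pos = (flat // side, flat % side)
            if pos not in self.occupied:
                return pos


def seed_population(
    profile: AbundanceProfile,
    arena: Arena,
    base_count: int | None = None,
) -> Arena:
    """Seed the arena from relative abundances with the ceiling rule.

    Species *i* receives ``ceil(base_count · a_i)`` agents, so every
    detected species is represented by at least one individual and the
    total is at least ``base_count``.  Agents land on distinct uniformly
    random free cells.
    """
    if base_count is None:
        base_count = arena.config.base_count
    items = sorted(profile.abundances.items())
    counts = {s: math.ceil(base_count * a) for s, a in items if a > 0}
    total = sum(counts.values())
    if total + len(arena.occupied) > arena.config.grid_cells:
        raise ValueError(
            f"cannot seed {total} agents onto a grid with "
            f"{arena.config.grid_cells - len(arena.occupied)} free cells"
        )
    cells = arena.rng.choice(
        arena.config.grid_cells, size=total, replace=False
    )
    side = arena.config.side_cells
    i = 0
    for species, n in counts.items():
        for _ in range(n):
            pos = (int(cells[i]) // side, int(cells[i]) % side)
            while pos in arena.occupied:
                pos = arena._random_free_cell()
            agent = Agent(species, arena.config.founder_biomass_gdw, pos)
            arena.agents.append(agent)
            arena.occupied[pos] = agent
            i += 1
    return arena


def build_rich_medium(models, conc_um: float | None = 0.2) -> DietSpec:
    """Rich medium: every metabolite any model can take up, at one
    uniform (low) concentration in µM."""
    union = uptake_union(models.values() if isinstance(models, dict) else models)
    if not union:
        raise ValueError("no model can take up any metabolite")
    return DietSpec({m: conc_um for m in sorted(union)}, unit="uM")


def apply_diet(arena: Arena, diet: DietSpec) -> Arena:
    """Add diet metabolites to the shared pool.

    amount (µmol) = concentration (mM) × arena volume (L) × 1000; pools
    are kept in mmol internally, so the increment is mM × L.
    """
    for met, conc_mm in diet.in_mm().items():
        arena.pools[met] = arena.pools.get(met, 0.0) + conc_mm * arena.volume_l
    return arena


def _exchange_table(model) -> list[tuple[str, str, float, float]]:
    """Static (reaction id, metabolite id, lb, ub) rows for all exchanges."""
    table = []
    for rxn in model.exchanges:
        (met,) = rxn.metabolites
        table.append((rxn.id, met.id, rxn.lower_bound, rxn.upper_bound))
    return table


def uptake_bounds(agent: Agent, arena: Arena, model, dt: float | None = None):
    """Effective exchange bounds for one agent against the current pools.

    For each exchange the effective lower bound is
    ``max(lb_model, -pool / (m · dt))``: an agent may never draw more of
    a metabolite than the shared pool still holds.
    """
    if dt is None:
        dt = arena.config.dt_h
    overrides: dict[str, tuple[float, float]] = {}
    m_dt = agent.biomass * dt
    for rxn in model.exchanges:
        if rxn.lower_bound >= 0:
            continue
        (met,) = rxn.metabolites
        pool = arena.pools.get(met.id, 0.0)
        lb_eff = max(rxn.lower_bound, -pool / m_dt) if pool > 0 else 0.0
        if lb_eff != rxn.lower_bound:
            overrides[rxn.id] = (lb_eff, rxn.upper_bound)
    return overrides


def step(arena: Arena, models: dict, flux_log: list | None = None,
         fba_cache: dict | None = None,
         exchange_tables: dict | None = None) -> Arena:
    """Advance the community by one time step of length dt.

    Agents are visited in a freshly drawn random order.  Each agent's
    FBA is solved with pool-aware uptake bounds; its exchange fluxes are
    applied to the pools immediately, its biomass updated, and division
    and (optional) death applied.  Identical (species, effective-bounds)
    subproblems share one LP solution via ``fba_cache``.
    """
    cfg = arena.config
    dt = cfg.dt_h
    if fba_cache is None:
        fba_cache = {}
    if exchange_tables is None:
        exchange_tables = {s: _exchange_table(m) for s, m in models.items()}
    live = arena.live_agents()
    order = arena.rng.permutation(len(live))
    step_index = int(round(arena.t / dt))
    pools = arena.pools
    newborns: list[Agent] = []
    for idx in order:
        agent = live[idx]
        if not agent.alive:
            continue
        table = exchange_tables[agent.species_id]
        m_dt_inv = 1.0 / (agent.biomass * dt)
        overrides: list[tuple[str, float, float]] = []
        for rxn_id, met_id, lb, ub in table:
            if lb >= 0:
                continue
            pool = pools.get(met_id, 0.0)
            lb_eff = max(lb, -pool * m_dt_inv) if pool > 0 else 0.0
            if lb_eff != lb:
                overrides.append((rxn_id, lb_eff, ub))
        key = (agent.species_id,
               tuple((r, l) for r, l, _ in overrides))
        cached = fba_cache.get(key)
        if cached is None:
            solution = fba(
                models[agent.species_id],
                bound_overrides={r: (l, u) for r, l, u in overrides},
            )
            if solution.optimal:
                mu = max(0.0, solution.objective_value)
                ex_fluxes = tuple(
                    (met_id, solution.fluxes[rxn_id])
                    for rxn_id, met_id, _, _ in table
                    if solution.fluxes.get(rxn_id, 0.0) != 0.0
                )
                cached = (mu, ex_fluxes)
            else:
                cached = (0.0, ())  # infeasible LP: no growth, no exchange
            fba_cache[key] = cached
        mu, ex_fluxes = cached
        m_dt = agent.biomass * dt
        for met_id, v in ex_fluxes:
            amount = v * m_dt  # mmol; negative = uptake
            pool = arena.pools.get(met_id, 0.0)
            if amount < 0 and pool + amount < 0:
                # cap at the available pool (LP bound honored to solver
                # tolerance; the logged amount is what actually moved)
                amount = -pool
            arena.pools[met_id] = pool + amount
            if flux_log is not None and amount != 0.0:
                flux_log.append((step_index, agent.species_id, met_id, amount))
        if mu <= 0:
            agent.zero_growth_streak += 1
            if (cfg.death_after_steps is not None
                    and agent.zero_growth_streak >= cfg.death_after_steps):
                agent.alive = False
                del arena.occupied[agent.position]
                continue
        else:
            agent.zero_growth_streak = 0
        agent.biomass *= 1.0 + mu * dt
        if agent.biomass >= 2.0 * cfg.founder_biomass_gdw:
            pos = arena._random_free_cell()
            if pos is None:
                arena.overflow_events += 1  # grid full: biomass capped
                agent.biomass = 2.0 * cfg.founder_biomass_gdw
            else:
                agent.biomass /= 2.0
                daughter = Agent(agent.species_id, agent.biomass, pos)
                arena.occupied[pos] = daughter
                newborns.append(daughter)
    arena.agents.extend(newborns)
    arena.t += dt
    return arena


@dataclass
class SimulationResult:
    """Time series of one community simulation (index 0 is t = 0)."""

    abundance_series: list[dict[str, int]]
    pool_series: list[dict[str, float]]  # mmol
    flux_log: list[tuple[int, str, str, float]]  # (step, species, met, mmol)
    volume_l: float
    config: SimConfig
    seed: int
    #: extracellular metabolites the present models and diet span
    metabolite_namespace: frozenset = frozenset()

    def concentrations_mm(self, step_index: int = -1) -> dict[str, float]:
        pools = self.pool_series[step_index]
        return {m: v / self.volume_l for m, v in pools.items()}

    @property
    def steps(self) -> int:
        return len(self.abundance_series) - 1


def assert_mass_conservation(result: "SimulationResult",
                             rel_tol: float = 1e-9) -> None:
    """Verify the bookkeeping invariants of a finished simulation.

    For every step and metabolite, the pool change must equal the summed
    logged exchange amounts (flux × biomass × dt) to ``rel_tol``
    relative, and no pool may ever be negative.  Raises AssertionError
    on violation.
    """
    per_step: dict[tuple[int, str], float] = {}
    for step_index, _, met, amount in result.flux_log:
        key = (step_index, met)
        per_step[key] = per_step.get(key, 0.0) + amount
    for s in range(len(result.pool_series) - 1):
        before = result.pool_series[s]
        after = result.pool_series[s + 1]
        for met in set(before) | set(after):
            delta = after.get(met, 0.0) - before.get(met, 0.0)
            flux_sum = per_step.get((s, met), 0.0)
            scale = max(abs(before.get(met, 0.0)), abs(flux_sum), 1e-30)
            assert abs(delta - flux_sum) <= rel_tol * scale, (
                f"step {s}, {met}: pool change {delta} != flux sum {flux_sum}"
            )
    for pools in result.pool_series:
        for met, amount in pools.items():
            assert amount >= 0.0, f"negative pool for {met}: {amount}"


def simulate(
    profile: AbundanceProfile,
    models: dict,
    diet: DietSpec | None = None,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    extra_diet: DietSpec | None = None,
) -> SimulationResult:
    """Run a full community simulation for one sample.

    ``diet`` defaults to the rich medium built from the union of
    metabolites the present species can take up, at
    ``config.medium_conc_um``; ``extra_diet`` (e.g. a treatment
    supplement) is added on top.  Deterministic given ``seed``.
    """
    missing = [s for s in profile.abundances if s not in models]
    if missing:
        raise KeyError(f"no model for species: {missing}")
    present = {s: models[s] for s in profile.abundances}
    if diet is None:
        diet = build_rich_medium(present, config.medium_conc_um)
    arena = Arena(config, seed=seed)
    seed_population(profile, arena)
    apply_diet(arena, diet)
    if extra_diet is not None:
        apply_diet(arena, extra_diet)
    abundance_series = [arena.species_counts()]
    pool_series = [dict(arena.pools)]
    flux_log: list[tuple[int, str, str, float]] = []
    cache: dict = {}
    tables = {s: _exchange_table(m) for s, m in present.items()}
    for _ in range(config.steps):
        step(arena, present, flux_log=flux_log, fba_cache=cache,
             exchange_tables=tables)
        abundance_series.append(arena.species_counts())
        pool_series.append(dict(arena.pools))
    if arena.overflow_events:
        warnings.warn(
            f"{arena.overflow_events} division(s) suppressed by a full grid",
            stacklevel=2,
        )
    namespace = set(arena.pools)
    for model in present.values():
        namespace |= {m.id for m in model.metabolites if m.compartment == "e"}
    return SimulationResult(
        abundance_series=abundance_series,
        pool_series=pool_series,
        flux_log=flux_log,
        volume_l=arena.volume_l,
        config=config,
        seed=seed,
        metabolite_namespace=frozenset(namespace),
    )
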