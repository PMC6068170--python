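"""SCFA signatures, taxon flux attribution, and group comparison.

The tracked fermentation products are butyrate, propionate,
isobutyrate, acetate, and L-lactate.  A sample's SCFA signature is the
vector of their molar concentrations in the shared environment at the
end of the simulation (t = 24 h by default).  Production and
consumption are attributed to taxon classes by summing, over all agents
of a class, the logged exchange amounts (flux × biomass × dt), an exact
decomposition of each pool's net change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .abundance import rank_sum_test
from .community_sim import SimulationResult

__all__ = [
    "SCFA_METABOLITES",
    "MissingMetaboliteWarning",
    "SCFASignature",
    "scfa_signature",
    "taxon_contributions",
    "group_ratio",
    "compare_groups",
]

class MissingMetaboliteWarning(UserWarning):
    """An expected SCFA is entirely absent from a simulation's namespace."""


#: canonical SCFA name → extracellular metabolite id
SCFA_METABOLITES = {
    "butyrate": "but_e",
    "propionate": "ppa_e",
    "isobutyrate": "ibut_e",
    "L-lactate": "lac_e",
    "acetate": "ac_e",
}


@dataclass
class SCFASignature:
    """Per-sample SCFA concentrations (mM) at one time point."""

    sample_id: str
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < -1e-12 for v in self.concentrations.values()):
            raise ValueError("SCFA concentrations cannot be negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.concentrations, name=self.sample_id)


def scfa_signature(
    result: SimulationResult,
    sample_id: str = "",
    t_h: float | None = None,
) -> SCFASignature:
    """Read the SCFA concentrations from the pool series at time ``t_h``.

    Defaults to the final time point.  An SCFA missing from the
    metabolite namespace is reported as 0 with a warning.
    """
    if t_h is None:
        idx = len(result.pool_series) - 1
    else:
        idx = int(round(t_h / result.config.dt_h))
        if not 0 <= idx < len(result.pool_series):
            raise ValueError(f"t = {t_h} h is outside the simulated series")
    pools = result.pool_series[idx]
    known = result.metabolite_namespace or set().union(
        *[set(p) for p in result.pool_series]
    )
    conc = {}
    for name, met in SCFA_METABOLITES.items():
        if met not in known:
            warnings.warn(
                f"{name} ({met}) absent from the metabolite namespace; "
                "reporting 0 mM",
                MissingMetaboliteWarning,
                stacklevel=2,
            )
        conc[name] = max(0.0, pools.get(met, 0.0)) / result.volume_l
    return SCFASignature(sample_id=sample_id, concentrations=conc)


def taxon_contributions(
    result: SimulationResult,
    taxonomy: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Per-class summed exchange amounts (mmol over the whole simulation).

    Rows: (taxon class, metabolite, amount); uptake < 0 < secretion.
    The class decomposition is exact: per metabolite, the amounts sum to
    the net pool change between t = 0 and the end.  Species without a
    taxonomy entry are binned as "Other" with a warning.
    """
    if isinstance(taxonomy, pd.DataFrame):
        class_of = dict(zip(taxonomy["strain_id"], taxonomy["class"]))
    else:
        class_of = dict(taxonomy)
    unmapped = set()
    records: dict[tuple[str, str], float] = {}
    for _, species, met, amount in result.flux_log:
        cls = class_of.get(species)
        if cls is None:
            unmapped.add(species)
            cls = "Other"
        key = (cls, met)
        records[key] = records.get(key, 0.0) + amount
    if unmapped:
        warnings.warn(
            f"species without taxonomy assigned to 'Other': {sorted(unmapped)}",
            stacklevel=2,
        )
    table = pd.DataFrame(
        [(cls, met, amt) for (cls, met), amt in sorted(records.items())],
        columns=["taxon_class", "metabolite", "amount_mmol"],
    )
    return table


def group_ratio(healthy, cd) -> dict[str, float]:
    """Per-SCFA ratio of group mean concentrations, healthy / dysbiotic.

    A zero dysbiotic mean with a positive healthy mean is flagged as
    ``inf``; 0/0 is reported as ``nan``.
    """
    healthy, cd = list(healthy), list(cd)
    if not healthy or not cd:
        raise ValueError("both groups must be non-empty")
    out = {}
    for name in SCFA_METABOLITES:
        h = float(np.mean([s.concentrations.get(name, 0.0) for s in healthy]))
        c = float(np.mean([s.concentrations.get(name, 0.0) for s in cd]))
        if c == 0.0:
            out[name] = float("inf") if h > 0 else float("nan")
        else:
            out[name] = h / c
    return out


def compare_groups(healthy, cd) -> pd.DataFrame:
    """Two-sided rank-sum comparison of each SCFA between groups.

    ``direction`` is the sign of (healthy median − dysbiotic median).
    Raw p-values are the primary output; a Benjamini–Hochberg column
    (``p_bh``) is added as a clearly separate convenience.
    """
    healthy, cd = list(healthy), list(cd)
    if len(healthy) < 3 or len(cd) < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for name in SCFA_METABOLITES:
        h = np.array([s.concentrations.get(name, 0.0) for s in healthy])
        c = np.array([s.concentrations.get(name, 0.0) for s in cd])
        stat, p = rank_sum_test(h, c)
        rows.append({
            "scfa": name,
            "healthy_mean_mM": float(h.mean()),
            "cd_mean_mM": float(c.mean()),
            "direction": int(np.sign(np.median(h) - np.median(c))),
            "statistic": stat,
            "p_value": p,
        })
    table = pd.DataFrame(rows)
    table["p_bh"] = false_discovery_control(table["p_value"], method="bh")
    return table
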