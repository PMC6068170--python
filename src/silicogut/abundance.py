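"""Relative abundance estimation and between-sample statistics.

The mapping pipeline upstream of this package produces, per sample, a
table of genome-coverage records (already quality-filtered).  Here those
records are turned into relative strain abundances and compared:

* coverage depth = mapped reads / genome length (reads per bp),
* strains with breadth of coverage below 1 % are treated as false
  positives and removed (inclusive threshold),
* per-sample depths are normalized to relative abundances,
* samples are compared with Bray-Curtis dissimilarity + PCoA, model
  reaction content with Jaccard distance, and group differences with
  the two-sided Wilcoxon rank-sum test (exact permutation null for
  small samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "AbundanceProfile",
    "compute_coverage",
    "filter_low_coverage",
    "normalize_abundance",
    "bray_curtis",
    "distance_matrix",
    "jaccard_reaction_distance",
    "pcoa",
    "rank_sum_test",
    "class_abundances",
    "COVERAGE_COLUMNS",
]

COVERAGE_COLUMNS = [
    "sample_id", "strain_id", "genome_length_bp", "mapped_reads",
    "covered_fraction",
]

DEFAULT_BREADTH_THRESHOLD = 0.01

#: largest combined sample size for which the exact permutation null is used
EXACT_RANKSUM_LIMIT = 20


@dataclass
class AbundanceProfile:
    """Per-sample relative strain abundances with taxonomy annotations."""

    sample_id: str
    abundances: dict[str, float]
    taxonomy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"abundances of {self.sample_id!r} sum to {total}, not 1"
            )
        if any(a <= 0 for a in self.abundances.values()):
            raise ValueError("all retained abundances must be positive")

    def vector(self, strain_order) -> np.ndarray:
        return np.array([self.abundances.get(s, 0.0) for s in strain_order])


def compute_coverage(mapped_reads: int, genome_length_bp: int) -> float:
    """Coverage depth in reads per bp: mapped reads / genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped read count cannot be negative")
    return mapped_reads / genome_length_bp


def filter_low_coverage(
    records: pd.DataFrame,
    threshold: float = DEFAULT_BREADTH_THRESHOLD,
) -> pd.DataFrame:
    """Drop rows whose breadth of coverage falls below ``threshold``.

    The comparison is inclusive (breadth == threshold is retained) and row
    order is preserved.  Samples losing all strains are flagged with a
    warning: they cannot be modeled downstream.
    """
    kept = records[records["covered_fraction"] >= threshold].copy()
    emptied = set(records["sample_id"]) - set(kept["sample_id"])
    for sample_id in sorted(emptied):
        warnings.warn(
            f"sample {sample_id!r}: no strain passes the "
            f"{threshold:.2%} coverage threshold; sample is unmodelable",
            stacklevel=2,
        )
    return kept


def normalize_abundance(
    filtered: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> dict[str, AbundanceProfile]:
    """Per-sample relative abundances from coverage depths.

    Depth is recomputed from mapped reads and genome length; within each
    sample the depths are normalized to sum to one.
    """
    tax_map: dict[str, tuple[str, str]] = {}
    if taxonomy is not None:
        tax_map = {
            strain: (genus, cls)
            for strain, genus, cls in zip(
                taxonomy["strain_id"], taxonomy["genus"], taxonomy["class"]
            )
        }
    profiles: dict[str, AbundanceProfile] = {}
    for sample_id, sub in filtered.groupby("sample_id", sort=True):
        depths = np.array([
            compute_coverage(mr, gl)
            for mr, gl in zip(sub["mapped_reads"], sub["genome_length_bp"])
        ])
        total = depths.sum()
        if total <= 0:
            raise ValueError(
                f"sample {sample_id!r}: total coverage depth is zero"
            )
        abundances = {
            strain: depth / total
            for strain, depth in zip(sub["strain_id"], depths)
            if depth > 0
        }
        # re-normalize after dropping zero-depth strains
        s = sum(abundances.values())
        abundances = {k: v / s for k, v in abundances.items()}
        profiles[str(sample_id)] = AbundanceProfile(
            sample_id=str(sample_id),
            abundances=abundances,
            taxonomy={s: tax_map[s] for s in abundances if s in tax_map},
        )
    return profiles


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2·Σmin(x,y)/(Σx+Σy) on aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same strain order")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(scipy.spatial.distance.braycurtis(x, y))


def distance_matrix(profiles, metric=bray_curtis) -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix over the strain union."""
    profiles = list(profiles)
    strains = sorted(set().union(*[p.abundances for p in profiles]))
    ids = [p.sample_id for p in profiles]
    vectors = [p.vector(strains) for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = metric(vectors[i], vectors[j])
    return pd.DataFrame(d, index=ids, columns=ids)


def jaccard_reaction_distance(a, b) -> float:
    """Jaccard distance 1 - |A∩B|/|A∪B| between reaction id sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard distance is undefined for two empty sets")
    return 1.0 - len(a & b) / len(a | b)


def pcoa(distances):
    """Classical metric scaling (principal coordinate analysis).

    Accepts a square symmetric zero-diagonal distance matrix (DataFrame or
    array) and returns ``(coordinates, explained)``: sample coordinates
    ordered by eigenvalue, and explained-variance fractions computed over
    the positive eigenvalues only (negative eigenvalues from non-Euclidean
    distances are clamped to zero, no Lingoes/Cailliez correction).
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        ids = list(range(mat.shape[0]))
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = _skbio_pcoa(mat, method="eigh", number_of_dimensions=0)
    eigvals = np.asarray(result.eigvals, dtype=float)
    clamped = np.clip(eigvals, 0.0, None)
    total = clamped.sum()
    explained = clamped / total if total > 0 else clamped
    coords = pd.DataFrame(
        np.asarray(result.samples),
        index=ids,
        columns=[f"PCo{i + 1}" for i in range(result.samples.shape[1])],
    )
    return coords, explained


@functools.lru_cache(maxsize=8)
def _label_combinations(n: int, n1: int) -> np.ndarray:
    """All size-n1 index subsets of range(n), as one array (memoized)."""
    return np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)


def _midranks(values: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(values, method="average")


def rank_sum_test(group1, group2) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the midrank sum of the first group.  For
    combined n ≤ 20 the p-value is exact, obtained by enumerating all
    label assignments of the observed (possibly tied) values; the
    two-sided p doubles the smaller one-sided tail and is capped at 1.
    Larger samples use the tie-corrected normal approximation.  If every
    value is tied across both groups, p = 1.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(_midranks(pooled)[: len(x)].sum()), 1.0
    ranks = _midranks(pooled)
    n1, n = len(x), len(pooled)
    w_obs = float(ranks[:n1].sum())
    if n <= EXACT_RANKSUM_LIMIT:
        w_null = ranks[_label_combinations(n, n1)].sum(axis=1)
        eps = 1e-9
        lower = np.mean(w_null <= w_obs + eps)
        upper = np.mean(w_null >= w_obs - eps)
        p = min(1.0, 2.0 * min(lower, upper))
        return w_obs, float(p)
    _, p = scipy.stats.ranksums(x, y)  # normal approximation
    if np.unique(pooled).size < n:
        # midrank ties: use the tie-corrected Mann-Whitney normal variant
        _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic")
    return w_obs, float(p)


def class_abundances(profiles) -> pd.DataFrame:
    """Sample × taxon-class table of summed relative abundances."""
    rows = {}
    for p in profiles:
        sums: dict[str, float] = {}
        for strain, a in p.abundances.items():
            cls = p.taxonomy.get(strain, (None, "Other"))[1]
            sums[cls] = sums.get(cls, 0.0) + a
        rows[p.sample_id] = sums
    return pd.DataFrame(rows).T.fillna(0.0).sort_index()
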