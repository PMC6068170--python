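"""Coverage filtering, normalization, distances, PCoA, and the rank-sum
test against its brute-force enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from silicogut.abundance import (
    AbundanceProfile,
    bray_curtis,
    compute_coverage,
    distance_matrix,
    filter_low_coverage,
    jaccard_reaction_distance,
    normalize_abundance,
    pcoa,
    rank_sum_test,
)

from lp_oracle import ranksum_exact_p


def coverage_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "strain_id", "genome_length_bp",
                 "mapped_reads", "covered_fraction"],
    )


@pytest.mark.parametrize("reads,length,expected", [
    (1000, 1_000_000, 0.001),
    (0, 12345, 0.0),
    (500, 250_000, 0.002),
])
def test_compute_coverage(reads, length, expected):
    assert compute_coverage(reads, length) == pytest.approx(expected)


def test_compute_coverage_rejects_zero_genome():
    with pytest.raises(ValueError):
        compute_coverage(10, 0)


def test_filter_threshold_is_inclusive():
    frame = coverage_frame([
        ("s1", "a", 100, 1, 0.005),
        ("s1", "b", 100, 1, 0.01),
        ("s1", "c", 100, 1, 0.02),
    ])
    kept = filter_low_coverage(frame)
    assert list(kept["strain_id"]) == ["b", "c"]
    # threshold 0 keeps everything, preserving order
    assert list(filter_low_coverage(frame, 0.0)["strain_id"]) == ["a", "b", "c"]


def test_filter_warns_on_emptied_sample():
    frame = coverage_frame([("s1", "a", 100, 1, 0.001)])
    with pytest.warns(UserWarning, match="unmodelable"):
        kept = filter_low_coverage(frame)
    assert kept.empty


def test_normalize_abundance_sums_to_one():
    frame = coverage_frame([
        ("s1", "a", 1_000_000, 2000, 0.5),
        ("s1", "b", 1_000_000, 3000, 0.5),
        ("s1", "c", 1_000_000, 5000, 0.5),
        ("s2", "a", 1_000_000, 700, 0.5),
    ])
    profiles = normalize_abundance(frame)
    assert profiles["s1"].abundances == pytest.approx(
        {"a": 0.2, "b": 0.3, "c": 0.5}
    )
    assert profiles["s2"].abundances == {"a": 1.0}


def test_normalize_zero_depth_is_hard_error():
    frame = coverage_frame([("s1", "a", 1_000_000, 0, 0.5)])
    with pytest.raises(ValueError, match="zero"):
        normalize_abundance(frame)


def test_normalize_filter_idempotent():
    """Re-filtering and re-deriving abundances from an already filtered,
    normalized profile changes nothing."""
    frame = coverage_frame([
        ("s1", "a", 1_000_000, 4000, 0.6),
        ("s1", "b", 1_000_000, 6000, 0.4),
        ("s1", "c", 1_000_000, 10, 0.002),
    ])
    once = normalize_abundance(filter_low_coverage(frame))
    again = normalize_abundance(
        filter_low_coverage(filter_low_coverage(frame))
    )
    assert once["s1"].abundances == pytest.approx(again["s1"].abundances)


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        AbundanceProfile("x", {"a": 0.5, "b": 0.6})


@pytest.mark.parametrize("x,y,expected", [
    ([1, 0], [0, 1], 1.0),
    ([0.5, 0.5], [0.5, 0.5], 0.0),
    ([0.7, 0.3], [0.3, 0.7], 0.4),  # hand-evaluated
])
def test_bray_curtis_values(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)
    assert bray_curtis(y, x) == pytest.approx(expected)  # symmetry


def test_bray_curtis_all_zero_is_error():
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


@pytest.mark.parametrize("a,b,expected", [
    ({"r1", "r2"}, {"r2", "r3"}, 2 / 3),
    ({"r1"}, {"r1"}, 0.0),
    ({"r1"}, {"r2"}, 1.0),
])
def test_jaccard_reaction_distance(a, b, expected):
    assert jaccard_reaction_distance(a, b) == pytest.approx(expected)


def test_jaccard_empty_sets_error():
    with pytest.raises(ValueError):
        jaccard_reaction_distance(set(), set())


def test_pcoa_line_metric_first_axis_dominates():
    """4 points on a line (d_ij = |i−j|): the first coordinate carries
    > 90 % of the positive-eigenvalue variance.  Cross-checked with an
    independent eigendecomposition of the double-centered matrix."""
    d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
    coords, explained = pcoa(d)
    assert explained[0] > 0.9
    # independent oracle: Gower double-centering + numpy eigh
    a = -0.5 * d**2
    centered = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    eig = np.sort(np.linalg.eigvalsh(centered))[::-1]
    eig_pos = np.clip(eig, 0, None)
    assert explained[0] == pytest.approx(eig_pos[0] / eig_pos.sum(), abs=1e-9)


def test_pcoa_equidistant_points_have_two_equal_axes():
    d = np.ones((3, 3)) - np.eye(3)
    _, explained = pcoa(d)
    assert explained[0] == pytest.approx(explained[1])


def test_pcoa_duplicate_samples_give_zero_eigenvalue():
    d = np.array([
        [0.0, 0.0, 1.0],
        [0.0, 0.0, 1.0],
        [1.0, 1.0, 0.0],
    ])
    coords, explained = pcoa(d)
    assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)
    assert explained[-1] == pytest.approx(0.0, abs=1e-12)


def test_pcoa_rejects_asymmetric_input():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        pcoa(d)


@pytest.mark.parametrize("g1,g2,expected_p", [
    ((1, 2, 3), (4, 5, 6), 0.1),          # 2/20, full enumeration
    ((1, 2, 3, 4), (5, 6, 7, 8), 2 / 70),
    ((1, 2, 3), (1, 2, 3), 1.0),
])
def test_rank_sum_exact_examples(g1, g2, expected_p):
    _, p = rank_sum_test(g1, g2)
    assert p == pytest.approx(expected_p)


def test_rank_sum_all_tied_returns_one():
    assert rank_sum_test([7, 7, 7], [7, 7, 7])[1] == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n1=st.integers(3, 6), n2=st.integers(3, 6),
    data=st.data(),
)
def test_rank_sum_matches_bruteforce_enumeration(n1, n2, data):
    """Exact branch equals the independent full enumeration, including
    under heavy ties (combined n ≤ 12)."""
    values = st.integers(0, 4)
    g1 = data.draw(st.lists(values, min_size=n1, max_size=n1))
    g2 = data.draw(st.lists(values, min_size=n2, max_size=n2))
    _, p = rank_sum_test(g1, g2)
    assert p == pytest.approx(ranksum_exact_p(g1, g2), abs=1e-12)


def test_rank_sum_matches_scipy_exact_when_tie_free():
    rng = np.random.default_rng(11)
    for _ in range(10):
        g1 = rng.permutation(40)[:6]
        g2 = rng.permutation(40)[6:12] + 0.5
        _, p = rank_sum_test(g1, g2)
        expected = scipy.stats.mannwhitneyu(
            g1, g2, alternative="two-sided", method="exact"
        ).pvalue
        assert p == pytest.approx(expected, abs=1e-12)


def test_rank_sum_large_samples_use_normal_approximation():
    rng = np.random.default_rng(5)
    g1 = rng.normal(0, 1, 15)
    g2 = rng.normal(1, 1, 15)
    _, p = rank_sum_test(g1, g2)
    expected = scipy.stats.ranksums(g1, g2).pvalue
    assert p == pytest.approx(expected, rel=1e-9)


def test_distance_matrix_separates_cohort_groups(cohort_run):
    """Mean between-group Bray-Curtis exceeds mean within-group."""
    dm = distance_matrix(cohort_run.profiles.values())
    healthy = cohort_run.group("healthy")
    cd = cohort_run.group("cd")
    within = [dm.loc[a, b] for g in (healthy, cd)
              for a, b in itertools.combinations(g, 2)]
    between = [dm.loc[a, b] for a in healthy for b in cd]
    assert np.mean(between) > np.mean(within)
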