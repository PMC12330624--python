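"""Group comparisons, conserved fractions, amino-acid profiles, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from idrscape.exceptions import InvalidInputError
from idrscape.llr import AA_ALPHABET, LLRMatrix
from idrscape.stats import (
    aa_mean_llr,
    cluster_aa_profiles,
    compare_groups,
    esm2_cs_correlation,
    fraction_by_class,
    mann_whitney,
    ps_localization_probability,
    significance_tier,
)


def brute_force_two_sided_p(a, b):
    """Full enumeration of label assignments (independent of the package's
    enumeration: ranks recomputed per assignment from raw values)."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, len(a)

    def u_of(idx):
        group = pooled[list(idx)]
        rest = pooled[[i for i in range(n) if i not in idx]]
        greater = sum((group[:, None] > rest[None, :]).sum()
                      for _ in (0,))  # scalar
        ties = (group[:, None] == rest[None, :]).sum()
        return greater + 0.5 * ties

    u_obs = u_of(tuple(range(n_a)))
    us = [u_of(idx) for idx in itertools.combinations(range(n), n_a)]
    le = sum(u <= u_obs + 1e-9 for u in us)
    ge = sum(u >= u_obs - 1e-9 for u in us)
    return min(1.0, 2 * min(le, ge) / len(us))


# ---------------------------------------------------------------------------
# Mann–Whitney


def test_separated_small_samples_exact_p():
    c = mann_whitney([1, 2, 3], [4, 5, 6])
    assert c.u_statistic == 0
    assert c.p_value == pytest.approx(0.1)
    assert c.significance == "n.s."


def test_identical_samples_null():
    c = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.p_value == pytest.approx(1.0)
    assert c.significance == "n.s."


def test_empty_group_rejected():
    with pytest.raises(InvalidInputError):
        mann_whitney([], [1.0])


def test_symmetry_in_group_order():
    rng = np.random.default_rng(1)
    for n_a, n_b in [(3, 4), (5, 5), (40, 60)]:
        a, b = rng.normal(0, 1, n_a), rng.normal(0.5, 1, n_b)
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(b, a).p_value, rel=1e-9)


def test_exact_mode_matches_scipy_on_tie_free_samples():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n_a, n_b = rng.integers(2, 6), rng.integers(2, 6)
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.8, 1, n_b)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.u_statistic == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_exact_mode_matches_brute_force_with_ties():
    rng = np.random.default_rng(13)
    for _ in range(10):
        n_a, n_b = int(rng.integers(2, 5)), int(rng.integers(2, 6))
        a = rng.integers(0, 4, n_a).astype(float)  # coarse grid forces ties
        b = rng.integers(0, 4, n_b).astype(float)
        assert mann_whitney(a, b).p_value == pytest.approx(
            brute_force_two_sided_p(a, b), abs=1e-12)


@pytest.mark.parametrize(
    "p, tier",
    [
        (0.0004, "***"), (0.005, "**"), (0.03, "*"), (0.07, "†"),
        (0.05, "†"),     # boundary: strict inequality for '*'
        (0.10, "n.s."), (0.5, "n.s."),
    ],
)
def test_significance_tiers(p, tier):
    assert significance_tier(p) == tier


def test_compare_groups_all_pairs():
    rng = np.random.default_rng(0)
    samples = {"x": rng.normal(0, 1, 30), "y": rng.normal(1, 1, 30),
               "z": rng.normal(2, 1, 30)}
    table = compare_groups(samples)
    assert len(table) == 3
    assert set(zip(table.group_a, table.group_b)) == {
        ("x", "y"), ("x", "z"), ("y", "z")}


# ---------------------------------------------------------------------------
# class fractions and localisation probability


def _toy_track(scores, order="disordered"):
    from idrscape.llr import classify_tolerance

    return pd.DataFrame({
        "protein_id": "p",
        "position": range(1, len(scores) + 1),
        "wt_aa": ["G"] * len(scores),
        "esm2_score": scores,
        "order_class": order,
        "tolerance_class": [classify_tolerance(s) for s in scores],
    })


def test_fraction_by_class_worked_example():
    track = _toy_track([0.2, 0.4, 0.6, 2.5])
    assert fraction_by_class(track, "disordered", "conserved") == 0.5
    assert fraction_by_class(track, "disordered", "flexible") == 0.25


def test_fraction_missing_when_no_residues():
    track = _toy_track([0.2], order="ordered")
    assert np.isnan(fraction_by_class(track, "disordered", "conserved"))


def test_fractions_sum_to_one():
    rng = np.random.default_rng(3)
    track = _toy_track(rng.uniform(0, 3, 50))
    total = sum(fraction_by_class(track, "disordered", c)
                for c in ("conserved", "intermediate", "flexible"))
    assert total == pytest.approx(1.0)


def test_ps_localization_probability():
    from idrscape.idr import IDRRegion

    scores = [0.1] * 10  # 10 conserved residues at positions 1..10
    track = _toy_track(scores)
    idrs = [IDRRegion("p", 1, 7, "driving"),
            IDRRegion("p", 8, 10, "non_participating")]
    p = ps_localization_probability(track, idrs)
    assert p == pytest.approx(0.7)
    assert ps_localization_probability(
        track, [IDRRegion("p", 1, 10, "participating")]) == 1.0
    assert ps_localization_probability(
        track, [IDRRegion("p", 1, 10, "non_participating")]) == 0.0


def test_ps_localization_missing_without_conserved_residues():
    track = _toy_track([2.5, 2.8])
    assert np.isnan(ps_localization_probability(track, []))


# ---------------------------------------------------------------------------
# amino-acid profiles


def _matrix(pid, seq, rows):
    return LLRMatrix(pid, seq, rows)


def test_aa_mean_llr_elementwise_mean():
    rng = np.random.default_rng(5)
    v1, v2 = rng.normal(-2, 1, 20), rng.normal(-2, 1, 20)
    g = AA_ALPHABET.index("G")
    v1[g] = v2[g] = 0.0
    m = _matrix("p", "GG", np.vstack([v1, v2]))
    track = pd.DataFrame({
        "protein_id": "p", "position": [1, 2], "wt_aa": ["G", "G"],
        "esm2_score": [1.0, 2.0],
    })
    profiles = aa_mean_llr(track, {"p": m})
    got = profiles.loc["G", [f"mean_llr_{c}" for c in AA_ALPHABET]].to_numpy(float)
    assert np.allclose(got, (v1 + v2) / 2)
    assert profiles.loc["G", "mean_esm2"] == pytest.approx(1.5)
    assert profiles.loc["G", "n_residues"] == 2
    assert profiles.loc["A", "n_residues"] == 0
    assert np.isnan(profiles.loc["A", "mean_esm2"])


def test_aa_mean_llr_single_residue_and_empty_filter():
    v = np.zeros(20)
    m = _matrix("p", "A", v[None, :])
    track = pd.DataFrame({"protein_id": "p", "position": [1], "wt_aa": ["A"],
                          "esm2_score": [3.0]})
    profiles = aa_mean_llr(track, {"p": m})
    assert np.allclose(
        profiles.loc["A", [f"mean_llr_{c}" for c in AA_ALPHABET]].to_numpy(float), v)
    empty = aa_mean_llr(track, {"p": m}, residue_filter=lambda t: t["position"] < 0)
    assert (empty["n_residues"] == 0).all()


# ---------------------------------------------------------------------------
# correlation


def _linear_profiles(slope=-1 / 3):
    profiles = pd.DataFrame(index=list(AA_ALPHABET))
    profiles["mean_esm2"] = np.linspace(0.2, 2.9, 20)
    profiles["mean_cs"] = 1 + slope * profiles["mean_esm2"]
    return profiles


def test_perfect_linear_relation_gives_minus_one():
    assert esm2_cs_correlation(_linear_profiles()) == pytest.approx(-1.0)


def test_constant_cs_rejected():
    profiles = _linear_profiles()
    profiles["mean_cs"] = 0.5
    with pytest.raises(InvalidInputError, match="variance"):
        esm2_cs_correlation(profiles)


def test_too_few_points_rejected():
    profiles = _linear_profiles().iloc[:3]
    profiles.index = ["M", "A", "C"]  # M excluded -> only 2 points left
    with pytest.raises(InvalidInputError):
        esm2_cs_correlation(profiles)


def test_methionine_excluded():
    profiles = _linear_profiles()
    profiles.loc["M", "mean_cs"] = 5.0  # wild outlier: must not matter
    assert esm2_cs_correlation(profiles) == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# clustering


def _planted_cluster_profiles(n_clusters=5, spread=0.01, separation=30.0):
    """20 letters in well-separated point clouds; cluster k has the k-th
    lowest mean entropy score so relabelling is deterministic."""
    rng = np.random.default_rng(8)
    profiles = pd.DataFrame(index=list(AA_ALPHABET))
    centers = rng.normal(0, 1, (n_clusters, 20)) * separation
    truth = np.arange(20) % n_clusters
    vectors = centers[truth] + rng.normal(0, spread, (20, 20))
    for k, c in enumerate(AA_ALPHABET):
        profiles[f"mean_llr_{c}"] = vectors[:, k]
    profiles["mean_esm2"] = truth * 0.5 + 0.1
    return profiles, truth


def test_planted_clusters_recovered_exactly():
    profiles, truth = _planted_cluster_profiles()
    labels = cluster_aa_profiles(profiles, n_clusters=5)
    # same partition, and ordered by ascending mean score (group 1 lowest)
    for k in range(5):
        members = labels[truth == k]
        assert len(set(members)) == 1
        assert members.iloc[0] == k + 1


def test_cluster_count_extremes():
    profiles, _ = _planted_cluster_profiles()
    assert set(cluster_aa_profiles(profiles, n_clusters=1)) == {1}
    assert sorted(cluster_aa_profiles(profiles, n_clusters=20)) == list(range(1, 21))


def test_missing_profiles_rejected():
    profiles, _ = _planted_cluster_profiles()
    profiles.loc["A", "mean_llr_C"] = np.nan
    with pytest.raises(InvalidInputError, match="A"):
        cluster_aa_profiles(profiles)
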