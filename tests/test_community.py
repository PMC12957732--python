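"""Bray-Curtis, ordination and PERMANOVA behaviour, including brute-force
permutation equivalence and an independent scikit-bio cross-check."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from reefdiet.community import (
    bray_curtis,
    nmds,
    pairwise_permanova,
    pcoa,
    permanova,
)


def table(rows, ids=None):
    rows = np.asarray(rows, float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids)


class TestBrayCurtis:
    def test_identity_and_disjoint_bounds(self):
        t = table([[1, 2, 3], [1, 2, 3], [0, 0, 7]])
        dm = bray_curtis(t, mode="raw")
        assert dm["s0", "s1"] == pytest.approx(0.0, abs=1e-12)
        assert dm["s0", "s2"] < 1.0
        d2 = bray_curtis(table([[5, 0], [0, 3]]), mode="raw")
        assert d2["s0", "s1"] == pytest.approx(1.0)

    def test_worked_raw_count_example(self):
        dm = bray_curtis(table([[1, 0], [1, 1]]), mode="raw")
        assert dm["s0", "s1"] == pytest.approx(1 / 3, rel=1e-12)

    def test_relative_mode_depth_invariant(self):
        t1 = table([[10, 30, 60], [50, 25, 25]])
        t2 = t1.copy()
        t2.iloc[0] *= 10  # rescale one sample's depth
        np.testing.assert_allclose(
            bray_curtis(t1).data, bray_curtis(t2).data, atol=1e-12)

    def test_presence_absence_mode(self):
        t = table([[5, 0, 2], [1, 1, 0]])
        dm = bray_curtis(t, mode="presence_absence")
        # binary BC = 1 - 2a/(A+B) with a=1 shared, A=2, B=2
        assert dm["s0", "s1"] == pytest.approx(0.5)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="bad_sample"):
            bray_curtis(table([[1, 2], [0, 0]], ids=["ok", "bad_sample"]))


class TestPCoA:
    def test_line_configuration_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(D, ids=list("abcd")), k=1)
        got = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_planar_configuration_exact(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        D = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(D, ids=[str(i) for i in range(6)]), k=2)
        got = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_two_samples_one_axis(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        res = pcoa(DistanceMatrix(D, ids=["a", "b"]), k=1)
        d = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert d == pytest.approx(0.4, rel=1e-9)

    def test_reduced_axes_flagged(self):
        # 3 collinear points have only one positive eigenvalue
        x = np.array([0.0, 1.0, 2.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(D, ids=list("abc")), k=2)
        assert res.coordinates.shape[1] == 1
        assert not res.converged

    def test_matches_skbio_on_bray_curtis(self):
        rng = np.random.default_rng(1)
        t = table(rng.integers(0, 50, size=(8, 6)))
        dm = bray_curtis(t, mode="raw")
        mine = pcoa(dm, k=2).coordinates.to_numpy()
        import skbio.stats.ordination as sko
        theirs = sko.pcoa(dm, number_of_dimensions=2).samples.to_numpy()
        # same up to per-axis sign
        for j in range(2):
            assert (np.allclose(mine[:, j], theirs[:, j], atol=1e-8)
                    or np.allclose(mine[:, j], -theirs[:, j], atol=1e-8))


class TestNMDS:
    def test_euclidean_input_low_stress(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = nmds(DistanceMatrix(D, ids=[str(i) for i in range(10)]),
                   k=2, n_starts=5, seed=0)
        assert res.stress < 0.01
        assert 0 <= res.stress <= 1

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        t = table(rng.integers(0, 30, size=(9, 5)))
        res = nmds(bray_curtis(t, mode="raw"), k=2, n_starts=3, seed=1)
        trace = np.array(res.stress_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        t = table(rng.integers(0, 30, size=(8, 5)))
        dm = bray_curtis(t, mode="raw")
        a = nmds(dm, k=2, n_starts=4, seed=7)
        b = nmds(dm, k=2, n_starts=4, seed=7)
        np.testing.assert_array_equal(a.coordinates.to_numpy(),
                                      b.coordinates.to_numpy())
        assert a.stress == b.stress


def brute_force_permanova_p(dm, labels):
    """Exhaustive relabelling oracle for a two-group instance: enumerate every
    distinct assignment of the group-A positions."""
    from itertools import combinations as combs
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    assert uniq.size == 2
    n = len(labels)
    idx_a = set(np.flatnonzero(labels == uniq[0]))
    d2 = dm.data ** 2

    def f_of(assign_a):
        lab = np.where(np.isin(np.arange(n), list(assign_a)), uniq[0], uniq[1])
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in uniq:
            ix = np.flatnonzero(lab == g)
            sub = d2[np.ix_(ix, ix)]
            ss_within += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
        ss_among = ss_total - ss_within
        return (ss_among / 1) / (ss_within / (n - 2))

    f_obs = f_of(idx_a)
    all_f = [f_of(set(c)) for c in combs(range(n), len(idx_a))]
    return sum(f >= f_obs - 1e-12 for f in all_f) / len(all_f), f_obs


class TestPermanova:
    def test_matches_brute_force_enumeration_on_tiny_instance(self):
        rng = np.random.default_rng(5)
        t = table(rng.integers(1, 40, size=(6, 4)))
        dm = bray_curtis(t, mode="raw")
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        p_exact, f_exact = brute_force_permanova_p(dm, labels)
        res = permanova(dm, labels, n_perm=19_999, seed=0)
        assert res.pseudo_f == pytest.approx(f_exact, rel=1e-10)
        # MC estimate converges to the exhaustive p (20 distinct relabellings)
        se = np.sqrt(p_exact * (1 - p_exact) / 19_999)
        assert abs(res.p_value - p_exact) < 4 * se + 1e-4

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(6)
        t = table(rng.integers(0, 50, size=(12, 6)))
        dm = bray_curtis(t, mode="raw")
        labels = np.repeat(["a", "b", "c"], 4)
        res = permanova(dm, labels, n_perm=99, seed=0)
        sk = skbio_permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_separated_clusters_maximally_significant(self):
        # groups large enough that a random relabelling almost never
        # reproduces the true partition (2/C(20,10) ~ 1e-5)
        rng = np.random.default_rng(7)
        a = rng.integers(50, 60, size=(10, 4))
        b = np.zeros((10, 4), int); b[:, 3] = rng.integers(50, 60, 10)
        dm = bray_curtis(table(np.vstack([a, b])), mode="raw")
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert 0 <= res.r2 <= 1

    def test_two_seeds_within_monte_carlo_error(self):
        rng = np.random.default_rng(8)
        t = table(rng.integers(0, 30, size=(14, 5)))
        dm = bray_curtis(t, mode="raw")
        labels = np.repeat(["a", "b"], 7)
        p1 = permanova(dm, labels, n_perm=10_000, seed=1).p_value
        p2 = permanova(dm, labels, n_perm=10_000, seed=2).p_value
        assert abs(p1 - p2) <= 3 * np.sqrt(p1 * (1 - p1) / 10_000) + 1e-6

    def test_single_sample_group_rejected(self):
        t = table(np.eye(4) + 1)
        dm = bray_curtis(t, mode="raw")
        with pytest.raises(ValueError):
            permanova(dm, ["a", "a", "a", "b"], n_perm=99)

    def test_stratified_permutation_supported(self):
        rng = np.random.default_rng(9)
        t = table(rng.integers(0, 30, size=(12, 5)))
        dm = bray_curtis(t, mode="raw")
        labels = np.repeat(["a", "b"], 6)
        strata = np.tile(["s1", "s2", "s3"], 4)
        res = permanova(dm, labels, n_perm=199, seed=0, strata=strata)
        assert 0 < res.p_value <= 1


class TestPairwise:
    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(10)
        t = table(rng.integers(0, 30, size=(12, 5)))
        dm = bray_curtis(t, mode="raw")
        labels = np.repeat(["a", "b", "c"], 4)
        pw = pairwise_permanova(dm, labels, n_perm=199, seed=0)
        assert (pw["p_bonferroni"] >= pw["p"] - 1e-12).all()
        assert len(pw) == 3

    def test_displaced_group_drives_significance(self):
        rng = np.random.default_rng(11)
        base = rng.integers(20, 30, size=(18, 4))
        shifted = base.copy()
        shifted[12:, :] = 0
        shifted[12:, 0] = rng.integers(50, 80, 6)
        dm = bray_curtis(table(shifted), mode="raw")
        labels = np.repeat(["a", "b", "c"], 6)
        pw = pairwise_permanova(dm, labels, n_perm=999, seed=0)
        involving_c = pw[(pw["group_a"] == "c") | (pw["group_b"] == "c")]
        other = pw[(pw["group_a"] != "c") & (pw["group_b"] != "c")]
        assert (involving_c["p_bonferroni"] < 0.05).all()
        assert (other["p_bonferroni"] > 0.05).all()
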