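"""Distance metrics, diversity, exact MWU, PERMANOVA, PCoA."""

import io as stdio
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix, TreeNode

from amplimit.community import mock_community
from amplimit.compare import (
    exact_mann_whitney_u,
    pcoa,
    permanova,
    shannon_index,
    weighted_unifrac,
)
from amplimit.simulate import draw_taxon_counts


def read_tree(newick: str) -> TreeNode:
    return TreeNode.read(stdio.StringIO(newick))


def unifrac_oracle(tree, counts_a, counts_b, normalized=True):
    """Branch-by-branch weighted UniFrac, independent of skbio internals."""
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    raw = norm = 0.0
    for node in tree.postorder(include_self=False):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        pa = sum(counts_a.get(t, 0) for t in tips) / total_a
        pb = sum(counts_b.get(t, 0) for t in tips) / total_b
        raw += node.length * abs(pa - pb)
        norm += node.length * (pa + pb)
    return raw / norm if normalized else raw


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, tree):
        counts = {"P_aeruginosa": 10, "S_aureus": 5}
        assert weighted_unifrac(tree, counts, counts) == 0.0

    def test_disjoint_single_taxa_on_star_tree(self):
        star = read_tree("(A:1,B:1,C:1);")
        d = weighted_unifrac(star, {"A": 4}, {"B": 7}, normalized=True)
        assert d == pytest.approx(1.0)

    def test_hand_example_raw_and_normalized(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        raw = weighted_unifrac(t, {"A": 2}, {"B": 1, "C": 1}, normalized=False)
        norm = weighted_unifrac(t, {"A": 2}, {"B": 1, "C": 1}, normalized=True)
        assert raw == pytest.approx(3.0)
        assert norm == pytest.approx(0.75)

    def test_matches_branch_by_branch_oracle(self, tree):
        rng = np.random.default_rng(17)
        spec = mock_community()
        for _ in range(10):
            a = draw_taxon_counts(spec, 500, rng)
            b = draw_taxon_counts(spec, 500, rng)
            a = {k: v for k, v in a.items() if v}
            b = {k: v for k, v in b.items() if v}
            for normalized in (False, True):
                got = weighted_unifrac(tree, a, b, normalized)
                want = unifrac_oracle(tree, a, b, normalized)
                assert got == pytest.approx(want, abs=1e-12)

    def test_metric_properties_random_fixtures(self, tree):
        """Normalized distance in [0,1], symmetric, 0 iff same profile."""
        rng = np.random.default_rng(23)
        spec = mock_community()
        samples = [draw_taxon_counts(spec, 400, rng) for _ in range(6)]
        for a, b in combinations(samples, 2):
            d_ab = weighted_unifrac(tree, a, b)
            d_ba = weighted_unifrac(tree, b, a)
            assert 0.0 <= d_ab <= 1.0
            assert d_ab == pytest.approx(d_ba, abs=1e-15)
        scaled = {k: 3 * v for k, v in samples[0].items()}
        assert weighted_unifrac(tree, samples[0], scaled) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_skbio_on_bifurcating_tree(self):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        t = read_tree("((A:1,B:2):0.5,(C:1.5,D:0.7):0.9);")
        rng = np.random.default_rng(55)
        taxa = list("ABCD")
        for _ in range(10):
            u = rng.integers(0, 20, size=4)
            v = rng.integers(0, 20, size=4)
            if u.sum() == 0 or v.sum() == 0:
                continue
            a = dict(zip(taxa, (int(x) for x in u)))
            b = dict(zip(taxa, (int(x) for x in v)))
            for normalized in (False, True):
                mine = weighted_unifrac(t, a, b, normalized)
                ref = skbio_wu(u, v, taxa=taxa, tree=t, normalized=normalized)
                assert mine == pytest.approx(float(ref), abs=1e-12)

    def test_errors(self, tree):
        with pytest.raises(ValueError, match="read"):
            weighted_unifrac(tree, {"P_aeruginosa": 0}, {"S_aureus": 1})
        with pytest.raises(ValueError, match="absent"):
            weighted_unifrac(tree, {"not_a_leaf": 3}, {"S_aureus": 1})


class TestShannonIndex:
    def test_single_taxon_zero(self):
        assert shannon_index({"a": 42}) == 0.0

    def test_uniform_four_taxa(self):
        assert shannon_index({c: 5 for c in "abcd"}) == pytest.approx(
            np.log(4), abs=1e-12
        )

    def test_half_quarter_quarter(self):
        assert shannon_index([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_log_base_two(self):
        assert shannon_index([1, 1], log_base=2) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


def mwu_brute_force(x, y, alternative):
    """Direct pairwise-count enumeration over all group assignments."""
    pooled = list(x) + list(y)
    m, n = len(x), len(y)

    def u_of(group_x, group_y):
        return sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0
            for xi in group_x
            for yj in group_y
        )

    u_obs = u_of(x, y)
    us = []
    for idx in combinations(range(m + n), m):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(m + n) if i not in idx]
        us.append(u_of(gx, gy))
    us = np.array(us)
    center = m * n / 2
    eps = 1e-9
    if alternative == "greater":
        return u_obs, np.mean(us >= u_obs - eps)
    if alternative == "less":
        return u_obs, np.mean(us <= u_obs + eps)
    return u_obs, np.mean(np.abs(us - center) >= abs(u_obs - center) - eps)


class TestExactMannWhitneyU:
    def test_fully_separated_three_vs_three(self):
        u, p_two = exact_mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p_two == pytest.approx(0.10)
        _, p_less = exact_mann_whitney_u([1, 2, 3], [4, 5, 6], "less")
        assert p_less == pytest.approx(1 / 20)

    def test_identical_samples_p_one(self):
        _, p = exact_mann_whitney_u([3.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_matches_brute_force_oracle_small_samples(self):
        rng = np.random.default_rng(99)
        for m in range(1, 5):
            for n in range(1, 5):
                if m + n > 8:
                    continue
                x = rng.integers(0, 4, size=m).astype(float)
                y = rng.integers(0, 4, size=n).astype(float)
                for alt in ("two-sided", "greater", "less"):
                    u, p = exact_mann_whitney_u(x, y, alt)
                    u_ref, p_ref = mwu_brute_force(x, y, alt)
                    assert u == pytest.approx(u_ref)
                    assert p == pytest.approx(p_ref)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        x = rng.permutation(10)[:4].astype(float)
        y = (rng.permutation(10)[:4] + 100).astype(float)
        u, p = exact_mann_whitney_u(x, y)
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == res.statistic
        assert p == pytest.approx(res.pvalue)

    def test_size_bound_and_empty(self):
        with pytest.raises(ValueError, match="bound"):
            exact_mann_whitney_u(list(range(8)), list(range(8)))
        with pytest.raises(ValueError):
            exact_mann_whitney_u([], [1.0])


def permanova_f_oracle(dm, groups):
    """Pseudo-F from explicit sums of squared distances."""
    d2 = dm.data**2
    n = len(groups)
    labels = np.asarray(groups)
    g = len(set(groups))
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for label in set(groups):
        idx = np.flatnonzero(labels == label)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


class TestPermanova:
    def two_cluster_matrix(self, rng, size=5, gap=10.0):
        a = rng.normal(0, 0.1, size=(size, 2))
        b = rng.normal(gap, 0.1, size=(size, 2))
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(2 * size)]
        return DistanceMatrix(squareform(pdist(pts)), ids=ids)

    def test_pseudo_f_matches_sum_of_squares_oracle(self):
        dm = DistanceMatrix(
            np.array(
                [
                    [0.0, 1.0, 4.0, 5.0],
                    [1.0, 0.0, 4.5, 5.5],
                    [4.0, 4.5, 0.0, 1.5],
                    [5.0, 5.5, 1.5, 0.0],
                ]
            ),
            ids=list("abcd"),
        )
        groups = ["g1", "g1", "g2", "g2"]
        f, _ = permanova(dm, groups, n_perm=99, seed=0)
        assert f == pytest.approx(permanova_f_oracle(dm, groups), rel=1e-10)

    def test_separated_clusters_highly_significant(self):
        """Two tight, well-separated 5-sample clusters.

        Only label permutations that map the clusters onto each other can
        match F_obs; those occur with probability 2*(5!)^2/10! = 1/126 per
        draw, so with 1000 permutations the p-value concentrates near
        9/1001 and stays far below any conventional significance level.
        """
        rng = np.random.default_rng(42)
        dm = self.two_cluster_matrix(rng)
        f, p = permanova(dm, ["A"] * 5 + ["B"] * 5, n_perm=1000, seed=1)
        assert p >= 1 / 1001  # permutation floor
        assert p < 0.03  # mean 9/1001, binomial sd ~ 2.8/1001

    def test_pvalue_floor_under_null(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(8)])
        _, p = permanova(dm, ["A", "B"] * 4, n_perm=200, seed=3)
        assert 1 / 201 <= p <= 1.0

    def test_null_pvalues_uniform(self):
        """Under random labels the permutation p-value is ~ U(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(100)
        pvals = []
        for _ in range(200):
            pts = rng.normal(size=(10, 2))
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[f"s{i}" for i in range(10)])
            labels = rng.permutation(["A"] * 5 + ["B"] * 5)
            _, p = permanova(dm, list(labels), n_perm=199,
                             seed=int(rng.integers(2**31)))
            pvals.append(p)
        stat, ks_p = kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_singleton_groups_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            permanova(dm, ["A", "B"], n_perm=10, seed=0)


class TestPcoa:
    def test_three_equidistant_samples(self):
        dm = DistanceMatrix(np.array([
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ]), ids=list("abc"))
        _, explained, eigvals = pcoa(dm)
        positive = np.sort(eigvals[eigvals > 1e-12])
        assert positive.size == 2
        assert positive[0] == pytest.approx(positive[1], rel=1e-9)

    def test_round_trip_from_planar_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(7)])
        coords, explained, _ = pcoa(dm, n_axes=7)
        recovered = squareform(pdist(coords.to_numpy()))
        assert np.allclose(recovered, dm.data, atol=1e-8)
        assert explained.sum() <= 1.0 + 1e-12

    def test_negative_eigenvalues_reported(self):
        # a non-Euclidean dissimilarity matrix must surface negative eigvals
        d = np.array([
            [0.0, 1.0, 1.0, 1.9],
            [1.0, 0.0, 1.9, 1.0],
            [1.0, 1.9, 0.0, 1.0],
            [1.9, 1.0, 1.0, 0.0],
        ])
        _, _, eigvals = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert eigvals.min() < -1e-9


class TestReplicateComparisonWorkflow:
    def test_systematic_shift_detected_over_seed_noise(self, tree,
                                                       unit_cn_spec):
        """Within- vs between-group UniFrac + exact MWU finds a real shift.

        Seed-only replicate groups should give unremarkable p-values on
        average; a systematic composition shift (dominant taxon knocked from
        75% to 55%) should drive them down.  Directional check over 20 seeds.
        """
        spec = unit_cn_spec
        shifted_probs = dict(spec.abundances)
        delta = 0.20
        shifted_probs["P_aeruginosa"] -= delta
        shifted_probs["S_aureus"] += delta

        def draws(rng, probs, k=3, depth=2000):
            out = []
            ids = list(probs)
            pvec = [probs[t] for t in ids]
            for _ in range(k):
                out.append(dict(zip(ids, rng.multinomial(depth, pvec))))
            return out

        p_null, p_shift = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ref = draws(rng, spec.abundances)
            null = draws(rng, spec.abundances)
            shift = draws(rng, shifted_probs)
            within = [
                weighted_unifrac(tree, a, b) for a, b in combinations(ref, 2)
            ]
            for group, sink in ((null, p_null), (shift, p_shift)):
                between = [
                    weighted_unifrac(tree, a, b)
                    for a in ref
                    for b in group
                ]
                _, p = exact_mann_whitney_u(within, between, "less")
                sink.append(p)
        assert np.mean(p_shift) < np.mean(p_null)
        assert np.median(p_shift) < 0.05
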