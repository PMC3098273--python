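"""Bray-Curtis, PERMANOVA and CAP: oracle equivalences, calibration and
invariants."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway

from seclipid.model import ValidationError
from seclipid.similarity import DistanceMatrix
from seclipid.simulate import gen_trait_matrix
from seclipid.traits import (TraitMatrix, bray_curtis, bray_curtis_matrix,
                             cap, pairwise_permanova, pcoa, permanova,
                             trait_biplot)


def euclidean_dm(x):
    x = np.asarray(x, dtype=float)
    D = np.abs(x[:, None] - x[None, :]) if x.ndim == 1 else \
        np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    return DistanceMatrix(tuple(f"i{i}" for i in range(len(x))), D)


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis((1, 0, 1), (1, 0, 1)) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis((1, 1, 0), (0, 0, 1)) == 1.0

    def test_half_shared(self):
        assert bray_curtis((1, 1, 0), (1, 0, 1)) == pytest.approx(0.5)

    def test_both_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis((0, 0), (0, 0))

    def test_matrix_matches_pairwise_calls(self):
        tm = gen_trait_matrix({"A": 3, "B": 3}, n_traits=10, theta=0.5, seed=1)
        dm = bray_curtis_matrix(tm)
        for i in range(6):
            for j in range(6):
                assert dm.values[i, j] == pytest.approx(
                    0.0 if i == j else
                    bray_curtis(tm.values[i], tm.values[j]))


class TestPermanova:
    def test_univariate_anova_equivalence_hand_example(self):
        dm = euclidean_dm([1, 2, 3, 4, 5, 6])
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3,
                        n_permutations="exhaustive")
        assert res.pseudo_F == pytest.approx(13.5, abs=1e-9)
        assert res.p_value == pytest.approx(0.1)
        assert res.n_permutations == 20

    def test_ss_partition_adds_up(self):
        dm = euclidean_dm([1, 2, 3, 4, 5, 6])
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3, n_permutations=9, seed=0)
        assert res.SS_among + res.SS_within == pytest.approx(res.SS_total,
                                                             abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_euclidean_limit_equals_classical_anova(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 6, size=3)
        x = rng.normal(size=int(sizes.sum()))
        groups = np.repeat([f"g{k}" for k in range(3)], sizes)
        res = permanova(euclidean_dm(x), groups, n_permutations=9, seed=0)
        parts = np.split(x, np.cumsum(sizes)[:-1])
        assert res.pseudo_F == pytest.approx(f_oneway(*parts).statistic,
                                             abs=1e-9)

    def test_agrees_with_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        tm = gen_trait_matrix({"A": 6, "B": 7, "C": 5}, theta=0.7, seed=42)
        dm = bray_curtis_matrix(tm)
        ours = permanova(dm, tm.groups, n_permutations=99, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.labels),
            list(tm.groups), permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_zero_within_variance(self):
        # identical observations within each group: F is infinite and no
        # group-mixing permutation can reach it, so p sits at the estimator
        # floor 1/(B+1) (a permutation recreating the exact partition would
        # tie at infinity; none occurs in this seeded run)
        D = np.zeros((12, 12))
        D[:6, 6:] = 1.0
        D[6:, :6] = 1.0
        dm = DistanceMatrix(tuple(f"i{i}" for i in range(12)), D)
        res = permanova(dm, ["g1"] * 6 + ["g2"] * 6, n_permutations=99,
                        seed=0)
        assert res.pseudo_F == np.inf
        assert res.p_value == pytest.approx(1 / 100)

    def test_small_group_rejected(self):
        dm = euclidean_dm([1, 2, 3])
        with pytest.raises(ValidationError):
            permanova(dm, ["g1", "g1", "g2"])

    def test_label_length_mismatch_rejected(self):
        dm = euclidean_dm([1, 2, 3, 4])
        with pytest.raises(ValidationError):
            permanova(dm, ["g1", "g2"])

    def test_null_p_values_super_uniform(self):
        """Under a true null the permutation p-values must be (super-)uniform
        at the resolution 1/(B+1)."""
        B, n_sims = 49, 100
        pvals = []
        for sim in range(n_sims):
            rng = np.random.default_rng(500 + sim)
            x = rng.normal(size=15)
            dm = euclidean_dm(x)
            groups = np.repeat(["a", "b", "c"], 5)
            pvals.append(permanova(dm, groups, n_permutations=B,
                                   seed=sim).p_value)
        pvals = np.asarray(pvals)
        for alpha in (0.1, 0.25, 0.5):
            emp = np.mean(pvals <= alpha)
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_sims)
            assert emp <= bound


class TestPairwisePermanova:
    def test_three_groups_three_pairs(self):
        tm = gen_trait_matrix({"A": 4, "B": 4, "C": 4}, theta=0.9, seed=2)
        dm = bray_curtis_matrix(tm)
        table = pairwise_permanova(dm, tm.groups, n_permutations=49, seed=0)
        assert len(table) == 3
        assert set(zip(table.group_a, table.group_b)) == \
            {("A", "B"), ("A", "C"), ("B", "C")}

    def test_pair_consistent_with_subset_global_test(self):
        tm = gen_trait_matrix({"A": 5, "B": 5}, theta=0.8, seed=3)
        dm = bray_curtis_matrix(tm)
        table = pairwise_permanova(dm, tm.groups, n_permutations=99, seed=7)
        direct = permanova(dm, tm.groups, n_permutations=99, seed=7)
        assert table.pseudo_F.iloc[0] == pytest.approx(direct.pseudo_F)

    def test_well_separated_groups_all_significant(self):
        tm = gen_trait_matrix({"A": 8, "B": 8, "C": 8}, theta=0.9, seed=11)
        dm = bray_curtis_matrix(tm)
        table = pairwise_permanova(dm, tm.groups, n_permutations=999, seed=0)
        assert (table.p_value <= 0.01).all()


class TestPcoa:
    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(D)
        D2 = np.linalg.norm(res.coordinates[:, None] -
                            res.coordinates[None, :], axis=-1)
        assert np.allclose(D, D2, atol=1e-6)

    def test_eigenvalue_sum_equals_retained_variance(self, rng):
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(D)
        total_var = (res.coordinates ** 2).sum()
        assert total_var == pytest.approx(res.eigvals.sum())


class TestCap:
    def test_perfectly_separated_groups(self):
        values = np.array([[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]] * 5)
        tm = TraitMatrix(tuple(f"o{i}" for i in range(10)),
                         ("t1", "t2", "t3", "t4"), values,
                         ("A",) * 5 + ("B",) * 5)
        dm = bray_curtis_matrix(tm)
        res = cap(dm, tm.groups, m=1, n_permutations=99, seed=0)
        assert res.allocation_success_overall == 100.0
        assert res.permutation_p <= 0.05

    def test_chance_threshold_seven_groups(self):
        tm = gen_trait_matrix({g: 5 for g in "ABFILMR"}, theta=0.5, seed=4)
        dm = bray_curtis_matrix(tm)
        res = cap(dm, tm.groups, m=3, n_permutations=0)
        assert round(res.chance_threshold, 1) == 14.3

    def test_m_too_large_rejected(self):
        tm = gen_trait_matrix({"A": 4, "B": 4}, theta=0.5, seed=5)
        dm = bray_curtis_matrix(tm)
        with pytest.raises(ValidationError):
            cap(dm, tm.groups, m=7)

    def test_success_monotone_in_association_strength(self):
        success = []
        for theta in (0.0, 0.5, 1.0):
            tm = gen_trait_matrix({"A": 8, "B": 8, "C": 8}, theta=theta,
                                  seed=21)
            dm = bray_curtis_matrix(tm)
            res = cap(dm, tm.groups, m=5, n_permutations=0)
            success.append(res.allocation_success_overall)
        assert success[0] <= success[1] <= success[2]
        assert success[2] >= 90.0

    def test_auto_m_maximises_loo_success(self):
        tm = gen_trait_matrix({"A": 6, "B": 6}, theta=1.0, seed=8)
        dm = bray_curtis_matrix(tm)
        res = cap(dm, tm.groups, m="auto", n_permutations=0)
        by_m = res.metadata["loo_success_by_m"]
        assert by_m[res.m] == max(by_m.values())

    def test_canonical_correlations_bounded(self):
        tm = gen_trait_matrix({"A": 6, "B": 6, "C": 6}, theta=0.7, seed=9)
        dm = bray_curtis_matrix(tm)
        res = cap(dm, tm.groups, m=4, n_permutations=0)
        assert np.all(res.canonical_correlations >= 0)
        assert np.all(res.canonical_correlations <= 1)
        assert res.canonical_axes.shape == (18, 2)


class TestTraitBiplot:
    def _cap_for(self, tm):
        dm = bray_curtis_matrix(tm)
        return cap(dm, tm.groups, m=3, n_permutations=0)

    def test_trait_equal_to_axis_rank(self):
        tm = gen_trait_matrix({"A": 6, "B": 6}, theta=1.0, seed=13)
        res = self._cap_for(tm)
        axis1 = res.canonical_axes[:, 0]
        values = np.column_stack([tm.values,
                                  (axis1 > np.median(axis1)).astype(np.int8)])
        tm2 = TraitMatrix(tm.organisms, tm.traits + ("aligned",), values,
                          tm.groups)
        table = trait_biplot(res, tm2)
        row = table[(table.trait == "aligned") & (table.axis == 1)]
        assert abs(row.rho.iloc[0]) > 0.8

    def test_constant_trait_omitted_with_warning(self):
        tm = gen_trait_matrix({"A": 5, "B": 5}, theta=1.0, seed=14)
        values = tm.values.copy()
        values[:, 0] = 1
        tm2 = TraitMatrix(tm.organisms, tm.traits, values, tm.groups)
        res = self._cap_for(tm2)
        with pytest.warns(UserWarning, match="constant"):
            table = trait_biplot(res, tm2)
        assert "trait_01" not in set(table.trait)

    def test_rows_respect_absolute_threshold(self):
        tm = gen_trait_matrix({"A": 8, "B": 8}, theta=0.6, seed=15)
        res = self._cap_for(tm)
        table = trait_biplot(res, tm, min_abs_rho=0.4)
        if len(table):
            assert (table.rho.abs() >= 0.4).all()


class TestTraitMatrix:
    def test_group_size_filter(self):
        tm = gen_trait_matrix({"A": 6, "B": 3}, theta=0.5, seed=16)
        filtered = tm.filter_by_group_size(min_n=5)
        assert set(filtered.groups) == {"A"}
        assert len(filtered.organisms) == 6

    def test_tsv_roundtrip(self, tmp_path):
        tm = gen_trait_matrix({"A": 4, "B": 4}, theta=0.5, seed=17)
        v, g = tmp_path / "v.tsv", tmp_path / "g.tsv"
        tm.write_tsv(v, g)
        back = TraitMatrix.read_tsv(v, g)
        assert back.organisms == tm.organisms
        assert back.groups == tm.groups
        assert np.array_equal(back.values, tm.values)

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            TraitMatrix(("a", "b"), ("t",), np.array([[2], [0]]), ("A", "B"))
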