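"""Latent-space statistics: BH, Welch, matching, atypicality, networks."""

import numpy as np
import pandas as pd
import pytest

from clockfactors.analysis import (benjamini_hochberg, compare_groups,
                                   correlation_network, count_atypical,
                                   propensity_match, traverse_latent,
                                   traversal_montage)
from clockfactors.rfvae import RFVAE


def bh_bruteforce(pvals, q):
    """Step-up by direct enumeration: largest i with p_(i) <= i*q/m."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBenjaminiHochberg:
    def test_worked_example(self):
        reject, _ = benjamini_hochberg([0.001, 0.02, 0.03, 0.5], q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = rng.choice([0.01, 0.05, 0.1])
            reject, p_adj = benjamini_hochberg(p, q)
            assert np.array_equal(reject, bh_bruteforce(p, q))
            assert np.all(p_adj >= p - 1e-15)

    def test_adjusted_monotone_in_raw_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        _, p_adj = benjamini_hochberg(p, 0.01)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-15)


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(40, 5))
        y = np.array([True] * 20 + [False] * 20)
        Z[y] = Z[~y]                     # byte-identical groups
        comp = compare_groups(Z, y)
        assert np.allclose(comp.table["t"], 0.0)
        assert np.allclose(comp.table["p_raw"], 1.0)
        assert not comp.significant.any()

    def test_welch_matches_textbook_formula(self):
        """t and df agree with the Welch formulas in extended precision."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = rng.integers(3, 40, 2)
            a = np.longdouble(rng.normal(0, rng.uniform(0.5, 3), n1))
            b = np.longdouble(rng.normal(rng.uniform(-1, 1),
                                         rng.uniform(0.5, 3), n2))
            v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
            t_ref = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
            df_ref = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
            Z = np.concatenate([a, b]).astype(float)[:, None]
            y = np.array([True] * n1 + [False] * n2)
            row = compare_groups(Z, y).table.iloc[0]
            assert abs(row["t"] - float(t_ref)) < 1e-10
            assert abs(row["df"] - float(df_ref)) < 1e-10

    def test_zero_variance_dimension_flagged(self):
        Z = np.zeros((20, 2))
        Z[:, 1] = np.arange(20.0)
        y = np.array([True] * 10 + [False] * 10)
        comp = compare_groups(Z, y)
        assert comp.table.loc[0, "degenerate"]
        assert comp.table.loc[0, "p_raw"] == 1.0
        assert not comp.table.loc[1, "degenerate"]

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(60, 10))
        Z[:30, 0] += 2.0
        y = np.array([True] * 30 + [False] * 30)
        comp = compare_groups(Z, y, q=0.01)
        assert np.all(comp.table["p_adj"] >= comp.table["p_raw"] - 1e-15)


class TestCountAtypical:
    def test_direct_threshold(self):
        counts = count_atypical(np.array([[2.5], [-3.0], [0.5]]),
                                np.zeros(1), np.ones(1), k=2)
        assert counts.tolist() == [2]

    def test_k_zero_counts_everything_off_mean(self):
        vals = np.array([[0.0], [1.0], [-2.0], [0.0]])
        counts = count_atypical(vals, np.zeros(1), np.ones(1), k=0)
        assert counts.tolist() == [2]

    def test_zero_sd_names_dimension(self):
        with pytest.raises(ValueError, match="1"):
            count_atypical(np.zeros((3, 2)), np.zeros(2),
                           np.array([1.0, 0.0]))

    def test_strictly_greater_than(self):
        counts = count_atypical(np.array([[2.0]]), np.zeros(1), np.ones(1),
                                k=2)
        assert counts.tolist() == [0]


class TestPropensityMatch:
    @staticmethod
    def make_subjects(ages_dem, ages_ctl, edu_dem=None, edu_ctl=None):
        rows = []
        for i, a in enumerate(ages_dem):
            rows.append({"id": f"d{i}", "label": "dementia", "age": a,
                         "education": (edu_dem or [12] * len(ages_dem))[i]})
        for i, a in enumerate(ages_ctl):
            rows.append({"id": f"c{i}", "label": "control", "age": a,
                         "education": (edu_ctl or [12] * len(ages_ctl))[i]})
        return pd.DataFrame(rows)

    def test_nearest_control_selected(self):
        df = self.make_subjects([80], [79, 60])
        res = propensity_match(df, ratio=1)
        picked = res.matched[res.matched.label == "control"]["age"].tolist()
        assert picked == [79]

    def test_null_confounding_balances(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(70, 5, 240)
        edus = rng.normal(14, 2, 240)
        df = self.make_subjects(ages[:40].tolist(), ages[40:].tolist(),
                                edus[:40].tolist(), edus[40:].tolist())
        res = propensity_match(df, ratio=2)
        assert len(res.matched) == 40 * 3
        assert abs(res.smd_after["age"]) < 0.1
        assert abs(res.smd_after["education"]) < 0.1

    def test_matched_cohort_size_ratio_two(self):
        """With 1:2 matching the analyzed cohort is cases + 2x cases."""
        rng = np.random.default_rng(1)
        df = self.make_subjects(rng.normal(80, 5, 55).tolist(),
                                rng.normal(68, 6, 175).tolist(),
                                rng.normal(13, 2, 55).tolist(),
                                rng.normal(16, 2, 175).tolist())
        res = propensity_match(df, ratio=2)
        assert (res.matched.label == "dementia").sum() == 55
        assert (res.matched.label == "control").sum() == 110

    def test_without_replacement(self):
        rng = np.random.default_rng(2)
        df = self.make_subjects(rng.normal(75, 3, 20).tolist(),
                                rng.normal(72, 4, 50).tolist())
        res = propensity_match(df, ratio=2)
        ctl_ids = res.matched[res.matched.label == "control"]["id"]
        assert ctl_ids.is_unique

    def test_shortfall_flagged(self):
        df = self.make_subjects([80, 81, 82], [79])
        with pytest.warns(UserWarning, match="fewer"):
            res = propensity_match(df, ratio=2)
        assert res.shortfall >= 2


class TestCorrelationNetwork:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        Z = np.column_stack([a, a, rng.normal(size=200)])
        net = correlation_network(Z)
        pos = net.pos_edges
        assert len(pos) == 1
        assert pos.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_columns_no_edges(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(10000, 6))
        net = correlation_network(Z)
        assert len(net.edges) == 0

    def test_three_planted_blocks_recovered(self):
        """Three positively-correlated blocks with negative cross-block
        correlation yield exactly three subnetworks."""
        rng = np.random.default_rng(2)
        n = 2000
        u = rng.normal(size=(n, 3))
        u -= u.mean(axis=0)
        noise = lambda: 0.8 * rng.normal(size=n)
        Z = np.column_stack([
            u[:, 0] + noise(), u[:, 0] + noise(),          # block 1
            u[:, 1] - 0.45 * u[:, 0] + noise(),
            u[:, 1] - 0.45 * u[:, 0] + noise(),            # block 2
            u[:, 2] - 0.45 * u[:, 1] + noise(),
            u[:, 2] - 0.45 * u[:, 1] + noise(),            # block 3
        ])
        net = correlation_network(Z, threshold=0.2)
        assert len(net.subnetworks) == 3
        assert sorted(map(sorted, net.subnetworks)) == [
            ["z0", "z1"], ["z2", "z3"], ["z4", "z5"]]
        assert len(net.neg_edges) > 0

    def test_label_excluded_from_subnetworks(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=500)
        y = (a > 0).astype(int)
        Z = np.column_stack([a, a + 0.1 * rng.normal(size=500)])
        net = correlation_network(Z, labels=y)
        assert all("dementia_label" not in s for s in net.subnetworks)
        assert "dementia_label" in net.corr.columns

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        Z = np.column_stack([rng.normal(size=100), np.full(100, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(Z)
        assert net.dropped == ["z1"]
        assert "z1" not in net.corr.columns

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(500, 2))
        Z = np.column_stack([u[:, 0], u[:, 0] + 0.3 * rng.normal(size=500),
                             u[:, 1], u[:, 1] + 0.3 * rng.normal(size=500)])
        net1 = correlation_network(Z)
        assert np.allclose(net1.corr.values, net1.corr.values.T)
        perm = [2, 3, 0, 1]
        net2 = correlation_network(Z[:, perm],
                                   names=[f"z{p}" for p in perm])
        assert (sorted(map(sorted, net1.subnetworks))
                == sorted(map(sorted, net2.subnetworks)))


class TestTraversal:
    def test_linear_grid(self):
        m = RFVAE(latent_dim=10, seed=0)
        grid = traverse_latent(m, dim=1, steps=7)
        assert np.allclose(grid.values, [-3, -2, -1, 0, 1, 2, 3])
        assert grid.images.shape == (7, 64, 64)

    def test_dim_out_of_range(self):
        m = RFVAE(latent_dim=10, seed=0)
        with pytest.raises(ValueError, match="dim"):
            traverse_latent(m, dim=11)

    def test_base_code_held_fixed(self, tiny_trained_vae):
        model, _ = tiny_trained_vae
        base = np.zeros(10)
        grid = traverse_latent(model, dim=3, steps=5, base_code=base)
        mid = grid.images[2]             # value 0 == base code itself
        assert np.allclose(mid, model.decode(base), atol=1e-12)

    def test_montage_shape(self, tiny_trained_vae):
        model, _ = tiny_trained_vae
        montage = traversal_montage(model, steps=3)
        assert montage.shape == (3 * 64, 10 * 64)
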