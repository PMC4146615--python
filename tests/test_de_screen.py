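"""Normalization, the conditioned NB test, BH adjustment, and the screen.

The conditioned test is checked against two independent oracles: the
closed-form conditional binomial at dispersion zero, and a plain
probability-space enumeration of all splits of the total count otherwise.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regulon_screen.de_screen import (
    STATUS_ELIMINATED,
    STATUS_KNOWN,
    STATUS_NOVEL,
    STATUS_REGULATOR,
    bh_adjust,
    candidate_screen,
    de_test,
    estimate_dispersion,
    nb_conditioned_test,
    size_factors,
)
from regulon_screen.io_formats import CountTable
from regulon_screen.synthetic_data import SimulationSpec, simulate_counts
from tests.conftest import KNOWN_TARGETS, REGULATOR


def _table(counts, conditions=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    conditions = conditions or {c: "A" for c in df.columns}
    return CountTable(counts=df.astype(np.int64), conditions=conditions)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        t = _table([[5, 5, 5], [9, 9, 9], [2, 2, 2]])
        np.testing.assert_allclose(size_factors(t).to_numpy(), 1.0)

    def test_two_by_two_direct_evaluation(self):
        t = _table([[2, 8], [2, 8]])
        np.testing.assert_allclose(size_factors(t).to_numpy(), [0.5, 2.0])

    def test_scale_equivariance(self, rng):
        k = rng.integers(1, 100, size=(30, 4))
        t = _table(k)
        s = size_factors(t).to_numpy()
        k2 = k.copy()
        k2[:, 2] *= 3
        s2 = size_factors(_table(k2)).to_numpy()
        np.testing.assert_allclose(s2[2], 3 * s[2] * (s2[0] / s[0]))
        # relative factors of untouched samples unchanged
        np.testing.assert_allclose(s2[[0, 1, 3]] / s2[0], s[[0, 1, 3]] / s[0])

    def test_permutation_invariance_over_genes(self, rng):
        k = rng.integers(1, 100, size=(30, 4))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            size_factors(_table(k)).to_numpy(), size_factors(_table(k[perm])).to_numpy()
        )

    def test_all_zero_gene_universe_rejected(self):
        t = _table([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="positive counts"):
            size_factors(t)


class TestDispersion:
    def test_identical_replicates_give_zero(self):
        t = _table([[10, 10], [50, 50], [3, 3]])
        phi = estimate_dispersion(t, size_factors(t), pool_all=True)
        np.testing.assert_allclose(phi.to_numpy(), 0.0)

    def test_poisson_counts_yield_near_zero_trend_floor(self):
        spec = SimulationSpec(seed=11, genes=2000, dispersion=0.0, n_de=0,
                              samples_per_condition=(10, 10), baseline_mean=200.0)
        table, _ = simulate_counts(spec)
        phi = estimate_dispersion(table, size_factors(table))
        assert np.median(phi) < 0.02

    def test_nb_dispersion_recovered(self):
        spec = SimulationSpec(seed=12, genes=2000, dispersion=0.1, n_de=0,
                              samples_per_condition=(10, 10), baseline_mean=200.0)
        table, _ = simulate_counts(spec)
        phi = estimate_dispersion(table, size_factors(table))
        assert 0.05 <= np.median(phi) <= 0.2

    def test_single_replicate_condition_warns_and_pools(self):
        t = _table([[10, 11, 200], [50, 52, 49]],
                   conditions={"s0": "A", "s1": "A", "s2": "B"})
        with pytest.warns(UserWarning, match="blind"):
            estimate_dispersion(t, size_factors(t))


def _oracle_conditional_p(counts_a, counts_b, sf_a, sf_b, phi):
    """Probability-space enumeration over all splits a + b = k_S."""
    k_a, k_b = int(sum(counts_a)), int(sum(counts_b))
    k_s = k_a + k_b
    mu = k_s / (sum(sf_a) + sum(sf_b))

    def pmf(k, sf):
        mean = mu * sum(sf)
        var = sum(mu * f + phi * (mu * f) ** 2 for f in sf)
        if var <= mean * (1 + 1e-12):
            return stats.poisson.pmf(k, mean)
        r = mean**2 / (var - mean)
        return stats.nbinom.pmf(k, r, r / (r + mean))

    a = np.arange(k_s + 1)
    joint = pmf(a, sf_a) * pmf(k_s - a, sf_b)
    obs = joint[k_a]
    return joint[joint <= obs * (1 + 1e-9)].sum() / joint.sum()


class TestConditionedTest:
    def test_balanced_counts_give_p_one(self):
        p = nb_conditioned_test([10, 10], [10, 10], [1, 1], [1, 1], 0.1)
        assert p == 1.0

    def test_poisson_limit_equals_conditional_binomial(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ka = rng.integers(0, 60)
            kb = rng.integers(0, 60)
            n_a, n_b = rng.integers(1, 4, size=2)
            p = nb_conditioned_test([ka], [kb], np.ones(n_a), np.ones(n_b), 0.0)
            k_s = ka + kb
            q = n_a / (n_a + n_b)
            pmf = stats.binom.pmf(np.arange(k_s + 1), k_s, q)
            expected = pmf[pmf <= pmf[ka] * (1 + 1e-9)].sum()
            assert p == pytest.approx(min(expected, 1.0), abs=1e-12)

    def test_extreme_split_is_significant_and_matches_oracle(self):
        p = nb_conditioned_test([0], [50], [1.0], [1.0], 0.1)
        assert p < 0.01
        oracle = _oracle_conditional_p([0], [50], [1.0], [1.0], 0.1)
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_matches_enumeration_oracle_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            counts_a = rng.integers(0, 40, size=rng.integers(1, 4))
            counts_b = rng.integers(0, 40, size=rng.integers(1, 4))
            if counts_a.sum() + counts_b.sum() == 0:
                continue
            sf_a = rng.uniform(0.5, 2.0, size=len(counts_a))
            sf_b = rng.uniform(0.5, 2.0, size=len(counts_b))
            phi = float(rng.choice([0.0, 0.05, 0.2]))
            p = nb_conditioned_test(counts_a, counts_b, sf_a, sf_b, phi)
            oracle = _oracle_conditional_p(counts_a, counts_b, sf_a, sf_b, phi)
            assert p == pytest.approx(min(oracle, 1.0), abs=1e-12)

    def test_symmetric_in_conditions(self):
        p1 = nb_conditioned_test([3, 7], [25, 30], [1, 1.2], [0.9, 1.1], 0.08)
        p2 = nb_conditioned_test([25, 30], [3, 7], [0.9, 1.1], [1, 1.2], 0.08)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            nb_conditioned_test([1.5], [2], [1], [1], 0.1)


class TestBH:
    def test_equal_ps_unchanged(self):
        p = np.full(5, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_stepup_hand_examples(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust(np.array([0.005, 0.5])), [0.01, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_properties_and_statsmodels_agreement(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p-rank
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-10)


class TestCandidateScreen:
    def _run(self, table2, **kw):
        de_a = table2.rename(columns={"fc_a": "fc", "q_a": "q"})[["fc", "q"]]
        de_b = table2.rename(columns={"fc_b": "fc", "q_b": "q"})[["fc", "q"]]
        return candidate_screen(de_a, de_b, KNOWN_TARGETS, REGULATOR, **kw)

    def test_published_fixture_yields_twelve_novel(self, table2):
        out = self._run(table2)
        novel = (out.status == STATUS_NOVEL).sum() + (out.status == STATUS_ELIMINATED).sum()
        assert novel == 12
        assert (out.status == STATUS_KNOWN).sum() == 5
        assert (out.status == STATUS_REGULATOR).sum() == 1

    def test_published_elimination_set(self, table2):
        out = self._run(table2)
        eliminated = set(out.loc[out.status == STATUS_ELIMINATED, "gene"])
        assert eliminated == {"SCO7688", "SCO7682", "SCO2878"}

    def test_sorted_by_descending_fold(self, table2):
        out = self._run(table2)
        assert (out.fc_a.diff().dropna() <= 0).all()

    def test_empty_input_gives_empty_table(self):
        empty = pd.DataFrame(columns=["fc", "q"])
        out = candidate_screen(empty, empty, [], "soxR")
        assert out.empty

    def test_mismatched_universes_rejected(self, table2):
        de_a = table2.rename(columns={"fc_a": "fc", "q_a": "q"})[["fc", "q"]]
        de_b = de_a.drop("SCO0319")
        with pytest.raises(ValueError, match="SCO0319"):
            candidate_screen(de_a, de_b, [], "x")


class TestParameterRecovery:
    def test_screen_fdp_and_sensitivity_on_planted_truth(self):
        """1000 genes, 50 planted at fold 4, 3 vs 3, phi = 0.05: across 20
        seeds the realized false-discovery proportion at q <= 0.05 stays
        below 0.10 and sensitivity above 0.8."""
        fdps, sens = [], []
        for seed in range(20):
            spec = SimulationSpec(seed=seed, genes=1000, n_de=50, log2_fold=2.0,
                                  dispersion=0.05, samples_per_condition=(3, 3))
            table, truth = simulate_counts(spec)
            res = de_test(table, "B", "A").table
            called = res.index[(res.q <= 0.05) & (res.fc >= 1)]
            true_de = {g for g, b in truth.true_log2_fold.items() if b != 0}
            if len(called) == 0:
                continue
            fp = len([g for g in called if g not in true_de])
            fdps.append(fp / len(called))
            sens.append(len([g for g in called if g in true_de]) / len(true_de))
        assert np.mean(fdps) <= 0.10
        assert np.mean(sens) >= 0.8
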