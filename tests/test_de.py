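"""Differential-expression tests against closed forms and enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen.de import (
    call_de,
    cpm_normalize,
    equalize_libraries,
    estimate_common_dispersion,
    log_fold_change,
    nb_exact_test,
    summarize_de,
    t_test_feature,
)
from mirscreen.exceptions import DataError
from mirscreen.io import ExpressionMatrix

from _factories import make_de_table, make_matrix, t_density_pvalue


class TestCpm:
    def test_single_feature_hits_a_million(self):
        m = make_matrix({"s1": [5]}, {"s1": "ND"})
        assert cpm_normalize(m).iloc[0, 0] == 1e6

    def test_proportions_preserved(self):
        m = make_matrix({"s1": [1, 3]}, {"s1": "ND"})
        assert list(cpm_normalize(m)["s1"]) == [250_000.0, 750_000.0]

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            pd.DataFrame(rng.integers(0, 500, (30, 6)).astype(np.int64)
                         ).rename(columns=str).rename(index=str),
            {str(i): "G" for i in range(6)},
        )
        np.testing.assert_allclose(cpm_normalize(m).sum(axis=0), 1e6)

    def test_all_zero_sample_rejected(self):
        m = make_matrix({"s1": [0, 0], "s2": [1, 2]}, {"s1": "ND", "s2": "WD"})
        with pytest.raises(DataError, match="s1"):
            cpm_normalize(m)


class TestLogFoldChange:
    @pytest.mark.parametrize(
        "mt,mr,pc,expected",
        [(8, 2, 0, 2.0), (5, 5, 0, 0.0), (0, 7.5, 0.5, -4.0)],
    )
    def test_closed_forms(self, mt, mr, pc, expected):
        assert log_fold_change(mt, mr, pc) == pytest.approx(expected)

    def test_zero_means_need_pseudocount(self):
        with pytest.raises(DataError):
            log_fold_change(0.0, 0.0, 0.0)


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert t_test_feature([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_pooled_p_matches_density_integration(self):
        # {1,2,3} vs {4,5,6}: |t| = 3/sqrt(2/3) = 3.674, df = 4
        p = t_test_feature([1, 2, 3], [4, 5, 6])
        t_stat = 3.0 / math.sqrt(2.0 / 3.0)
        assert t_stat == pytest.approx(3.674, abs=5e-4)
        assert p == pytest.approx(t_density_pvalue(t_stat, 4), rel=1e-5)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 4.0, 2.0], [5.0, 3.0, 8.0]
        assert t_test_feature(a, b) == pytest.approx(t_test_feature(b, a))

    def test_constant_groups(self):
        assert t_test_feature([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert t_test_feature([2.0, 2.0], [3.0, 3.0]) == 0.0


from _oracles import nb_conditional_oracle  # noqa: E402


class TestNbExactTest:
    def test_balanced_split_gives_p_one(self):
        assert nb_exact_test([5, 5], [5, 5], 0.1) == pytest.approx(1.0)

    def test_phi_zero_reduces_to_binomial(self):
        # totals 10 vs 0 from equal-sized groups: two-sided binomial(10, 1/2)
        p = nb_exact_test([5, 5], [0, 0], 0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 1.0])
    def test_matches_enumeration_oracle_on_small_totals(self, phi):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_a, n_b = rng.integers(2, 5, size=2)
            a = rng.integers(0, 6, size=n_a)
            b = rng.integers(0, 6, size=n_b)
            if a.sum() + b.sum() > 30:
                continue
            expected = nb_conditional_oracle(list(a), list(b), phi)
            assert nb_exact_test(a, b, phi) == pytest.approx(expected, rel=1e-8)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(DataError):
            nb_exact_test([1], [2], -0.1)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(100, size=(2000, 8)),
            index=[f"f{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = {f"s{i}": "A" for i in range(8)}
        assert estimate_common_dispersion(counts, groups) < 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(4)
        phi = 0.1
        mu = rng.uniform(50, 500, size=2000)
        size = 1 / phi
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mu[:, None]), size=(2000, 8)),
            index=[f"f{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(8)],
        )
        est = estimate_common_dispersion(counts, {f"s{i}": "A" for i in range(8)})
        assert 0.05 <= est <= 0.2

    def test_constant_counts_clamp_to_zero(self):
        counts = pd.DataFrame(
            np.full((5, 4), 7), index=list("abcde"), columns=list("wxyz")
        )
        assert estimate_common_dispersion(counts, {s: "A" for s in "wxyz"}) == 0.0

    def test_requires_a_replicated_group(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(DataError):
            estimate_common_dispersion(counts, {"s1": "A"})


class TestCallDe:
    @staticmethod
    def _two_group_matrix(rng, n_features=60, effect_rows=(), lfc=2.0):
        mu = np.full((n_features, 8), 200.0)
        for r in effect_rows:
            mu[r, 4:] *= 2.0**lfc
        counts = rng.poisson(mu)
        df = pd.DataFrame(
            counts, index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = {f"s{i}": ("ND" if i < 4 else "WD") for i in range(8)}
        return ExpressionMatrix(df, groups)

    def test_unknown_group_rejected(self):
        m = make_matrix({"s1": [1], "s2": [2]}, {"s1": "ND", "s2": "WD"})
        with pytest.raises(DataError, match="XX"):
            call_de(m, ("XX", "ND"))

    def test_planted_effect_called_with_direction(self):
        rng = np.random.default_rng(8)
        m = self._two_group_matrix(rng, effect_rows=(0, 1), lfc=2.0)
        table = call_de(m, ("WD", "ND"), test="nb", lfc_min=1.0)
        assert set(table.up_ids) >= {"f0", "f1"}

    def test_antisymmetry_of_comparisons(self):
        rng = np.random.default_rng(9)
        m = self._two_group_matrix(rng, effect_rows=(0,), lfc=2.0)
        fwd = call_de(m, ("WD", "ND"), test="t")
        rev = call_de(m, ("ND", "WD"), test="t")
        np.testing.assert_allclose(
            fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12
        )
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert list(rev.table["call"]) == [swap[c] for c in fwd.table["call"]]

    def test_stricter_alpha_selects_a_subset(self):
        rng = np.random.default_rng(10)
        m = self._two_group_matrix(rng, effect_rows=tuple(range(10)), lfc=1.2)
        loose = set(call_de(m, ("WD", "ND"), test="t", alpha=0.05).de_ids)
        strict = set(call_de(m, ("WD", "ND"), test="t", alpha=0.01).de_ids)
        assert strict <= loose

    def test_mrna_rule_requires_large_fold_change(self):
        # p < 0.05 but |log2fc| < 1 must stay ns under the mRNA rule
        rng = np.random.default_rng(11)
        m = self._two_group_matrix(rng, effect_rows=(0,), lfc=0.6)
        table = call_de(m, ("WD", "ND"), test="nb", lfc_min=1.0)
        row = table.table.loc["f0"]
        assert row["p_value"] < 0.05 and abs(row["log2fc"]) < 1
        assert row["call"] == "ns"


class TestSummarize:
    @pytest.mark.parametrize("n_up,n_down", [(39, 81), (856, 641), (0, 0)])
    def test_total_is_up_plus_down(self, n_up, n_down):
        table = make_de_table(
            up=[f"u{i}" for i in range(n_up)],
            down=[f"d{i}" for i in range(n_down)],
            ns=["x1", "x2"],
        )
        s = summarize_de(table)
        assert (s.n_up, s.n_down, s.n_total) == (n_up, n_down, n_up + n_down)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 10))
    def test_conservation_property(self, n_up, n_down, n_ns):
        table = make_de_table(
            up=[f"u{i}" for i in range(n_up)],
            down=[f"d{i}" for i in range(n_down)],
            ns=[f"n{i}" for i in range(n_ns)],
        )
        s = summarize_de(table)
        assert s.n_total == s.n_up + s.n_down


class TestEqualize:
    def test_columns_near_geometric_mean(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(rng.integers(10, 1000, (100, 6)))
        eq = equalize_libraries(counts)
        target = np.exp(np.log(counts.sum(axis=0)).mean())
        assert np.allclose(eq.sum(axis=0), target, rtol=0.01)
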