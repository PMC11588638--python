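"""Statistical tests, star conventions and the summary tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vhh_typology import (
    ValidationError,
    mann_whitney_u,
    paired_t_test,
    pearson_correlation,
    stars,
    summarize_by_type,
    summarize_interfaces,
)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, "ns"), (0.051, "ns"),
            (0.05, "*"), (0.03, "*"), (0.01, "*"),
            (0.009, "**"), (0.001, "**"),
            (0.0009, "***"), (0.0001, "***"),
            (0.00009, "****"), (0.0, "****"),
        ],
    )
    def test_boundaries(self, p, expected):
        assert stars(p) == expected

    def test_total_on_unit_interval(self):
        for p in np.linspace(0, 1, 1001):
            assert stars(float(p)) in {"ns", "*", "**", "***", "****"}


def enumeration_oracle(a, b):
    """Literal two-sided exact Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n_le = n_ge = total = 0
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        total += 1
        n_le += u <= u_obs + 1e-9
        n_ge += u >= u_obs - 1e-9
    return min(1.0, 2 * min(n_le, n_ge) / total)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        s = list(range(10))
        assert mann_whitney_u(s, s).p_value >= 0.99

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 7), rng.integers(3, 7)
        a = rng.normal(size=na)
        b = rng.normal(loc=rng.uniform(0, 2), size=nb)
        got = mann_whitney_u(a, b).p_value
        assert got == pytest.approx(enumeration_oracle(a, b))

    def test_exact_equals_enumeration_with_ties(self):
        a = [1, 2, 2, 3, 5]
        b = [2, 3, 3, 4, 4, 6]
        assert mann_whitney_u(a, b).p_value == pytest.approx(enumeration_oracle(a, b))

    def test_exact_agrees_with_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=8)
        b = rng.normal(loc=0.8, size=7)
        got = mann_whitney_u(a, b).p_value
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(float(ref))

    def test_separated_samples_fully_significant(self):
        cmp = mann_whitney_u(list(range(1, 11)), list(range(101, 111)))
        assert cmp.p_value == pytest.approx(2 / math.comb(20, 10))
        assert cmp.stars == "****"

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        b = rng.normal(loc=1.0, size=50)
        cmp = mann_whitney_u(a, b)
        assert 0 < cmp.p_value < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_null_simulation_type_one_error(self):
        """Rejection rate at alpha=0.05 under the null stays near nominal."""
        rng = np.random.default_rng(123)
        reps = 800
        rejections = sum(
            mann_whitney_u(rng.normal(size=30), rng.normal(size=30)).p_value <= 0.05
            for _ in range(reps)
        )
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        r, p = pearson_correlation(x, y)
        sx, sy = x - x.mean(), y - y.mean()
        r_hand = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert r == pytest.approx(r_hand)
        t = r_hand * math.sqrt(8 / (1 - r_hand**2))
        p_hand = 2 * sps.t.sf(abs(t), df=8)
        assert p == pytest.approx(p_hand, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestPairedT:
    def test_identical_pairs(self):
        cmp = paired_t_test([1, 2, 3], [1, 2, 3])
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0 and cmp.stars == "ns"

    def test_constant_nonzero_difference(self):
        cmp = paired_t_test([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert math.isinf(cmp.statistic) and cmp.p_value == 0.0

    def test_alternating_differences_zero_t(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [0.0, 3.0, 2.0, 5.0]  # differences +1, -1, +1, -1
        cmp = paired_t_test(a, b)
        assert cmp.statistic == pytest.approx(0.0)

    def test_matches_closed_form(self):
        a = np.array([2.0, 4.0, 3.0, 5.0, 7.0])
        b = np.array([1.0, 2.0, 4.0, 3.0, 6.0])
        cmp = paired_t_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), df=len(d) - 1)
        assert cmp.statistic == pytest.approx(t)
        assert cmp.p_value == pytest.approx(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t_test([1, 2], [1, 2, 3])


class TestRepertoireTables:
    def _typed_df(self, rng, n=400):
        types = rng.choice(["Y_C2", "F_C2", "F_C4"], size=n, p=[0.4, 0.3, 0.3])
        length_mean = {"Y_C2": 12, "F_C2": 16, "F_C4": 19}
        return pd.DataFrame({
            "vhh_type": types,
            "classical": True,
            "cdr3_length": [rng.poisson(length_mean[t]) for t in types],
            "mismatches": rng.poisson(9, size=n),
            "mismatch_score": rng.normal(10, 1, size=n),
            "net_charge_CDR3": rng.normal(-0.5, 1, size=n),
            "animal_id": rng.choice([f"A{i}" for i in range(6)], size=n),
            "age_group": rng.choice(["0-1", "1-2", "3-4"], size=n),
            "hinge": rng.choice(["2B", "2C"], size=n),
        })

    def test_single_type_percentage_is_100(self):
        df = pd.DataFrame({
            "vhh_type": ["Y_C2"] * 5, "classical": [True] * 5,
            "cdr3_length": [12] * 5, "mismatches": [3] * 5,
            "mismatch_score": [1.0] * 5, "net_charge_CDR3": [0.0] * 5,
            "animal_id": ["A1"] * 5, "age_group": ["3-4"] * 5, "hinge": ["2B"] * 5,
        })
        tables = summarize_by_type(df)
        assert tables["type_percentages"].loc["Y_C2", "All"] == pytest.approx(100.0)

    def test_se_of_constant_column_is_zero(self):
        df = pd.DataFrame({
            "vhh_type": ["Y_C2"] * 4, "classical": [True] * 4,
            "cdr3_length": [12] * 4, "mismatches": [3] * 4,
            "mismatch_score": [7.0] * 4, "net_charge_CDR3": [0.0] * 4,
            "animal_id": ["A1"] * 4, "age_group": ["3-4"] * 4, "hinge": ["2B"] * 4,
        })
        tables = summarize_by_type(df)
        assert tables["mismatch_scores"].loc["Y_C2", "All_se"] == 0.0

    def test_length_ordering_recovered_with_stars(self):
        rng = np.random.default_rng(4)
        df = self._typed_df(rng)
        df.loc[df.index[-40:], "classical"] = False
        df.loc[df.index[-40:], "cdr3_length"] -= 4
        tables = summarize_by_type(df)
        t = tables["classical_vs_nonclassical"]
        assert t.loc["Classical", "cdr3_length_mean"] > t.loc["Non-classical", "cdr3_length_mean"]
        assert t["cdr3_length_stars"].iloc[0] in {"***", "****"}
        ms = tables["mismatch_scores"]
        assert list(ms.index) == ["Y_C2", "F_C2", "F_C4"]

    def test_hinge_rows_sum_to_100(self):
        rng = np.random.default_rng(9)
        tables = summarize_by_type(self._typed_df(rng))
        hinge = tables["hinge_usage"]
        np.testing.assert_allclose(hinge.sum(axis=1), 100.0, rtol=1e-9)


class TestInterfaceTables:
    def _frame(self):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(60):
            vhh_type = ["Y_C2", "F_C2", "F_C4", "N_V3"][i % 4]
            fr2 = 1 if vhh_type in ("Y_C2", "N_V3") and i % 2 == 0 else 0
            cdr2 = int(rng.integers(0, 4))
            cdr3 = 8 - cdr2 + int(rng.integers(0, 2))  # planted CDR2/CDR3 trade-off
            rows.append({
                "complex_id": f"c{i}", "vhh_type": vhh_type,
                "paratope_kind": "FR2_involving" if fr2 else "non_FR2",
                "cdr3_length": int(rng.integers(8, 18)),
                "bsa_epitope": float(rng.uniform(400, 900)),
                "bsa_paratope": float(rng.uniform(400, 900)),
                "contacts_CDR1": int(rng.integers(0, 4)),
                "contacts_CDR2": cdr2, "contacts_CDR3": cdr3,
                "contacts_FR2": fr2, "contacts_other": 0,
                "fr2_positions": ("42",) if fr2 else (),
            })
        return pd.DataFrame(rows)

    def test_top3_ranks_planted_position_first(self):
        out = summarize_interfaces(self._frame())
        top = out["fr2_top3"]
        first = top[(top["vhh_type"] == "Y_C2") & (top["rank"] == 1)]
        assert first["imgt_position"].iloc[0] == "42"
        assert first["pct"].iloc[0] == pytest.approx(100.0)

    def test_no_fr2_involving_notice(self):
        df = self._frame()
        df["paratope_kind"] = "non_FR2"
        df["contacts_FR2"] = 0
        df["fr2_positions"] = [()] * len(df)
        out = summarize_interfaces(df)
        assert len(out["fr2_top3"]) == 0
        assert "no FR2-involving" in out["fr2_top3_notice"]

    def test_planted_cdr2_cdr3_tradeoff_gives_negative_correlation(self):
        out = summarize_interfaces(self._frame())
        for mat in out["contact_correlations"].values():
            assert mat.loc["CDR2", "CDR3"] < 0

    def test_fr2_involving_fraction(self):
        out = summarize_interfaces(self._frame())
        pct = out["fr2_involving_pct"]
        assert pct["Y_C2"] > pct["F_C2"] == 0.0
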