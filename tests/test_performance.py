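import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from niptcnv.performance import (OutcomeLedger, ScreeningTable,
                                 build_outcome_ledger, pearson_chi2,
                                 positive_rate, ppv, stratify_calls,
                                 summarize_cohort)


class TestPpv:
    @pytest.mark.parametrize("tp,fp,expected", [
        (92, 69, 57.14),   # overall screening PPV
        (22, 12, 64.71),   # calls around 1 Mb
        (5, 0, 100.00),
        (4, 10, 28.57),
        (88, 59, 59.86),
    ])
    def test_values(self, tp, fp, expected):
        assert ppv(tp=tp, fp=fp) == expected

    def test_undefined_without_diagnosed_cases(self):
        with pytest.raises(ValueError):
            ppv(tp=0, fp=0)
        with pytest.raises(ValueError):
            ppv(tp=-1, fp=5)

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           k=st.integers(1, 9))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, tp, fp, k):
        if tp + fp == 0:
            return
        assert ppv(tp=tp * k, fp=fp * k) == ppv(tp=tp, fp=fp)


class TestPositiveRate:
    @pytest.mark.parametrize("pos,screened,expected", [
        (281, 68_588, 0.41),
        (19, 12_885, 0.15),
        (262, 55_703, 0.47),
        (0, 100, 0.0),
    ])
    def test_values(self, pos, screened, expected):
        assert positive_rate(pos, screened) == expected

    def test_zero_screened_rejected(self):
        with pytest.raises(ValueError):
            positive_rate(1, 0)


class TestStratification:
    def test_deletion_column_ppvs(self):
        """The four deletion strata (31/30, 17/11, 8/1, 5/6) give the printed
        PPVs 50.82 / 60.71 / 88.89 / 45.45%."""
        rows = []
        strata = {"0-5": (31, 30), "5-10": (17, 11), "10-20": (8, 1),
                  ">=20": (5, 6)}
        for stratum, (tp, fp) in strata.items():
            rows += [{"stratum": stratum, "kind": "deletion",
                      "true_positive": True}] * tp
            rows += [{"stratum": stratum, "kind": "deletion",
                      "true_positive": False}] * fp
        table = stratify_calls(rows)
        assert table.loc["0-5", "deletion_ppv"] == 50.82
        assert table.loc["5-10", "deletion_ppv"] == 60.71
        assert table.loc["10-20", "deletion_ppv"] == 88.89
        assert table.loc[">=20", "deletion_ppv"] == 45.45
        assert table.loc["total", "deletion_ppv"] == 55.96

    def test_strata_sum_to_margins(self):
        rng = np.random.default_rng(3)
        rows = [{"size_mb": float(rng.uniform(0.5, 40)),
                 "kind": rng.choice(["deletion", "duplication"]),
                 "true_positive": bool(rng.random() < 0.6)}
                for _ in range(200)]
        t = stratify_calls(rows)
        body = t.drop(index="total")
        for col in ("deletion_tp", "deletion_fp", "duplication_tp",
                    "duplication_fp", "total_tp", "total_fp"):
            assert body[col].sum() == t.loc["total", col]
        assert (t["total_tp"] == t["deletion_tp"] + t["duplication_tp"]).all()

    def test_empty_stratum_flagged_undefined(self):
        rows = [{"size_mb": 2.0, "kind": "deletion", "true_positive": True}]
        t = stratify_calls(rows)
        assert t.loc["10-20", "deletion_tp"] == 0
        assert np.isnan(t.loc["10-20", "deletion_ppv"])

    def test_all_true_gives_100_everywhere_nonempty(self):
        rows = [{"size_mb": s, "kind": "duplication", "true_positive": True}
                for s in (1.0, 7.0, 15.0, 25.0)]
        t = stratify_calls(rows)
        filled = t["duplication_ppv"].dropna()
        assert (filled == 100.0).all()

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            stratify_calls([{"size_mb": -2.0, "kind": "deletion",
                             "true_positive": True}])


class TestPearsonChi2:
    @pytest.mark.parametrize("table,expected", [
        ([[19, 12_866], [262, 55_441]], 26.74),  # screen-positive rates
        ([[4, 10], [88, 59]], 5.11),             # era PPV contrast
        ([[10, 90], [20, 180]], 0.00),           # proportional rows
    ])
    def test_statistics(self, table, expected):
        stat, df, p = pearson_chi2(table)
        assert stat == expected and df == 1
        assert 0.0 <= p <= 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 10]])

    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_formula(self, cells):
        """Oracle: Sum (O-E)^2/E with expected counts from the marginals."""
        obs = np.array(cells, dtype=float).reshape(2, 2)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        oracle = ((obs - expected) ** 2 / expected).sum()
        stat, _, _ = pearson_chi2(obs)
        assert stat == round(oracle, 2)


class TestSummaries:
    def test_mean_sd_closed_form(self):
        out = summarize_cohort({"x": [10, 20]})
        assert out["x"]["mean"] == 15
        assert out["x"]["sd"] == pytest.approx(7.0711, abs=1e-4)
        assert summarize_cohort({"y": [5, 5, 5]})["y"]["sd"] == 0.0

    def test_categorical_percentages(self):
        out = summarize_cohort({"era": ["pre"] * 3 + ["post"] * 7})
        assert out["era"]["post"] == 70.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort({})


class TestOutcomeLedger:
    def test_deterministic_single_branch(self):
        ledger = build_outcome_ledger(
            {"tp": 10}, {"tp": {"tp_termination": 1.0, "tp_continue": 0.0}})
        assert ledger["tp_termination"] == 10 and ledger["tp_continue"] == 0

    def test_termination_share_matches_expectation(self):
        """92 confirmed cases with termination probability 80/92: the mean
        allocation over seeds is ~80 within 3 SE."""
        p = 80 / 92
        draws = [build_outcome_ledger(
            {"tp": 92}, {"tp": {"tp_termination": p, "tp_continue": 1 - p}},
            rng=seed)["tp_termination"] for seed in range(100)]
        se = np.sqrt(92 * p * (1 - p))
        assert abs(np.mean(draws) - 80) < 3 * se / np.sqrt(len(draws))

    def test_empty_cohort_all_zero(self):
        ledger = build_outcome_ledger(
            {"tp": 0}, {"tp": {"tp_termination": 0.5, "tp_continue": 0.5}},
            rng=1)
        assert ledger["tp_termination"] == 0 and ledger["tp_continue"] == 0

    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            OutcomeLedger({"tp": 10, "tp_termination": 5, "tp_continue": 3})

    @given(seed=st.integers(0, 1_000), n=st.integers(0, 300),
           p=st.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_random_models_conserve_counts(self, seed, n, p):
        ledger = build_outcome_ledger(
            {"diagnosed": n}, {"diagnosed": {"tp": p, "fp": 1 - p}}, rng=seed)
        assert ledger["tp"] + ledger["fp"] == n

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            build_outcome_ledger({"tp": 5},
                                 {"tp": {"tp_termination": 1.2,
                                         "tp_continue": -0.2}}, rng=0)
        with pytest.raises(ValueError):
            build_outcome_ledger({"tp": 5},
                                 {"tp": {"tp_termination": 0.5,
                                         "tp_continue": 0.1}}, rng=0)


def test_screening_table_invariants():
    t = ScreeningTable(tp=92, fp=69, screened=68_588, positives=281)
    assert t.diagnosed == 161
    with pytest.raises(ValueError):
        ScreeningTable(tp=-1, fp=0)
    with pytest.raises(ValueError):
        ScreeningTable(tp=1, fp=1, screened=10, positives=11)
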