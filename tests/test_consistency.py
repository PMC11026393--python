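"""Cross-method metric tables, Spearman matrices and the outlier ledger."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nucitox.consistency import (
    associate_bias_with_mito,
    auc_ratio,
    build_metric_table,
    flag_outliers,
    log2_deviation,
    pairwise_spearman_matrix,
)
from nucitox.stats import midranks

METHODS = ["XTT", "TB", "Hoechst", "H2B"]


def make_rows(methods=METHODS, lines=("A", "B", "C", "D"), drugs=None, seed=0):
    drugs = drugs or [f"d{i}" for i in range(6)]
    rng = np.random.default_rng(seed)
    recs = []
    for m, l, d in itertools.product(methods, lines, drugs):
        ic50 = float(10 ** rng.uniform(-1, 1))
        recs.append((m, l, d, ic50, False, ic50 * rng.uniform(20, 80) / ic50))
    df = pd.DataFrame(recs, columns=["method", "cell_line", "drug", "ic50_uM",
                                     "ic50_censored", "auc"])
    return df


class TestMetricTable:
    def test_full_grid_row_count(self):
        table = build_metric_table(make_rows())
        assert len(table) == 4 * 4 * 6

    def test_duplicate_key_rejected(self):
        rows = make_rows()
        with pytest.raises(ValueError, match="duplicate"):
            build_metric_table(pd.concat([rows, rows.iloc[[0]]]))

    def test_missing_rows_simply_absent(self):
        rows = make_rows().iloc[1:]
        table = build_metric_table(rows)
        assert len(table) == 95


class TestSpearmanMatrix:
    def test_proportional_methods_correlate_perfectly(self):
        rows = make_rows(methods=["TB"])
        doubled = rows.assign(method="XTT", ic50_uM=rows.ic50_uM * 2, auc=rows.auc * 2)
        table = build_metric_table(pd.concat([rows, doubled]))
        rho, p, n = pairwise_spearman_matrix(table, "auc")
        assert rho.loc["TB", "XTT"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self):
        rho, p, n = pairwise_spearman_matrix(build_metric_table(make_rows()), "ic50")
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)

    def test_matches_textbook_rank_formula(self):
        """rho for a permuted method equals 1 - 6*sum(d^2)/(n(n^2-1))."""
        rows = make_rows(methods=["TB"], lines=("A", "B", "C"), drugs=[f"d{i}" for i in range(8)])
        rng = np.random.default_rng(4)
        perm = rows.sample(frac=1.0, random_state=7).reset_index(drop=True)
        shuffled = rows.assign(method="XTT", auc=perm.auc.to_numpy())
        table = build_metric_table(pd.concat([rows, shuffled]))
        rho, _, _ = pairwise_spearman_matrix(table, "auc")
        merged = table.xs("TB", level="method").join(
            table.xs("XTT", level="method"), lsuffix="_a", rsuffix="_b"
        )
        d = midranks(merged["auc_a"]) - midranks(merged["auc_b"])
        n = len(merged)
        expected = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
        assert rho.loc["TB", "XTT"] == pytest.approx(expected)

    def test_censored_ic50_ranked_on_top(self):
        rows = make_rows(methods=["TB"], lines=("A",), drugs=[f"d{i}" for i in range(6)])
        other = rows.assign(method="XTT")
        # censor the two weakest drugs for XTT only; ordering must survive
        other.loc[other.ic50_uM.nlargest(2).index, "ic50_censored"] = True
        other.loc[other.ic50_censored, "ic50_uM"] = 0.001  # value ignored when censored
        table = build_metric_table(pd.concat([rows, other]))
        rho, _, _ = pairwise_spearman_matrix(table, "ic50")
        assert rho.loc["TB", "XTT"] > 0.8

    def test_insufficient_shared_keys_flagged(self):
        rows = make_rows(lines=("A",), drugs=["d0", "d1", "d2"])
        rho, p, n = pairwise_spearman_matrix(build_metric_table(rows), "auc")
        assert np.isnan(rho.loc["TB", "XTT"]) and n.loc["TB", "XTT"] == 3


class TestDeviationLedger:
    def _table(self, ic50s, lines=("A", "B", "C")):
        rows = pd.DataFrame({
            "method": "XTT", "cell_line": list(lines), "drug": "d0",
            "ic50_uM": ic50s, "ic50_censored": False, "auc": 50.0,
        })
        return build_metric_table(rows)

    def test_geometric_mean_reference(self):
        ledger = log2_deviation(self._table([1.0, 2.0, 4.0]))
        assert sorted(ledger["log2_dev"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_equal_values_zero_deviation(self):
        ledger = log2_deviation(self._table([3.0, 3.0, 3.0]))
        assert ledger["log2_dev"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])

    def test_scale_invariance(self):
        a = log2_deviation(self._table([1.0, 2.0, 4.0]))
        b = log2_deviation(self._table([10.0, 20.0, 40.0]))
        assert a["log2_dev"].to_numpy() == pytest.approx(b["log2_dev"].to_numpy())

    def test_censored_excluded_and_flagged(self):
        rows = pd.DataFrame({
            "method": "XTT", "cell_line": ["A", "B", "C"], "drug": "d0",
            "ic50_uM": [1.0, 4.0, 99.0], "ic50_censored": [False, False, True],
            "auc": 50.0,
        })
        ledger = log2_deviation(build_metric_table(rows))
        assert ledger.loc[ledger.cell_line == "C", "censored"].item()
        assert np.isnan(ledger.loc[ledger.cell_line == "C", "log2_dev"].item())
        # reference from the two numeric values only: gmean(1, 4) = 2
        assert ledger.loc[ledger.cell_line == "A", "log2_dev"].item() == pytest.approx(-1.0)


class TestOutlierFlags:
    def _grid(self, special=None):
        recs = []
        for m, l, d in itertools.product(METHODS, "ABCD", ["d0", "d1"]):
            v = 2.0
            if special and (m, l, d) == special:
                v = 8.0  # fourfold off the others
            recs.append((m, l, d, v, False, 50.0))
        return build_metric_table(pd.DataFrame(
            recs, columns=["method", "cell_line", "drug", "ic50_uM", "ic50_censored", "auc"]
        ))

    def test_agreement_yields_no_flags(self):
        flags = flag_outliers(log2_deviation(self._grid()))
        assert flags.empty

    def test_single_fourfold_triple_flagged(self):
        flags = flag_outliers(log2_deviation(self._grid(special=("XTT", "B", "d0"))))
        assert len(flags) == 1
        row = flags.iloc[0]
        assert (row.method, row.cell_line, row.drug) == ("XTT", "B", "d0")
        assert row.flag_fourfold == (abs(row.excess) > 2)

    def test_infinite_threshold_flags_nothing(self):
        ledger = log2_deviation(self._grid(special=("XTT", "B", "d0")))
        assert flag_outliers(ledger, threshold_log2=np.inf).empty


class TestAUCRatios:
    def _table(self, xtt_auc, h2b_auc, drugs=("d0",)):
        recs = []
        for d, xa, ha in zip(drugs, np.atleast_1d(xtt_auc), np.atleast_1d(h2b_auc)):
            recs.append(("XTT", "A", d, 1.0, False, xa))
            recs.append(("H2B", "A", d, 1.0, False, ha))
        return build_metric_table(pd.DataFrame(
            recs, columns=["method", "cell_line", "drug", "ic50_uM", "ic50_censored", "auc"]
        ))

    def test_basic_ratios(self):
        assert auc_ratio(self._table(80.0, 40.0))["d0"] == pytest.approx(2.0)
        assert auc_ratio(self._table(50.0, 50.0))["d0"] == pytest.approx(1.0)

    def test_zero_denominator_dropped(self):
        ratios = auc_ratio(self._table([80.0, 60.0], [0.0, 30.0], drugs=("d0", "d1")))
        assert "d0" not in ratios.index and ratios["d1"] == pytest.approx(2.0)

    def test_association_with_planted_mechanism(self):
        """phi drives both the AUC ratio and normalized mito activity."""
        rng = np.random.default_rng(11)
        phi = np.linspace(0.5, 2.5, 15)
        ratios = pd.Series(phi * np.exp(rng.normal(0, 0.05, 15)),
                           index=[f"d{i}" for i in range(15)])
        activity = pd.Series(100 * phi * np.exp(rng.normal(0, 0.05, 15)),
                             index=ratios.index)
        res = associate_bias_with_mito(ratios, activity)
        assert res.statistic > 0 and res.p_value < 0.05
        # shuffled pairing destroys the association most of the time
        null_ps = []
        for i in range(50):
            perm = pd.Series(activity.sample(frac=1.0, random_state=i).to_numpy(),
                             index=activity.index)
            null_ps.append(associate_bias_with_mito(ratios, perm).p_value)
        assert np.mean(np.asarray(null_ps) > 0.05) >= 0.9

    def test_minimum_drug_count(self):
        with pytest.raises(ValueError):
            associate_bias_with_mito(pd.Series([1, 2], index=["a", "b"]),
                                     pd.Series([1, 2], index=["a", "b"]))
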