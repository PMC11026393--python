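"""Cross-method agreement analysis of dose-response metrics.

Takes per-(method, cell line, drug) IC50/AUC rows and asks: do different
viability readouts rank drug sensitivities the same way? Three tools:

* pairwise Spearman matrices between methods, over shared (cell line, drug)
  keys, with censored IC50s ("> c_max") ranked above every numeric value and
  tied among themselves;
* a log2-deviation ledger — within a method, each IC50 is divided by the
  geometric mean IC50 of that drug across cell lines; a deviation beyond
  twofold (|log2| > 1) flags a method/cell-line/drug outlier, beyond
  fourfold (|log2| > 2) gets an extra tag;
* XTT/H2B AUC ratios per drug (> 1 means the metabolic assay over-reports
  viability) and their rank association with drug-induced normalized
  mitochondria activity.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .stats import TestResult, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "build_metric_table",
    "pairwise_spearman_matrix",
    "log2_deviation",
    "flag_outliers",
    "auc_ratio",
    "associate_bias_with_mito",
]

KEY = ["method", "cell_line", "drug"]


def build_metric_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Validate and index dose metrics by (method, cell_line, drug).

    Requires columns method, cell_line, drug, ic50_uM, ic50_censored, auc.
    Duplicate keys are an error; missing combinations are simply absent and
    later comparisons use pairwise-complete keys.
    """
    required = set(KEY + ["ic50_uM", "ic50_censored", "auc"])
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if rows.duplicated(subset=KEY).any():
        dup = rows[rows.duplicated(subset=KEY, keep=False)][KEY].iloc[0].tolist()
        raise ValueError(f"duplicate metric row for key {tuple(dup)}")
    return rows.set_index(KEY).sort_index()


def _rank_values(sub: pd.DataFrame, metric: str) -> np.ndarray:
    """Metric values for ranking; censored IC50s become +inf (top ranks, tied)."""
    vals = sub[metric].to_numpy(dtype=float)
    if metric == "ic50_uM":
        vals = np.where(sub["ic50_censored"].to_numpy(dtype=bool), np.inf, vals)
    return vals


def pairwise_spearman_matrix(table: pd.DataFrame, metric: str = "auc"):
    """Symmetric per-method-pair Spearman (rho, p) over shared keys.

    Entries with fewer than 4 shared (cell_line, drug) keys are flagged as
    insufficient (NaN). Diagonal is 1. Returns (rho_df, p_df, n_df).
    """
    if metric not in ("auc", "ic50_uM", "ic50"):
        raise ValueError("metric must be 'auc' or 'ic50'")
    metric = "ic50_uM" if metric == "ic50" else metric
    methods = sorted(table.index.get_level_values("method").unique())
    rho = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    pmat = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods, columns=methods)
    nmat = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for a, b in itertools.combinations(methods, 2):
        ta = table.xs(a, level="method")
        tb = table.xs(b, level="method")
        shared = ta.index.intersection(tb.index)
        nmat.loc[a, b] = nmat.loc[b, a] = len(shared)
        if len(shared) < 4:
            rho.loc[a, b] = rho.loc[b, a] = np.nan
            pmat.loc[a, b] = pmat.loc[b, a] = np.nan
            logger.info("pair (%s, %s): only %d shared keys", a, b, len(shared))
            continue
        va = _rank_values(ta.loc[shared], metric)
        vb = _rank_values(tb.loc[shared], metric)
        # replace inf by a finite value above the max so midranks apply
        va = _cap_inf(va)
        vb = _cap_inf(vb)
        res = spearman_rho(va, vb)
        rho.loc[a, b] = rho.loc[b, a] = res.statistic
        pmat.loc[a, b] = pmat.loc[b, a] = res.p_value
    return rho, pmat, nmat


def _cap_inf(v: np.ndarray) -> np.ndarray:
    if np.isinf(v).any():
        finite = v[np.isfinite(v)]
        top = (finite.max() if finite.size else 0.0) + 1.0
        v = np.where(np.isinf(v), top, v)
    return v


def log2_deviation(
    table: pd.DataFrame, metric: str = "ic50_uM", mean: str = "geometric"
) -> pd.DataFrame:
    """Per-row log2 deviation from the drug's cross-cell-line mean IC50.

    Within each (method, drug), the reference is the geometric mean of the
    numeric IC50s across cell lines (arithmetic optionally); censored values
    are excluded from the reference and flagged in the output. Groups with
    fewer than 2 numeric cell lines yield NaN deviations.
    """
    if mean not in ("geometric", "arithmetic"):
        raise ValueError("mean must be 'geometric' or 'arithmetic'")
    recs = []
    for (method, drug), sub in table.groupby(level=["method", "drug"]):
        vals = sub[metric].to_numpy(dtype=float)
        cens = sub["ic50_censored"].to_numpy(dtype=bool) if metric == "ic50_uM" else np.zeros(len(sub), bool)
        numeric = vals[~cens]
        if numeric.size >= 2:
            ref = float(np.exp(np.mean(np.log(numeric)))) if mean == "geometric" else float(numeric.mean())
        else:
            ref = np.nan
        for (m, line, d), v, c in zip(sub.index, vals, cens):
            dev = np.nan if (c or not np.isfinite(ref)) else float(np.log2(v / ref))
            recs.append((method, line, drug, v, bool(c), ref, dev))
    return pd.DataFrame(
        recs, columns=["method", "cell_line", "drug", metric, "censored",
                       "reference", "log2_dev"],
    )


def flag_outliers(
    ledger: pd.DataFrame, threshold_log2: float = 1.0, relative_to: str = "drug_mean"
) -> pd.DataFrame:
    """Flag method/cell-line/drug triples deviating beyond twofold.

    ``relative_to="drug_mean"`` (default) flags |log2_dev| > threshold — the
    deviation of a cell line's IC50 from the drug's cross-cell-line mean
    within one method. ``relative_to="consensus"`` first subtracts, per
    (cell_line, drug), the mean deviation across methods, isolating
    method-specific disagreement. Fourfold cases (> 2 on the same scale) get
    ``flag_fourfold``.
    """
    df = ledger.copy()
    if relative_to == "drug_mean":
        df["excess"] = df["log2_dev"]
    elif relative_to == "consensus":
        consensus = df.groupby(["cell_line", "drug"])["log2_dev"].transform("mean")
        df["excess"] = df["log2_dev"] - consensus
    else:
        raise ValueError("relative_to must be 'drug_mean' or 'consensus'")
    df["flag_twofold"] = df["excess"].abs() > threshold_log2
    df["flag_fourfold"] = df["excess"].abs() > 2.0
    return df[df["flag_twofold"]].reset_index(drop=True)


def auc_ratio(
    table: pd.DataFrame,
    numerator_method: str = "XTT",
    denominator_method: str = "H2B",
) -> pd.Series:
    """Per-drug ratio of AUCs between two methods (cell-line averaged).

    A ratio above 1 means the numerator assay (XTT by default) reports more
    surviving signal than the imaging count over the same dose range. Drugs
    with zero denominator AUC are dropped with a log entry.
    """
    num = table.xs(numerator_method, level="method")["auc"].groupby("drug").mean()
    den = table.xs(denominator_method, level="method")["auc"].groupby("drug").mean()
    shared = num.index.intersection(den.index)
    out = {}
    for d in shared:
        if den[d] == 0:
            logger.info("drug %s: denominator AUC is 0, ratio undefined", d)
            continue
        out[d] = float(num[d] / den[d])
    return pd.Series(out, name="auc_ratio").sort_index()


def associate_bias_with_mito(
    ratios: pd.Series, mito_activity: pd.Series
) -> TestResult:
    """Spearman association of XTT/H2B AUC ratios with normalized
    mitochondria activity across drugs (>= 5 drugs with both values)."""
    joined = pd.concat([ratios, mito_activity], axis=1, join="inner").dropna()
    if len(joined) < 5:
        raise ValueError("need >= 5 drugs with both quantities")
    return spearman_rho(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
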