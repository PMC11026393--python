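"""Plate-level orchestration: raw readout table -> viability -> dose metrics.

Glues the dose-response primitives to the long-format plate table emitted by
the generator (or read from ``plate.csv``): imaging fields are averaged per
replicate, XTT blanks are subtracted, every value is normalized to the
DMSO (concentration 0) control of its method x cell line x drug series, and
each series is reduced to IC50 (with censoring) and AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose import compute_auc, fit_4pl, normalize_to_control
from .synthetic import BLANK_DRUG

__all__ = ["plate_viability", "dose_metrics_table"]


def plate_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent viability per (method, cell_line, drug, conc, replicate).

    Imaging methods (multiple fields per well) are field-averaged first.
    XTT wells are blank-corrected with the plate's medium+reagent wells
    (drug == "BLANK"). The control for each series is its own concentration-0
    rows, averaged across replicates.
    """
    df = plate[plate["drug"] != BLANK_DRUG]
    blanks = plate[(plate["drug"] == BLANK_DRUG) & (plate["method"] == "XTT")]
    well = (
        df.groupby(["method", "cell_line", "drug", "conc_uM", "replicate"], sort=True)
        ["value"].mean().reset_index()
    )
    out = []
    for (method, line, drug), sub in well.groupby(["method", "cell_line", "drug"]):
        control = sub.loc[sub["conc_uM"] == 0, "value"].to_numpy()
        if control.size == 0:
            raise ValueError(f"no control (conc 0) rows for {(method, line, drug)}")
        blank_vals = None
        if method == "XTT":
            b = blanks.loc[blanks["cell_line"] == line, "value"].to_numpy()
            blank_vals = b if b.size else None
        treated = sub[sub["conc_uM"] > 0]
        v = normalize_to_control(treated["value"].to_numpy(), control, blank_vals)
        res = treated[["conc_uM", "replicate"]].copy()
        res.insert(0, "drug", drug)
        res.insert(0, "cell_line", line)
        res.insert(0, "method", method)
        res["viability_pct"] = v
        out.append(res)
    return pd.concat(out, ignore_index=True)


def dose_metrics_table(viability: pd.DataFrame) -> pd.DataFrame:
    """Fit 4PL and compute AUC per (method, cell_line, drug) series."""
    rows = []
    for (method, line, drug), sub in viability.groupby(["method", "cell_line", "drug"]):
        c = sub["conc_uM"].to_numpy(dtype=float)
        v = sub["viability_pct"].to_numpy(dtype=float)
        fit = fit_4pl(c, v)
        auc = compute_auc(c, v)
        rows.append((method, line, drug, fit.ic50, fit.censored, fit.hill,
                     fit.rss, auc, fit.status))
    return pd.DataFrame(
        rows,
        columns=["method", "cell_line", "drug", "ic50_uM", "ic50_censored",
                 "hill", "rss", "auc", "status"],
    )
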