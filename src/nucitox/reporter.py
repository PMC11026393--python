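"""Transgene-fluorescence shift detection (reporter intensity volcano).

Some drugs change the fluorescence of a constitutively expressed nuclear
reporter (e.g. HDAC inhibitors de-repressing a viral promoter driving
H2B-mRuby). The analysis: per-nucleus median intensities are normalized to
the DMSO grand mean, collapsed to per-image means (nuclei within an image
are pseudoreplicates), compared to DMSO by Mann-Whitney per drug x
concentration, and corrected across the panel by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = ["VolcanoRow", "normalize_reporter", "test_shift_per_drug", "volcano_table", "volcano"]

DMSO = "DMSO"


@dataclass
class VolcanoRow:
    drug: str
    concentration: float
    effect_log2: float
    p: float
    q: float = float("nan")
    significant: bool = False


def _require_dmso(table: pd.DataFrame, dmso_label: str):
    if not (table["drug"] == dmso_label).any():
        raise ValueError(f"no {dmso_label} rows in table")


def normalize_reporter(table: pd.DataFrame, dmso_label: str = DMSO) -> pd.DataFrame:
    """Divide every per-nucleus median intensity by the DMSO grand mean.

    The reference is the mean over all DMSO nuclei on the plate, so the DMSO
    normalized mean is 1 by construction and the normalization cancels any
    global exposure scaling.
    """
    _require_dmso(table, dmso_label)
    ref = table.loc[table["drug"] == dmso_label, "median_intensity"].mean()
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("DMSO reference mean must be positive")
    out = table.copy()
    out["normalized_intensity"] = out["median_intensity"] / ref
    return out


def _image_means(table: pd.DataFrame, drug: str, concentration=None) -> np.ndarray:
    sel = table["drug"] == drug
    if concentration is not None and "conc_uM" in table.columns:
        sel &= table["conc_uM"] == concentration
    col = "normalized_intensity" if "normalized_intensity" in table.columns else "median_intensity"
    return table[sel].groupby("image_id")[col].mean().to_numpy()


def test_shift_per_drug(
    table: pd.DataFrame,
    drug: str,
    concentration: float | None = None,
    dmso_label: str = DMSO,
) -> VolcanoRow | None:
    """Mann-Whitney of per-image means vs DMSO, effect as log2 mean ratio.

    Groups with fewer than 3 images are skipped (returns None, logged): the
    per-image design is underpowered below that.
    """
    _require_dmso(table, dmso_label)
    treated = _image_means(table, drug, concentration)
    control = _image_means(table, dmso_label)
    if treated.size < 3 or control.size < 3:
        logger.info("skipping %s @ %s: < 3 images per group", drug, concentration)
        return None
    res = mann_whitney_u(treated, control)
    effect = float(np.log2(treated.mean() / control.mean()))
    return VolcanoRow(drug, float(concentration) if concentration is not None else np.nan,
                      effect, res.p_value)


def volcano_table(rows: list[VolcanoRow], alpha: float = 0.05) -> pd.DataFrame:
    """Apply BH FDR across all rows and call significance at q < alpha."""
    if not rows:
        raise ValueError("no volcano rows")
    q = bh_fdr([r.p for r in rows])
    recs = []
    for r, qi in zip(rows, q):
        recs.append((r.drug, r.concentration, r.effect_log2, r.p, float(qi), bool(qi < alpha)))
    return pd.DataFrame(
        recs, columns=["drug", "conc_uM", "effect_log2", "p", "q", "significant"]
    )


def volcano(table: pd.DataFrame, alpha: float = 0.05, dmso_label: str = DMSO) -> pd.DataFrame:
    """Full panel: normalize, test every (drug, concentration) group, FDR."""
    norm = normalize_reporter(table, dmso_label)
    rows = []
    has_conc = "conc_uM" in norm.columns
    groups = (
        norm.loc[norm["drug"] != dmso_label]
        .groupby(["drug", "conc_uM"] if has_conc else ["drug"])
        .groups.keys()
    )
    for key in groups:
        drug, conc = key if has_conc else (key if isinstance(key, str) else key[0], None)
        row = test_shift_per_drug(norm, drug, conc, dmso_label)
        if row is not None:
            rows.append(row)
    return volcano_table(rows, alpha)
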