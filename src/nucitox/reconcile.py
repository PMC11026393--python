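"""Two-scale cell-mask reconciliation and per-cell mitochondria metrics.

Segmenting a mixed-size culture at a single expected diameter fails in one
direction or the other: a small-diameter pass shatters genuinely large cells
into fragments, a large-diameter pass merges groups of small cells into one
blob. The reconciliation here therefore runs on four object sets — small
cells, big cells, small nuclei, big nuclei (defaults 35 px and 150 px
expected cell diameters) — and decides, per big cell, whether it is a real
large cell or a misidentified cluster of small cells.

Rules, in pipeline order:

1. each cell (either scale) must contain a same-scale nucleus: a nucleus
   qualifies when more than half its area lies inside the cell, and the
   nucleus with the largest inside-fraction is matched (ties to the lowest
   nucleus label); cells without a matched nucleus are dropped;
2. small cells that touch no big cell are kept outright;
3. a small cell is "inside" a big cell when more than half its area overlaps
   the big footprint; if at least ``min_small_cells`` retained small cells
   are inside a big cell and jointly cover at least fraction ``T`` of its
   area, the big cell is judged to be a cluster and discarded in favour of
   those small cells; otherwise the big cell is kept and the small cells
   inside it are discarded;
4. partially overlapping survivors keep disjoint pixel sets: contested
   pixels stay with the object retained earlier in this order (small before
   big).

Mitochondria regions (e.g. TMRE-segmented blobs) are then assigned to the
reconciled cell with maximal pixel overlap, and per-cell activity metrics
are computed: integrated intensity over assigned mitochondria pixels ("total
mitochondria activity") and that integral divided by the mitochondria area
("normalized mitochondria activity").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleMasks",
    "CellObject",
    "CellMetrics",
    "filter_cells_by_nucleus",
    "resolve_big_cells",
    "reconcile",
    "assign_mitochondria",
    "compute_cell_metrics",
    "summarize_image",
]


@dataclass(frozen=True)
class ScaleMasks:
    """The four label masks produced by two-diameter segmentation."""

    small_cells: np.ndarray
    big_cells: np.ndarray
    small_nuclei: np.ndarray
    big_nuclei: np.ndarray
    small_diameter_px: float = 35.0
    big_diameter_px: float = 150.0

    def __post_init__(self):
        shapes = {
            np.asarray(m).shape
            for m in (self.small_cells, self.big_cells, self.small_nuclei, self.big_nuclei)
        }
        if len(shapes) != 1:
            raise ValueError("all four masks must share a shape")


@dataclass
class CellObject:
    cell_id: int
    scale: str  # "small" | "big"
    source_label: int
    nucleus_label: int
    area_px: int


@dataclass
class CellMetrics:
    cell_id: int
    cell_area_px: int
    mito_area_px: int
    integrated_mito_intensity: float
    normalized_mito_activity: float  # NaN when mito_area_px == 0


def _overlap_table(a: np.ndarray, b: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel overlap counts between non-zero labels of two masks."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    sel = (a != 0) & (b != 0)
    if not sel.any():
        return {}
    pairs = a[sel].astype(np.int64) * (int(b.max()) + 1) + b[sel]
    vals, counts = np.unique(pairs, return_counts=True)
    base = int(b.max()) + 1
    return {(int(v // base), int(v % base)): int(c) for v, c in zip(vals, counts)}


def _areas(mask: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(np.asarray(mask), return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


def filter_cells_by_nucleus(cells, nuclei) -> dict[int, int]:
    """Map each retained cell label to its matched nucleus label.

    A cell is retained iff at least one nucleus has > 50% of its area inside
    the cell; among qualifying nuclei the one with the largest inside
    fraction wins (ties to the lowest nucleus label).
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus masks must share a shape")
    nuc_areas = _areas(nuclei)
    overlaps = _overlap_table(cells, nuclei)
    best: dict[int, tuple[float, int]] = {}
    for (cell, nuc), count in overlaps.items():
        frac = count / nuc_areas[nuc]
        if frac <= 0.5:
            continue
        cur = best.get(cell)
        if cur is None or frac > cur[0] + 1e-12 or (abs(frac - cur[0]) <= 1e-12 and nuc < cur[1]):
            best[cell] = (frac, nuc)
    return {cell: nuc for cell, (_, nuc) in sorted(best.items())}


def resolve_big_cells(
    scales: ScaleMasks,
    small_map: dict[int, int],
    big_map: dict[int, int],
    cluster_area_fraction: float = 0.5,
    min_small_cells: int = 2,
) -> tuple[list[CellObject], np.ndarray]:
    """Reconcile nucleus-filtered small and big cell masks.

    ``small_map`` / ``big_map`` must come from :func:`filter_cells_by_nucleus`
    on the same-scale nuclei; passing labels absent from the maps is an
    error (the rule only applies to nucleus-validated cells). Returns the
    retained :class:`CellObject` list (small cells first, each with a fresh
    unique ``cell_id``) and the final disjoint label mask of those ids.
    """
    small = np.asarray(scales.small_cells)
    big = np.asarray(scales.big_cells)
    small_labels = set(_areas(small))
    big_labels = set(_areas(big))
    if not set(small_map) <= small_labels or not set(big_map) <= big_labels:
        raise ValueError("nucleus map refers to labels absent from the mask")
    if small_labels - set(small_map) or big_labels - set(big_map):
        raise ValueError(
            "masks contain cells without a nucleus match; run filter_cells_by_nucleus "
            "and remove unmatched labels first"
        )
    small_areas = _areas(small)
    big_areas = _areas(big)
    overlaps = _overlap_table(small, big)

    inside_of: dict[int, int] = {}  # small label -> big label it is inside
    touched: dict[int, set[int]] = {}  # small label -> big labels it touches
    for (s, b), count in overlaps.items():
        touched.setdefault(s, set()).add(b)
        if count > 0.5 * small_areas[s]:
            inside_of[s] = b  # > 50% overlap is unique per small cell

    kept_small: set[int] = {s for s in small_map if s not in touched}
    discarded_small: set[int] = set()
    kept_big: set[int] = set()
    for b in sorted(big_map):
        members = sorted(s for s, bb in inside_of.items() if bb == b)
        cover = sum(overlaps[(s, b)] for s in members) / big_areas[b]
        if len(members) >= min_small_cells and cover >= cluster_area_fraction:
            kept_small.update(members)
            logger.info(
                "big cell %d judged a cluster of %d small cells (cover %.2f) and discarded",
                b, len(members), cover,
            )
        else:
            kept_big.add(b)
            discarded_small.update(members)
    # small cells partially overlapping a big cell but not inside any are kept
    for s in small_map:
        if s in kept_small or s in discarded_small or s not in touched:
            continue
        if s not in inside_of:
            kept_small.add(s)

    final = np.zeros(small.shape, dtype=np.int32)
    objects: list[CellObject] = []
    next_id = 1
    # paint big first, small second: contested pixels end up with the small
    # cell, the object retained earlier in pipeline order
    id_of: dict[tuple[str, int], int] = {}
    for s in sorted(kept_small):
        id_of[("small", s)] = next_id
        next_id += 1
    for b in sorted(kept_big):
        id_of[("big", b)] = next_id
        next_id += 1
    for b in sorted(kept_big):
        final[big == b] = id_of[("big", b)]
    for s in sorted(kept_small):
        final[small == s] = id_of[("small", s)]
    final_areas = _areas(final)
    for s in sorted(kept_small):
        cid = id_of[("small", s)]
        objects.append(CellObject(cid, "small", s, small_map[s], final_areas.get(cid, 0)))
    for b in sorted(kept_big):
        cid = id_of[("big", b)]
        objects.append(CellObject(cid, "big", b, big_map[b], final_areas.get(cid, 0)))
    return objects, final


def reconcile(
    scales: ScaleMasks,
    cluster_area_fraction: float = 0.5,
    min_small_cells: int = 2,
) -> tuple[list[CellObject], np.ndarray]:
    """Nucleus-filter both scales, drop unmatched cells, then reconcile."""
    small_map = filter_cells_by_nucleus(scales.small_cells, scales.small_nuclei)
    big_map = filter_cells_by_nucleus(scales.big_cells, scales.big_nuclei)
    small = np.asarray(scales.small_cells).copy()
    big = np.asarray(scales.big_cells).copy()
    small[~np.isin(small, list(small_map) or [0])] = 0
    big[~np.isin(big, list(big_map) or [0])] = 0
    filtered = ScaleMasks(
        small, big, scales.small_nuclei, scales.big_nuclei,
        scales.small_diameter_px, scales.big_diameter_px,
    )
    return resolve_big_cells(
        filtered, small_map, big_map, cluster_area_fraction, min_small_cells
    )


def assign_mitochondria(cell_mask, mito_mask) -> dict[int, int]:
    """Assign each mitochondria region to the cell with maximal pixel overlap.

    Ties go to the lowest cell id; regions overlapping no cell are left out
    of the mapping entirely (and of all downstream metrics).
    """
    cell_mask = np.asarray(cell_mask)
    mito_mask = np.asarray(mito_mask)
    if cell_mask.shape != mito_mask.shape:
        raise ValueError("masks must share a shape")
    overlaps = _overlap_table(mito_mask, cell_mask)
    best: dict[int, tuple[int, int]] = {}
    for (region, cell), count in overlaps.items():
        cur = best.get(region)
        if cur is None or count > cur[0] or (count == cur[0] and cell < cur[1]):
            best[region] = (count, cell)
    return {region: cell for region, (_, cell) in sorted(best.items())}


def compute_cell_metrics(
    cells: list[CellObject],
    cell_mask,
    assignment: dict[int, int],
    mito_mask,
    mito_intensity_img,
) -> list[CellMetrics]:
    """Per-cell mitochondria area, integrated and area-normalized intensity.

    A cell's mitochondria pixels are the pixels of its assigned regions that
    lie inside the cell footprint (so mito_area never exceeds cell area).
    Cells with no assigned mitochondria report integrated 0 and an undefined
    (NaN) normalized activity.
    """
    cell_mask = np.asarray(cell_mask)
    mito_mask = np.asarray(mito_mask)
    intensity = np.asarray(mito_intensity_img, dtype=float)
    if not (cell_mask.shape == mito_mask.shape == intensity.shape):
        raise ValueError("masks and intensity image must share a shape")
    max_cell = int(cell_mask.max())
    # region -> cell lookup applied pixel-wise
    lut = np.zeros(int(mito_mask.max()) + 1, dtype=np.int64)
    for region, cell in assignment.items():
        lut[region] = cell
    owner = np.where(mito_mask > 0, lut[mito_mask], 0)
    counted = (owner > 0) & (cell_mask == owner)
    owners = owner[counted]
    areas = np.bincount(owners, minlength=max_cell + 1)
    integ = np.bincount(owners, weights=intensity[counted], minlength=max_cell + 1)
    out = []
    for c in cells:
        a = int(areas[c.cell_id]) if c.cell_id <= max_cell else 0
        s = float(integ[c.cell_id]) if c.cell_id <= max_cell else 0.0
        out.append(
            CellMetrics(
                cell_id=c.cell_id,
                cell_area_px=c.area_px,
                mito_area_px=a,
                integrated_mito_intensity=s,
                normalized_mito_activity=(s / a) if a > 0 else float("nan"),
            )
        )
    return out


def summarize_image(metrics: list[CellMetrics]) -> dict:
    """Per-image means of the cell metrics (the unit used for testing).

    Cells with undefined normalized activity are excluded from the
    normalized mean but still count toward the area means and n_cells.
    """
    if not metrics:
        raise ValueError("no cells to summarize")
    cell_area = float(np.mean([m.cell_area_px for m in metrics]))
    mito_area = float(np.mean([m.mito_area_px for m in metrics]))
    integrated = float(np.mean([m.integrated_mito_intensity for m in metrics]))
    norm_vals = [
        m.normalized_mito_activity
        for m in metrics
        if not np.isnan(m.normalized_mito_activity)
    ]
    normalized = float(np.mean(norm_vals)) if norm_vals else float("nan")
    return {
        "n_cells": len(metrics),
        "mean_cell_area": cell_area,
        "mean_mito_area": mito_area,
        "mean_integrated": integrated,
        "mean_normalized": normalized,
    }
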