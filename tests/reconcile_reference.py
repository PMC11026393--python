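"""Brute-force reference for two-scale mask reconciliation, plus an
enumerated configuration suite.

The reference implements the documented reconciliation rule with plain
Python sets and loops — no shared code with the vectorized implementation —
so agreement between the two is meaningful. The configuration generator
enumerates small/big cell-nucleus layouts on a 12x12 grid.
"""

from __future__ import annotations

import itertools

import numpy as np


def _pixels(mask, label):
    ys, xs = np.nonzero(np.asarray(mask) == label)
    return set(zip(ys.tolist(), xs.tolist()))


def reference_filter(cells, nuclei):
    """Cell -> nucleus matching by literal pixel-set arithmetic."""
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    out = {}
    cell_labels = sorted(set(cells.ravel().tolist()) - {0})
    nuc_labels = sorted(set(nuclei.ravel().tolist()) - {0})
    for c in cell_labels:
        cp = _pixels(cells, c)
        best = None
        for nl in nuc_labels:
            np_ = _pixels(nuclei, nl)
            frac = len(cp & np_) / len(np_)
            if frac > 0.5 and (best is None or frac > best[0] + 1e-12):
                best = (frac, nl)
        if best is not None:
            out[c] = best[1]
    return out


def reference_resolve(small, big, small_nuclei, big_nuclei, T=0.5, min_small=2):
    """Full reconciliation by sets; returns {(scale, source_label)} retained
    and the final pixel ownership {(y, x): (scale, source_label)}."""
    small = np.asarray(small)
    big = np.asarray(big)
    small_map = reference_filter(small, small_nuclei)
    big_map = reference_filter(big, big_nuclei)
    small_px = {s: _pixels(small, s) for s in small_map}
    big_px = {b: _pixels(big, b) for b in big_map}

    inside = {}
    touches = {s: set() for s in small_map}
    for s, sp in small_px.items():
        for b, bp in big_px.items():
            ov = len(sp & bp)
            if ov:
                touches[s].add(b)
            if ov > 0.5 * len(sp):
                inside[s] = b
    kept_small = {s for s in small_map if not touches[s]}
    kept_big = set()
    discarded_small = set()
    for b in sorted(big_map):
        members = sorted(s for s, bb in inside.items() if bb == b)
        cover = sum(len(small_px[s] & big_px[b]) for s in members) / len(big_px[b])
        if len(members) >= min_small and cover >= T:
            kept_small.update(members)
        else:
            kept_big.add(b)
            discarded_small.update(members)
    for s in small_map:
        if s not in kept_small and s not in discarded_small and s not in inside:
            kept_small.add(s)  # partial overlap, not inside: keep

    ownership = {}
    for b in sorted(kept_big):
        for px in big_px[b]:
            ownership[px] = ("big", b)
    for s in sorted(kept_small):
        for px in small_px[s]:
            ownership[px] = ("small", s)  # small overrides big on contested px
    retained = {("small", s) for s in kept_small} | {("big", b) for b in kept_big}
    return retained, ownership


def _block(mask, label, r0, c0, h, w):
    mask[r0 : r0 + h, c0 : c0 + w] = label


def enumerate_configurations():
    """Yield >= 200 four-mask layouts on a 12x12 grid.

    One big cell (8x8 at (2,2)) whose nucleus may be present, absent or
    straddling; up to three 3x3 small cells placed inside, straddling or
    outside the big footprint, each with its own 2x2 nucleus present/absent.
    """
    small_sites = {
        "in_a": (3, 3), "in_b": (3, 7), "in_c": (7, 3), "in_d": (7, 7),
        "straddle": (1, 5), "outside": (0, 9),
    }
    site_names = list(small_sites)
    layouts = []
    for combo in itertools.chain.from_iterable(
        itertools.combinations(site_names, k) for k in range(4)
    ):
        for big_nuc in ("present", "absent", "straddle"):
            for missing_nuc in range(len(combo) + 1):
                layouts.append((combo, big_nuc, missing_nuc))
    for combo, big_nuc, missing_nuc in layouts:
        small = np.zeros((12, 12), dtype=np.int32)
        big = np.zeros((12, 12), dtype=np.int32)
        small_nuclei = np.zeros((12, 12), dtype=np.int32)
        big_nuclei = np.zeros((12, 12), dtype=np.int32)
        _block(big, 1, 2, 2, 8, 8)
        if big_nuc == "present":
            _block(big_nuclei, 1, 5, 5, 3, 3)
        elif big_nuc == "straddle":
            _block(big_nuclei, 1, 0, 4, 4, 3)  # 50/50: not > 50% inside
        for i, name in enumerate(combo, start=1):
            r, c = small_sites[name]
            _block(small, i, r, c, 3, 3)
            if i != missing_nuc:
                _block(small_nuclei, i, r, c, 2, 2)
        yield small, big, small_nuclei, big_nuclei
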