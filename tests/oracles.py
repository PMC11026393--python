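"""Brute-force image-processing oracles, independent of the implementation."""

from __future__ import annotations

import numpy as np


def sauvola_oracle(img, params) -> np.ndarray:
    """Literal per-pixel evaluation of Sauvola's windowed formula with
    reflective border padding and the absolute intensity floor."""
    img = np.asarray(img, dtype=float)
    r = params.window // 2
    pad = np.pad(img, r, mode="reflect")
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = pad[i : i + params.window, j : j + params.window]
            m, s = win.mean(), win.std()
            thresh = m * (1.0 + params.k * (s / params.R - 1.0))
            out[i, j] = (img[i, j] > thresh) and (img[i, j] > params.min_intensity_floor)
    return out


def flood_fill_oracle(mask) -> list[set]:
    """8-connected components by breadth-first search over pixel sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp, queue = set(), [(i, j)]
                seen[i, j] = True
                while queue:
                    y, x = queue.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                queue.append((yy, xx))
                comps.append(comp)
    return comps
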