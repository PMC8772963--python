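"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive - nested loops, explicit pixel sets,
flood fill - and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def flood_components(mask: np.ndarray, connectivity: int = 8):
    """All connected components by explicit flood fill, in raster order."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def brute_largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    comps = flood_components(mask, connectivity)
    out = np.zeros_like(np.asarray(mask), dtype=bool)
    if not comps:
        return out
    best = max(comps, key=len)  # raster order + max keeps the first largest
    for r, c in best:
        out[r, c] = True
    return out


def disk_offsets(radius: int):
    return [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            # pixels outside the frame count as background
            out[r, c] = all(0 <= r + dr < h and 0 <= c + dc < w
                            and mask[r + dr, c + dc] for dr, dc in offs)
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in offs:
            if 0 <= r + dr < h and 0 <= c + dc < w:
                out[r + dr, c + dc] = True
    return out


def brute_open(mask: np.ndarray, radius: int) -> np.ndarray:
    return brute_dilate(brute_erode(mask, radius), radius)


def brute_metrics(truth: np.ndarray, pred: np.ndarray) -> dict:
    """All six metrics from explicit pixel sets."""
    t = {tuple(p) for p in np.argwhere(np.asarray(truth).astype(bool))}
    p = {tuple(q) for q in np.argwhere(np.asarray(pred).astype(bool))}
    allpix = {(r, c) for r in range(truth.shape[0]) for c in range(truth.shape[1])}
    tb, pb = allpix - t, allpix - p

    def iou(a, b):
        if not a and not b:
            return 1.0
        u = a | b
        return len(a & b) / len(u) if u else 1.0

    jac = iou(t, p)
    dsc = (1.0 if not t and not p
           else 2 * len(t & p) / (len(t) + len(p)))
    gpa = (len(t & p) + len(tb & pb)) / len(allpix)
    sens = (1.0 if not t and not p else 0.0) if not t else len(t & p) / len(t)
    spec = (1.0 if not tb and not pb else 0.0) if not tb else len(tb & pb) / len(tb)
    return {"jaccard": jac, "dsc": dsc, "gpa": gpa, "sensitivity": sens,
            "specificity": spec, "iou_mean_class": (iou(t, p) + iou(tb, pb)) / 2}


def mlp_weight_tally(mlp) -> int:
    """Count weights of a refinement MLP by explicit enumeration."""
    total = mlp.W1.data.size + mlp.W2.data.size
    for b in (mlp.b1, mlp.b2):
        if b is not None:
            total += b.data.size
    return total
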