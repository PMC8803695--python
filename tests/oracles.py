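"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: the
segmentation oracle re-finds components by exhaustive BFS flood fill, the
average-precision oracle walks every threshold with explicit loops, and the
staging oracle spells the category rules out case by case.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def floodfill_components(pet: np.ndarray, threshold_fraction: float,
                         suv_floor: float, connectivity: int = 26):
    """Max-first peeling re-implemented with an explicit BFS flood fill.

    Returns a list of sorted voxel-index-tuple lists, one per region, in
    emission order.
    """
    pet = np.asarray(pet, dtype=np.float64)
    shape = pet.shape
    if connectivity == 26:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    else:
        neigh = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    assigned = np.zeros(shape, dtype=bool)
    regions = []
    flat = pet.ravel()
    while True:
        # peak search: highest unassigned value above the floor, ties to the
        # lowest linear index (np.argmax returns the first maximum)
        masked = np.where(assigned.ravel(), -np.inf, flat)
        best_flat = int(np.argmax(masked))
        if masked[best_flat] <= suv_floor:
            break
        best = tuple(int(v) for v in np.unravel_index(best_flat, shape))
        best_val = pet[best]
        t = threshold_fraction * best_val
        comp = {best}
        queue = deque([best])
        while queue:
            cur = queue.popleft()
            for d in neigh:
                nxt = tuple(c + o for c, o in zip(cur, d))
                if any(v < 0 or v >= s for v, s in zip(nxt, shape)):
                    continue
                if nxt in comp or assigned[nxt] or pet[nxt] < t:
                    continue
                comp.add(nxt)
                queue.append(nxt)
        for idx in comp:
            assigned[idx] = True
        regions.append(sorted(comp))
    return regions


def average_precision_bruteforce(scores, labels) -> float:
    """AP (percent) by walking every distinct threshold explicitly."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return 100.0 * ap


def stage_bruteforce(r: int, a: int, b: int, c: int):
    """(N, M) stage from role counts, spelled out case by case."""
    if r == 0:
        n = "N0"
    elif r == 1:
        n = "N1"
    else:
        n = "N2"
    if c > 0:
        m = "M1c"
    else:
        if b == 0:
            m = "M1a" if a > 0 else "M0"
        elif b == 1:
            m = "M1b_u"
        elif b in (2, 3):
            m = "M1b_o"
        else:
            m = "M1b_d"
    return n, m
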