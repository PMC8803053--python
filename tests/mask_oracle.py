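"""Brute-force flood-fill reference for binary-mask operations.

Deliberately naive: breadth-first search on explicit pixel queues, no scipy
or scikit-image, so it is an independent check of the production mask
operations (hole filling, small-object removal, connected labeling).
Connectivity conventions match the production rules: foreground 4-connected,
background 8-connected.
"""

from collections import deque

import numpy as np

N4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
N8 = N4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def flood_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label True regions by BFS; 4- or 8-connectivity."""
    nbrs = N4 if connectivity == 4 else N8
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                queue = deque([(i, j)])
                labels[i, j] = current
                while queue:
                    y, x = queue.popleft()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels


def fill_small_holes_oracle(mask: np.ndarray, min_hole_px: float) -> np.ndarray:
    """Fill enclosed 8-connected background regions with size < min_hole_px."""
    out = mask.copy()
    bg = flood_label(~mask, connectivity=8)
    border_ids = set(bg[0, :]) | set(bg[-1, :]) | set(bg[:, 0]) | set(bg[:, -1])
    border_ids.discard(0)
    for lab in range(1, bg.max() + 1):
        if lab in border_ids:
            continue
        size = int((bg == lab).sum())
        if size < min_hole_px:
            out[bg == lab] = True
    return out


def remove_small_objects_oracle(mask: np.ndarray, min_obj_px: float) -> np.ndarray:
    """Drop 4-connected foreground components with size < min_obj_px."""
    out = mask.copy()
    fg = flood_label(mask, connectivity=4)
    for lab in range(1, fg.max() + 1):
        component = fg == lab
        if component.sum() < min_obj_px:
            out[component] = False
    return out
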