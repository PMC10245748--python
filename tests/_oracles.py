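"""Brute-force reference implementations used as independent test oracles."""

import numpy as np


def flood_count(mask: np.ndarray) -> int:
    """8-connected component count by explicit flood fill."""
    mask = mask.copy()
    h, w = mask.shape
    n = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            n += 1
            stack = [(i, j)]
            mask[i, j] = False
            while stack:
                a, b = stack.pop()
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        x, y = a + da, b + db
                        if 0 <= x < h and 0 <= y < w and mask[x, y]:
                            mask[x, y] = False
                            stack.append((x, y))
    return n
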