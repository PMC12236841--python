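"""Independent brute-force oracles used only to verify the pipeline.

The flood-fill labeller is deliberately written as an explicit-stack BFS
over neighbour offsets, sharing no code with the skimage-based path it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity_full: bool = True) -> list[set]:
    """Connected components of a boolean array by explicit flood fill.

    ``connectivity_full`` uses all 3^d - 1 neighbour offsets (8-connectivity
    in 2D, 26-connectivity in 3D).  Returns a list of voxel-index sets.
    """
    mask = np.asarray(mask, dtype=bool)
    d = mask.ndim
    if connectivity_full:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=d) if any(o)]
    else:
        offsets = [
            o
            for o in itertools.product((-1, 0, 1), repeat=d)
            if sum(abs(x) for x in o) == 1
        ]
    visited = np.zeros_like(mask, dtype=bool)
    components = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = set()
        while stack:
            p = stack.pop()
            comp.add(p)
            for off in offsets:
                q = tuple(pi + oi for pi, oi in zip(p, off))
                if any(qi < 0 or qi >= s for qi, s in zip(q, mask.shape)):
                    continue
                if mask[q] and not visited[q]:
                    visited[q] = True
                    stack.append(q)
        components.append(comp)
    return components
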