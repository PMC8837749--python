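"""Skeleton arc-length estimation on binary masks.

The length of a skeletonised structure is estimated from its pixel
adjacency graph: horizontal/vertical neighbour pairs contribute one pixel
step, diagonal pairs sqrt(2) steps.  A diagonal edge whose corner is
already bridged by an orthogonal pixel is skipped, so staircase corners
are not double counted.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Total arc length (pixels) of a skeleton mask."""
    edges = _edges(skeleton)
    return float(sum(w for _, _, w in edges))


def _edges(skeleton: np.ndarray) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Enumerate skeleton pixel-adjacency edges as (p, q, weight)."""
    s = skeleton.astype(bool)
    out: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    sqrt2 = math.sqrt(2.0)

    h_pairs = np.argwhere(s[:, :-1] & s[:, 1:])
    out += [((r, c), (r, c + 1), 1.0) for r, c in h_pairs]
    v_pairs = np.argwhere(s[:-1, :] & s[1:, :])
    out += [((r, c), (r + 1, c), 1.0) for r, c in v_pairs]

    # diagonal \ : skip when either orthogonal corner pixel is set
    d1 = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    out += [((r, c), (r + 1, c + 1), sqrt2) for r, c in np.argwhere(d1)]
    # diagonal / :
    d2 = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    out += [((r, c + 1), (r + 1, c), sqrt2) for r, c in np.argwhere(d2)]
    return out


def per_seed_lengths(skeleton: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Partition skeleton length among seed points.

    Each adjacency edge is assigned to the seed nearest its midpoint.
    Returns an array of per-seed lengths (pixels) aligned with ``seeds``.
    """
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    lengths = np.zeros(len(seeds))
    edges = _edges(skeleton)
    if not edges or not len(seeds):
        return lengths
    midpoints = np.array([[(p[0] + q[0]) / 2, (p[1] + q[1]) / 2] for p, q, _ in edges])
    weights = np.array([w for _, _, w in edges])
    _, owner = cKDTree(seeds).query(midpoints)
    np.add.at(lengths, owner, weights)
    return lengths
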