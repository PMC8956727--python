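"""Colony adjacency graph and connected-cluster extraction.

Colonies whose bounding boxes overlap by more than a small fraction of their
area are treated as one physical cluster, so that mutually overlapping
colonies are cut out and pasted as a unit and their overlap geometry is
preserved.  The overlap fraction is measured against the smaller of the two
box areas, which makes the relation symmetric and links a pair whenever
either colony loses more than the threshold share of itself.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .datamodel import BoundingBox

#: Default link threshold: boxes sharing strictly more than 1% of the smaller
#: box's area are adjacent.
DEFAULT_OVERLAP_THRESHOLD = 0.01


def overlap_fraction(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area divided by the smaller box area; symmetric, in [0, 1]."""
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    return (iw * ih) / min(a.area, b.area)


def build_adjacency(
    boxes: list[BoundingBox],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> np.ndarray:
    """Boolean adjacency matrix: edge iff overlap fraction strictly exceeds threshold."""
    n = len(boxes)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if overlap_fraction(boxes[i], boxes[j]) > threshold:
                adj[i, j] = adj[j, i] = True
    return adj


def connected_clusters(adj: np.ndarray) -> list[list[int]]:
    """Connected components by breadth-first search.

    Components are returned in ascending order of their smallest member and
    each component's members sorted ascending, so downstream sampling is
    reproducible regardless of dict/set iteration order.
    """
    adj = np.asarray(adj, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got {adj.shape}")
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        members = []
        while queue:
            node = queue.popleft()
            members.append(node)
            for nbr in np.flatnonzero(adj[node]):
                if not seen[nbr]:
                    seen[nbr] = True
                    queue.append(int(nbr))
        clusters.append(sorted(members))
    return clusters


def cluster_boxes(
    boxes: list[BoundingBox],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> list[list[int]]:
    """Convenience: adjacency + BFS in one call."""
    return connected_clusters(build_adjacency(boxes, threshold))


__all__ = [
    "DEFAULT_OVERLAP_THRESHOLD",
    "overlap_fraction",
    "build_adjacency",
    "connected_clusters",
    "cluster_boxes",
]
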