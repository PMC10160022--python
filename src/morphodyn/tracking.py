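"""Cluster-aware frame-to-frame cell tracking and backward history traces.

Cells are linked between consecutive frames with a two-regime heuristic.
Contiguous clusters of the foreground mask are separated first.  Cells whose
cluster occupies fewer than ``small_cluster_max_area`` pixels (default
10,000) are linked by minimum centroid distance with a cutoff (default 45
px).  Larger clusters are first matched between frames by centroid distance
(cutoff 300 px), each matched cluster pair is rigidly registered (rotation +
translation), and member cells are then linked by maximum mask overlap,
requiring at least ``min_overlap_px`` (default 10) shared pixels.

A child cell has at most one parent, but a parent may have several children:
divisions (and over-segmentations) appear as multi-child nodes, and the
backward history of each daughter shares the parental prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

__all__ = [
    "LinkageGraph",
    "TrajectoryHistory",
    "connected_clusters",
    "link_frame_pair",
    "build_linkage_graph",
    "trace_history",
    "leaf_histories",
    "link_metrics",
]

SMALL_CLUSTER_MAX_AREA = 10_000  # px; below this, plain distance linking
SMALL_DIST_CUTOFF = 45.0  # px, cell-to-cell
CLUSTER_DIST_CUTOFF = 300.0  # px, cluster-to-cluster
MIN_OVERLAP_PX = 10  # px, post-registration mask intersection


@dataclass
class LinkageGraph:
    """Directed frame-to-frame cell links; nodes are (frame, cell_label)."""

    parent: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    children: dict[tuple[int, int], list[tuple[int, int]]] = field(default_factory=dict)
    method: dict[tuple[tuple[int, int], tuple[int, int]], str] = field(default_factory=dict)

    def add_edge(self, t: int, lab_t: int, lab_t1: int, method: str) -> None:
        child = (t + 1, lab_t1)
        par = (t, lab_t)
        if child in self.parent:
            raise ValueError(f"cell {child} already has a parent")
        self.parent[child] = par
        self.children.setdefault(par, []).append(child)
        self.method[(par, child)] = method

    @property
    def edges(self) -> list[tuple[int, int, int, int]]:
        return sorted(
            (p[0], p[1], c[0], c[1]) for c, p in self.parent.items()
        )

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, p in sorted(self.parent.items()):
                fh.write(
                    json.dumps(
                        {
                            "t": p[0],
                            "label_t": p[1],
                            "t1": c[0],
                            "label_t1": c[1],
                            "method": self.method[(p, c)],
                        }
                    )
                    + "\n"
                )


@dataclass
class TrajectoryHistory:
    """The unique backward trace of one terminal cell through time."""

    terminal: tuple[int, int]
    trace: list[tuple[int, int]]  # time-ordered, oldest first, ends at terminal

    @property
    def length(self) -> int:
        return len(self.trace)


def connected_clusters(
    fg_mask: np.ndarray, connectivity: int = 2
) -> tuple[np.ndarray, dict[int, int]]:
    """Label contiguous foreground clusters (8-connected by default).

    Returns the cluster label image and a {cluster_label: pixel_area} map.
    """
    lab = cc_label(fg_mask > 0, connectivity=connectivity)
    labs, counts = np.unique(lab[lab > 0], return_counts=True)
    return lab, dict(zip(labs.tolist(), counts.tolist()))


def _centroids(mask: np.ndarray) -> dict[int, np.ndarray]:
    labs = np.unique(mask)
    labs = labs[labs > 0]
    if labs.size == 0:
        return {}
    cents = ndi.center_of_mass(np.ones_like(mask), mask, labs)
    return {int(l): np.asarray(c) for l, c in zip(labs, cents)}


def _rigid_register_cluster(
    ref: np.ndarray, mov: np.ndarray, max_angle: float = 20.0
) -> np.ndarray:
    """Rotate+translate a moving binary cluster onto a reference one.

    The moving mask is translated so the cluster centroids coincide, then the
    rotation (about the centroid) maximizing binary overlap is found by a
    coarse-to-fine grid search within +/- ``max_angle`` degrees.  Returns the
    transformed *label* image of the moving cluster resampled onto the
    reference frame (nearest-neighbor, so labels survive).
    """
    ref_b = ref > 0
    mov_b = mov > 0
    rc = np.array(ndi.center_of_mass(ref_b))
    mc = np.array(ndi.center_of_mass(mov_b))

    def transformed(angle_deg: float) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        # output coord y -> input coord: mc + R^-1 (y - rc)
        offset = mc - R.T @ rc
        return ndi.affine_transform(
            mov, R.T, offset=offset, output_shape=ref.shape, order=0,
            mode="constant", cval=0,
        )

    best = (-1.0, 0.0)
    for step, lo, hi in ((2.0, -max_angle, max_angle), (0.25, None, None)):
        if lo is None:
            lo, hi = best[1] - 2.0, best[1] + 2.0
        for ang in np.arange(lo, hi + 1e-9, step):
            score = np.sum((transformed(ang) > 0) & ref_b)
            if score > best[0]:
                best = (float(score), float(ang))
    return transformed(best[1])


def link_frame_pair(
    mask_t: np.ndarray,
    mask_t1: np.ndarray,
    small_cluster_max_area: int = SMALL_CLUSTER_MAX_AREA,
    small_dist_cutoff: float = SMALL_DIST_CUTOFF,
    cluster_dist_cutoff: float = CLUSTER_DIST_CUTOFF,
    min_overlap_px: int = MIN_OVERLAP_PX,
    connectivity: int = 2,
) -> list[tuple[int, int, str]]:
    """Link cells between two consecutive label masks.

    Returns ``(label_t, label_t1, method)`` tuples, where method is
    ``"distance"`` (small-cluster regime) or ``"overlap"`` (large-cluster
    regime).  Each cell at t+1 receives at most one parent; parents may be
    shared (division / over-segmentation).
    """
    cents_t = _centroids(mask_t)
    cents_t1 = _centroids(mask_t1)
    if not cents_t or not cents_t1:
        return []

    clus_t, areas_t = connected_clusters(mask_t, connectivity)
    clus_t1, areas_t1 = connected_clusters(mask_t1, connectivity)

    # cluster membership of each cell (majority cluster label under its mask)
    def memberships(mask, clus):
        out = {}
        for lab, c in _centroids(mask).items():
            sel = clus[mask == lab]
            sel = sel[sel > 0]
            out[lab] = int(np.bincount(sel).argmax()) if sel.size else 0
        return out

    memb_t = memberships(mask_t, clus_t)
    memb_t1 = memberships(mask_t1, clus_t1)

    large_t = {cl for cl, a in areas_t.items() if a >= small_cluster_max_area}
    large_t1 = {cl for cl, a in areas_t1.items() if a >= small_cluster_max_area}

    links: dict[int, tuple[int, str]] = {}  # label_t1 -> (label_t, method)

    # --- large-cluster regime: match clusters, rigidly register, overlap-link
    if large_t and large_t1:
        cl_cent_t = {
            cl: np.array(ndi.center_of_mass(clus_t == cl)) for cl in large_t
        }
        cl_cent_t1 = {
            cl: np.array(ndi.center_of_mass(clus_t1 == cl)) for cl in large_t1
        }
        for cl1, c1 in cl_cent_t1.items():
            dists = {cl: np.linalg.norm(c1 - c0) for cl, c0 in cl_cent_t.items()}
            cl0 = min(dists, key=lambda k: (dists[k], k))
            if dists[cl0] > cluster_dist_cutoff:
                continue
            ref_lab = np.where(clus_t == cl0, mask_t, 0)
            mov_lab = np.where(clus_t1 == cl1, mask_t1, 0)
            mov_reg = _rigid_register_cluster(ref_lab, mov_lab)
            for lab1 in np.unique(mov_reg):
                if lab1 == 0:
                    continue
                under = ref_lab[mov_reg == lab1]
                under = under[under > 0]
                if under.size == 0:
                    continue
                cand, counts = np.unique(under, return_counts=True)
                best = int(cand[np.argmax(counts)])
                if counts.max() >= min_overlap_px:
                    links[int(lab1)] = (best, "overlap")

    # --- small-cluster regime: nearest-centroid linking with distance cutoff
    small_cells_t = [lab for lab, cl in memb_t.items() if cl not in large_t]
    for lab1, c1 in cents_t1.items():
        if lab1 in links or memb_t1[lab1] in large_t1:
            continue
        if not small_cells_t:
            break
        dists = {lab: float(np.linalg.norm(c1 - cents_t[lab])) for lab in small_cells_t}
        best = min(dists, key=lambda k: (dists[k], k))
        if dists[best] <= small_dist_cutoff:
            links[lab1] = (best, "distance")

    return sorted((v[0], k, v[1]) for k, v in links.items())


def build_linkage_graph(masks: np.ndarray, **link_kwargs) -> LinkageGraph:
    """Union of frame-pair links over a whole label-mask stack."""
    graph = LinkageGraph()
    for t in range(masks.shape[0] - 1):
        for lab_t, lab_t1, method in link_frame_pair(masks[t], masks[t + 1], **link_kwargs):
            graph.add_edge(t, lab_t, lab_t1, method)
    return graph


def trace_history(terminal: tuple[int, int], graph: LinkageGraph) -> TrajectoryHistory:
    """Maximal backward trace of a terminal cell (oldest ancestor first)."""
    trace = [terminal]
    node = terminal
    while node in graph.parent:
        node = graph.parent[node]
        trace.append(node)
    trace.reverse()
    return TrajectoryHistory(terminal=terminal, trace=trace)


def leaf_histories(graph: LinkageGraph, masks: np.ndarray) -> list[TrajectoryHistory]:
    """Backward histories of every leaf cell (a cell with no successor).

    Every maximal track appears exactly once; daughters of a division give
    two histories sharing the parental prefix.
    """
    out = []
    for t in range(masks.shape[0]):
        for lab in np.unique(masks[t]):
            if lab == 0:
                continue
            node = (t, int(lab))
            if node not in graph.children:
                out.append(trace_history(node, graph))
    return out


def link_metrics(
    edges: list[tuple[int, int, int, int]],
    true_links: set[tuple[int, int, int, int]],
) -> tuple[float, float]:
    """(precision, recall) of predicted edges against ground-truth links."""
    pred = set(edges)
    if not pred or not true_links:
        return 0.0, 0.0
    tp = len(pred & true_links)
    return tp / len(pred), tp / len(true_links)
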