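"""Clustering of start conformations and hierarchical frame selection.

Start pools are clustered on pairwise superposition RMSD (average
linkage); the per-step selection ranks the pooled frames by a strict
lexicographic key -- interaction-region base-pair distance, then
whole-complex distance, then energy -- mirroring the idea that realising
the constrained interaction matters first, the rest of the complex
second, and energy only breaks ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .duplex2d import (
    ComplexStructure,
    ConstraintStructure,
    bp_distance,
    is_exact_match,
)
from .model3d import DEFAULT_GEOMETRY, GeometryParams, annotate_pairs, superpose_rmsd
from .sampler import TrajectoryFrame


class NoValidStartError(RuntimeError):
    """No frame in the pool exactly matches the initial 2D structure."""


@dataclass(frozen=True)
class ClusterAssignment:
    labels: tuple[int, ...]
    representatives: tuple[TrajectoryFrame, ...]
    n_cluster: int


def cluster_starts(
    pool: Sequence[TrajectoryFrame],
    n_cluster: int,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of the pool on pairwise RMSD.

    Cut at *n_cluster* clusters; each cluster's representative is its
    lowest-total-energy frame (ties: earliest pool index).  Pools smaller
    than *n_cluster* degrade to one singleton cluster per frame with a
    warning.
    """
    if not pool:
        raise ValueError("cluster_starts requires a non-empty pool")
    n = len(pool)
    if n < n_cluster:
        warnings.warn(
            f"pool of {n} frames smaller than n_cluster={n_cluster}; "
            "using one singleton cluster per frame",
            stacklevel=2,
        )
        return ClusterAssignment(tuple(range(n)), tuple(pool), n)
    if n_cluster == n:
        return ClusterAssignment(tuple(range(n)), tuple(pool), n)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = superpose_rmsd(pool[i].conf, pool[j].conf)
    z = linkage(squareform(dmat, checks=False), method=linkage_method)
    raw = fcluster(z, t=n_cluster, criterion="maxclust")
    # relabel clusters 0..k-1 by first appearance for determinism
    order: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in order:
            order[lab] = len(order)
        labels.append(order[lab])
    reps = []
    for c in range(len(order)):
        members = [i for i, lab in enumerate(labels) if lab == c]
        best = min(members, key=lambda i: (pool[i].total_energy, i))
        reps.append(pool[best])
    return ClusterAssignment(tuple(labels), tuple(reps), len(order))


def select_start(
    pool: Sequence[TrajectoryFrame],
    initial: ComplexStructure,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> TrajectoryFrame:
    """Lowest-energy frame whose annotation exactly matches *initial*.

    Matching is canonical-only: geometric annotation may report non-WC/GU
    contacts that the 2D constraint never speaks about.  Ties break by
    earliest step_index, then pool order.
    """
    best: Optional[tuple] = None
    chosen: Optional[TrajectoryFrame] = None
    for order, frame in enumerate(pool):
        annotated = annotate_pairs(frame.conf, params)
        if not is_exact_match(annotated, initial, canonical_only=True):
            continue
        key = (frame.total_energy, frame.step_index, order)
        if best is None or key < best:
            best, chosen = key, frame
    if chosen is None:
        raise NoValidStartError(
            "no sampled frame exactly matches the initial 2D structure"
        )
    return chosen


def selection_key(
    frame: TrajectoryFrame,
    constraint: ConstraintStructure,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> tuple[int, int, float, int]:
    """Hierarchical key: (interaction-region bp distance, full bp distance,
    total energy, step_index)."""
    annotated = annotate_pairs(frame.conf, params)
    reference = constraint.as_structure()
    region = {
        pos for bp in constraint.intermolecular_pairs for pos in bp.positions()
    }
    d_region = bp_distance(annotated, reference, region=region)
    d_full = bp_distance(annotated, reference)
    return (d_region, d_full, frame.total_energy, frame.step_index)


def select_step(
    pool: Sequence[TrajectoryFrame],
    constraint: ConstraintStructure,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> TrajectoryFrame:
    """Lexicographic minimum of :func:`selection_key` over the pool.

    Pool order is the final tie-break, so with all keys tied the earliest
    frame wins.
    """
    if not pool:
        raise ValueError("select_step requires a non-empty pool")
    best_key = None
    chosen = None
    for order, frame in enumerate(pool):
        key = selection_key(frame, constraint, params) + (order,)
        if best_key is None or key < best_key:
            best_key, chosen = key, frame
    return chosen


def write_selection_log(
    pool: Sequence[TrajectoryFrame],
    constraint: ConstraintStructure,
    chosen: TrajectoryFrame,
    path,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> None:
    """Audit log: frame id, key tuple, chosen flag (TSV)."""
    lines = ["frame\tbp_dist_interaction\tbp_dist_full\ttotal_energy\tstep_index\tchosen"]
    for order, frame in enumerate(pool):
        key = selection_key(frame, constraint, params)
        flag = 1 if frame is chosen else 0
        lines.append(
            f"{order}\t{key[0]}\t{key[1]}\t{key[2]:.6f}\t{key[3]}\t{flag}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
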