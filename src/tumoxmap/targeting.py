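"""Percentile-cluster biopsy targeting on parametric maps.

Candidate biopsy sites are connected clusters of extreme map values
inside the tumor (edema excluded — biopsies there are prohibited):
"high" clusters exceed the 80th percentile of the unflagged tumor
voxels, "low" clusters fall below the 20th.  Clusters need at least nine
voxels and a compact core (a full 2x2x2 block) to be actionable.
Clusters from different metrics that overlap are prioritised, OEF
considered first, then CBV, then vessel size.  Neighborhood-averaged map
values are extracted at each target for later pairing with histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ClusterCriteria",
    "Cluster",
    "BiopsyTarget",
    "find_clusters",
    "prioritize",
    "extract_target_values",
]

METRIC_ORDER = ("OEF", "CBV", "vessel_size")


@dataclass(frozen=True)
class ClusterCriteria:
    """Percentile-cluster definition for one metric and polarity.

    ``require_block`` demands a full 2x2x2 supra-threshold block inside
    the cluster as the compactness reading of "arranged cubically"; set
    False together with ``min_voxels`` to select the in-plane 3x3
    alternative reading externally.
    """

    metric: str
    polarity: str = "high"
    high_pct: float = 80.0
    low_pct: float = 20.0
    min_voxels: int = 9
    require_block: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRIC_ORDER:
            raise ValueError(f"metric must be one of {METRIC_ORDER}")
        if self.polarity not in ("high", "low"):
            raise ValueError("polarity must be 'high' or 'low'")


@dataclass
class Cluster:
    metric: str
    polarity: str
    voxels: np.ndarray  # (n, 3) int indices
    threshold: float
    mean_extremity: float  # mean |value - threshold| inside the cluster

    @property
    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels}


@dataclass
class BiopsyTarget:
    """A prioritised biopsy location with its defining criteria."""

    center_voxel: tuple[int, int, int]
    cluster_id: int
    defining_criteria: tuple[tuple[str, str], ...]
    priority_rank: int
    voi_label: str = ""
    mri_values: dict[str, float] = field(default_factory=dict)
    n_voxels: int = 0


def _has_2x2x2_block(mask: np.ndarray) -> bool:
    b = mask[:-1] & mask[1:]
    b = b[:, :-1] & b[:, 1:]
    b = b[:, :, :-1] & b[:, :, 1:]
    return bool(b.any())


def find_clusters(
    value_map: np.ndarray,
    criteria: ClusterCriteria,
    search_mask: np.ndarray,
    error_mask: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected percentile clusters of a map inside the search mask.

    The percentile is computed over the finite, unflagged search-mask
    voxels; thresholding is strict (> for high, < for low).  Components
    are taken under 26-connectivity, kept when they have at least
    ``min_voxels`` voxels and (optionally) contain a full 2x2x2 block,
    and returned ordered by decreasing mean extremity.
    """
    vol = np.asarray(value_map, dtype=float)
    mask = np.asarray(search_mask, dtype=bool)
    if error_mask is not None:
        mask = mask & ~np.asarray(error_mask, dtype=bool)
    mask = mask & np.isfinite(vol)
    if not mask.any():
        raise ValueError("search mask is empty")
    ref = vol[mask]
    if criteria.polarity == "high":
        thr = np.percentile(ref, criteria.high_pct)
        extreme = mask & (vol > thr)
    else:
        thr = np.percentile(ref, criteria.low_pct)
        extreme = mask & (vol < thr)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labelled, n = ndimage.label(extreme, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n + 1):
        comp = labelled == lab
        if comp.sum() < criteria.min_voxels:
            continue
        if criteria.require_block and not _has_2x2x2_block(comp):
            continue
        vox = np.argwhere(comp)
        clusters.append(
            Cluster(
                metric=criteria.metric,
                polarity=criteria.polarity,
                voxels=vox,
                threshold=float(thr),
                mean_extremity=float(np.abs(vol[comp] - thr).mean()),
            )
        )
    clusters.sort(key=lambda c: (-c.mean_extremity, tuple(map(tuple, c.voxels))))
    return clusters


def _centroid_voxel(voxels: np.ndarray) -> tuple[int, int, int]:
    """Component centroid snapped to the nearest member voxel."""
    c = voxels.mean(axis=0)
    d = np.sum((voxels - c) ** 2, axis=1)
    best = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], d))[0]
    return tuple(int(x) for x in voxels[best])


def prioritize(
    clusters_by_metric: dict[str, list[Cluster]],
    max_targets: int | None = None,
) -> list[BiopsyTarget]:
    """Merge per-metric clusters into a ranked biopsy-target list.

    Clusters overlapping across metrics form one combined target whose
    defining criteria are the union of the member (metric, polarity)
    pairs.  Targets supported by more metrics rank first; ties break on
    overlap voxel count, then mean extremity, then the fixed metric
    consideration order (OEF, CBV, vessel size).  Deterministic and
    invariant to input list order.
    """
    all_clusters: list[Cluster] = []
    for metric in METRIC_ORDER:
        cl = list(clusters_by_metric.get(metric, []))
        cl.sort(key=lambda c: (-c.mean_extremity, tuple(map(tuple, c.voxels))))
        all_clusters.extend(cl)
    if not all_clusters:
        return []

    sets = [c.voxel_set for c in all_clusters]
    # union-find over the overlap graph (edges only across metrics)
    parent = list(range(len(all_clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(all_clusters)):
        for j in range(i + 1, len(all_clusters)):
            if all_clusters[i].metric == all_clusters[j].metric:
                continue
            if sets[i] & sets[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(len(all_clusters)):
        groups.setdefault(find(i), []).append(i)

    records = []
    for members in groups.values():
        metrics = {all_clusters[i].metric for i in members}
        criteria = sorted(
            {(all_clusters[i].metric, all_clusters[i].polarity) for i in members},
            key=lambda mp: (METRIC_ORDER.index(mp[0]), mp[1]),
        )
        union: set = set()
        inter: set | None = None
        for i in members:
            union |= sets[i]
            inter = sets[i] if inter is None else inter & sets[i]
        overlap = inter if (inter and len(metrics) > 1) else union
        footprint = np.array(sorted(overlap if overlap else union))
        extremity = max(all_clusters[i].mean_extremity for i in members)
        first_metric = min(METRIC_ORDER.index(all_clusters[i].metric) for i in members)
        records.append(
            dict(
                n_metrics=len(metrics),
                overlap_voxels=len(overlap) if len(metrics) > 1 else 0,
                extremity=extremity,
                first_metric=first_metric,
                criteria=tuple(criteria),
                center=_centroid_voxel(footprint),
                n_voxels=len(union),
            )
        )

    records.sort(
        key=lambda r: (-r["n_metrics"], -r["overlap_voxels"], -r["extremity"],
                       r["first_metric"], r["center"])
    )
    targets = []
    for rank, r in enumerate(records, start=1):
        targets.append(
            BiopsyTarget(
                center_voxel=r["center"],
                cluster_id=rank,
                defining_criteria=r["criteria"],
                priority_rank=rank,
                n_voxels=r["n_voxels"],
            )
        )
    if max_targets is not None:
        targets = targets[:max_targets]
    return targets


def extract_target_values(
    maps: dict[str, np.ndarray],
    target: BiopsyTarget,
    error_mask: np.ndarray | None = None,
    mode: str = "cube27",
) -> dict[str, float]:
    """Neighborhood-averaged map values at a biopsy target.

    ``cube27`` (default) averages the full 3x3x3 neighborhood including
    the center; ``ten`` implements the literal ten-voxel reading (center
    plus its nine nearest neighbours by Euclidean distance, i.e. the six
    faces and three of the edge neighbours in fixed axis order).
    Out-of-bounds and error-mask voxels are excluded; if nothing
    remains, the value is NaN and the target is annotated.
    """
    cx, cy, cz = target.center_voxel
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    if mode == "ten":
        offsets.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
        offsets = offsets[:10]
    elif mode != "cube27":
        raise ValueError("mode must be 'cube27' or 'ten'")

    shape = next(iter(maps.values())).shape
    coords = []
    for dx, dy, dz in offsets:
        x, y, z = cx + dx, cy + dy, cz + dz
        if 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
            if error_mask is not None and error_mask[x, y, z]:
                continue
            coords.append((x, y, z))
    values: dict[str, float] = {}
    for name, vol in maps.items():
        if coords:
            vals = np.array([vol[c] for c in coords], dtype=float)
            vals = vals[np.isfinite(vals)]
            values[name] = float(vals.mean()) if vals.size else float("nan")
        else:
            values[name] = float("nan")
    target.mri_values = values
    return values
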