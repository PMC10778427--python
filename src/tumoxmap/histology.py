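"""Quantification of per-biopsy histology measurements.

Inputs are tabulated per-sample measurements exported from whole-slide
analysis (or phantom-generated stand-ins): segmented vessel records
inside vascular hotspot ROIs and the HIF-1alpha staining distribution.
Outputs per sample: vessel density (vessel area / tissue area), mean
vessel diameter (um), and an H-score for HIF-1alpha expression
(sum over intensity levels of level x percent positive cells, 0-300).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VesselRecord",
    "HistologySample",
    "vessel_density",
    "mean_vessel_diameter",
    "equivalent_circle_diameter",
    "hif_score",
    "quantify_samples",
]


@dataclass(frozen=True)
class VesselRecord:
    """One segmented vessel: area (um^2) and/or measured diameter (um)."""

    area_um2: float | None = None
    diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.area_um2 is None and self.diameter_um is None:
            raise ValueError("vessel record needs an area or a diameter")
        if self.diameter_um is not None and self.diameter_um <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.area_um2 is not None and self.area_um2 <= 0:
            raise ValueError("vessel area must be positive")


@dataclass
class HistologySample:
    """Per-biopsy histology measurements within hotspot ROIs.

    ``hif_cells`` maps staining intensity level (0..3) to the percentage
    of cells at that level; percentages must sum to 100 (+/- 0.5).
    """

    sample_id: str
    subject_id: str
    voi_label: str
    vessel_records: list[VesselRecord] = field(default_factory=list)
    tissue_area_um2: float = 0.0
    hif_cells: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voi_label not in ("nonenhancing", "enhancing", "necrosis"):
            raise ValueError("voi_label must be nonenhancing, enhancing or necrosis")
        if self.tissue_area_um2 <= 0:
            raise ValueError("tissue_area_um2 must be positive")


def vessel_density(sample: HistologySample) -> float:
    """Total vessel area divided by total tissue area (fraction)."""
    total_vessel = sum(
        r.area_um2 if r.area_um2 is not None else math.pi * (r.diameter_um / 2.0) ** 2
        for r in sample.vessel_records
    )
    if total_vessel > sample.tissue_area_um2:
        raise ValueError("total vessel area exceeds tissue area")
    return total_vessel / sample.tissue_area_um2


def equivalent_circle_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: 2*sqrt(area/pi)."""
    return 2.0 * math.sqrt(area_um2 / math.pi)


def mean_vessel_diameter(sample: HistologySample) -> float:
    """Unweighted mean of per-vessel diameters (um).

    Records carrying only a segmentation area use the equivalent-circle
    diameter.  Raises on samples without any vessel record (callers flag
    such samples rather than imputing).
    """
    if not sample.vessel_records:
        raise ValueError(f"sample {sample.sample_id}: no vessels recorded")
    ds = [
        r.diameter_um if r.diameter_um is not None else equivalent_circle_diameter(r.area_um2)
        for r in sample.vessel_records
    ]
    return float(np.mean(ds))


def hif_score(sample: HistologySample) -> float:
    """HIF-1alpha H-score: sum over levels of (level x percent), 0-300."""
    cells = sample.hif_cells
    if any(level not in (0, 1, 2, 3) for level in cells):
        raise ValueError("intensity levels must be 0..3")
    if any(p < 0 for p in cells.values()):
        raise ValueError("percentages must be non-negative")
    total = sum(cells.values())
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"cell percentages sum to {total}, expected 100 +/- 0.5")
    return float(sum(level * pct for level, pct in cells.items()))


def quantify_samples(samples: list[HistologySample]) -> pd.DataFrame:
    """Per-sample quantification table (one row per biopsy).

    Samples without vessel records get NaN diameter and are flagged in
    the ``flagged`` column instead of raising.
    """
    rows = []
    for s in samples:
        try:
            diameter = mean_vessel_diameter(s)
            flagged = False
        except ValueError:
            diameter, flagged = float("nan"), True
        rows.append(
            dict(
                sample_id=s.sample_id,
                subject_id=s.subject_id,
                voi_label=s.voi_label,
                vessel_density=vessel_density(s),
                vessel_diameter_um=diameter,
                hif_score=hif_score(s) if s.hif_cells else float("nan"),
                flagged=flagged,
            )
        )
    return pd.DataFrame(rows)
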