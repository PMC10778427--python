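"""VOI-level evaluation: masks, averaged decay curves, summary tables.

Volumes of interest (VOIs) are the tumor compartments (edema,
nonenhancing, enhancing, necrosis) plus contralateral gray and white
matter.  This module binarizes tissue probability maps into the
contralateral masks, averages FLAIR-ASE log-signal curves per VOI with
alignment to the contra-GM baseline, and computes per-VOI median/IQR
summaries of the parametric maps with error-mask exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qbold import AseSeries, log_signal

__all__ = [
    "TUMOR_VOI_NAMES",
    "VoiMaskSet",
    "VoiCurve",
    "binarize_probability_maps",
    "voi_curve",
    "voi_summary",
    "group_summary",
]

TUMOR_VOI_NAMES = ("edema", "nonenhancing", "enhancing", "necrosis")
ALL_VOI_NAMES = TUMOR_VOI_NAMES + ("contra_GM", "contra_WM")


@dataclass
class VoiMaskSet:
    """Named binary VOI masks on a common grid.

    Tumor masks must be pairwise disjoint; every mask must share the
    reference grid shape.
    """

    masks: dict[str, np.ndarray]
    source: str = "provided"

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all VOI masks must share the reference grid")
        for name in self.masks:
            if name not in ALL_VOI_NAMES:
                raise ValueError(f"unknown VOI name: {name!r}")
            self.masks[name] = np.asarray(self.masks[name], dtype=bool)
        tumor = [n for n in TUMOR_VOI_NAMES if n in self.masks]
        for i, a in enumerate(tumor):
            for b in tumor[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"tumor masks {a!r} and {b!r} overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def get(self, name: str, default=None):
        return self.masks.get(name, default)


@dataclass
class VoiCurve:
    """VOI-averaged FLAIR-ASE ln-signal curve with baseline alignment."""

    voi_name: str
    taus_ms: np.ndarray
    mean_ln_signal: np.ndarray
    sd_ln_signal: np.ndarray
    baseline_offset: float = 0.0
    n_voxels: int = 0


def binarize_probability_maps(
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    hemisphere_mask: np.ndarray,
    threshold: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold GM/WM probability maps into contralateral masks.

    A voxel enters a mask when its probability *strictly* exceeds the
    threshold (0.9 by default, chosen to minimise partial-volume
    contamination) and lies in the contralateral hemisphere.
    """
    for prob in (gm_prob, wm_prob):
        p = np.asarray(prob)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    hemi = np.asarray(hemisphere_mask, dtype=bool)
    gm = (np.asarray(gm_prob) > threshold) & hemi
    wm = (np.asarray(wm_prob) > threshold) & hemi
    if not gm.any() or not wm.any():
        import warnings

        warnings.warn("empty contralateral GM or WM mask after thresholding")
    return gm, wm


def voi_curve(
    series: AseSeries,
    mask: np.ndarray,
    error_mask: np.ndarray | None = None,
    contra_gm_curve: VoiCurve | None = None,
    voi_name: str = "",
) -> VoiCurve:
    """Mean +/- SD ln-signal over a VOI, aligned to the contra-GM start.

    Error-mask voxels are excluded before averaging.  When a contra-GM
    curve is supplied, an additive offset shifts this curve so its
    tau = 0 value matches the contra-GM tau = 0 value (the offset acts
    on the mean only; SDs are left untouched).
    """
    m = np.asarray(mask, dtype=bool)
    if error_mask is not None:
        m = m & ~np.asarray(error_mask, dtype=bool)
    if not m.any():
        raise ValueError(f"VOI {voi_name!r} is empty after error-mask exclusion")
    lnS = log_signal(series)[m]
    mean = np.nanmean(lnS, axis=0)
    sd = np.nanstd(lnS, axis=0, ddof=0)
    offset = 0.0
    if contra_gm_curve is not None:
        offset = float(contra_gm_curve.mean_ln_signal[0] - mean[0])
        mean = mean + offset
    return VoiCurve(
        voi_name=voi_name,
        taus_ms=series.taus_ms.copy(),
        mean_ln_signal=mean,
        sd_ln_signal=sd,
        baseline_offset=offset,
        n_voxels=int(m.sum()),
    )


def voi_summary(
    maps: dict[str, np.ndarray],
    voi_set: VoiMaskSet,
    error_mask: np.ndarray | None = None,
    subject: str = "phantom",
) -> pd.DataFrame:
    """Median and IQR of each metric per VOI with error-mask exclusion.

    IQR is reported as a single width, Q3 - Q1, with linearly
    interpolated percentiles.  ``n_excluded`` counts exactly the
    error-mask voxels intersecting the VOI.
    """
    rows = []
    err = None if error_mask is None else np.asarray(error_mask, dtype=bool)
    for voi, mask in voi_set.masks.items():
        excl = 0 if err is None else int((mask & err).sum())
        kept = mask if err is None else mask & ~err
        for metric, vol in maps.items():
            vals = np.asarray(vol)[kept]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append(
                    dict(subject=subject, voi=voi, metric=metric, median=med,
                         iqr=q3 - q1, n_voxels=int(vals.size), n_excluded=excl)
                )
            else:
                rows.append(
                    dict(subject=subject, voi=voi, metric=metric, median=np.nan,
                         iqr=np.nan, n_voxels=0, n_excluded=excl)
                )
    return pd.DataFrame(rows)


def group_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Group-level table: mean and SD across subjects of per-subject medians."""
    g = per_subject.groupby(["voi", "metric"])["median"]
    out = g.agg(mean="mean", sd="std", n_subjects="count").reset_index()
    return out
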