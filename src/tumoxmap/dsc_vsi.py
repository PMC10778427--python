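"""DSC perfusion and vessel-size imaging (VSI) mapping.

Dynamic susceptibility contrast (DSC) MRI follows a gadolinium bolus with
simultaneous gradient-echo (GRE, T2*-weighted) and spin-echo (SE,
T2-weighted) acquisitions.  Signal-time curves are converted to
relaxation-rate changes

    dR2(t) = -(1/TE) * ln(S(t) / S_baseline),

cerebral blood volume (CBV) is the trapezoidal integral of dR2*(t) over
the bolus passage normalised to the contralateral white-matter mean, and
mean vessel size follows the Kiselev model from the peak rate changes:

    vessel_size = 0.867 * (CBV * ADC)^(1/2) * dR2*_peak / dR2_peak^(3/2)

with ADC in mm^2/s and rates in s^-1, yielding mm (reported in um).

Contrast-agent extravasation through a disrupted blood-brain barrier
biases dR2*(t); the Boxerman-Schmainda-Weisskoff (BSW) correction fits
each voxel curve against a non-leaky reference curve and its running
integral and restores the leakage term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DscSeries",
    "BolusWindow",
    "PerfusionMaps",
    "delta_r2",
    "detect_bolus",
    "bsw_leakage_correct",
    "compute_cbv",
    "adc_from_dwi",
    "vessel_size_map",
    "perfusion_pipeline",
]


@dataclass
class DscSeries:
    """Paired GRE/SE dynamic series with acquisition metadata."""

    gre: np.ndarray
    se: np.ndarray
    tr_s: float
    te_gre_ms: float
    te_se_ms: float
    n_discard: int = 4
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.gre = np.asarray(self.gre, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.gre.shape != self.se.shape:
            raise ValueError("GRE and SE series must share grid and time axis")
        if self.gre.ndim != 4:
            raise ValueError("DSC series must be 4D (x, y, z, t)")
        if not (self.te_se_ms > self.te_gre_ms > 0):
            raise ValueError("require TE_se > TE_gre > 0")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def times_s(self) -> np.ndarray:
        """Time axis of the retained volumes (after discard), seconds."""
        n = self.gre.shape[-1] - self.n_discard
        return (np.arange(n) + self.n_discard) * self.tr_s


@dataclass(frozen=True)
class BolusWindow:
    """Bolus passage indices on the retained (post-discard) time axis."""

    t_in: int
    t_peak: int
    t_out: int
    baseline_range: tuple[int, int]  # half-open [start, stop)

    def __post_init__(self) -> None:
        if not (self.baseline_range[1] <= self.t_in):
            raise ValueError("baseline must precede bolus entrance")
        if not (self.t_in < self.t_peak <= self.t_out):
            raise ValueError("require t_in < t_peak <= t_out")


@dataclass
class PerfusionMaps:
    """Normalized CBV, vessel size and intermediate DSC quantities."""

    CBV: np.ndarray
    vessel_size: np.ndarray
    dR2star_peak: np.ndarray
    dR2_peak: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    ADC: np.ndarray | None = None


def delta_r2(
    signal: np.ndarray,
    baseline_range: tuple[int, int],
    te_ms: float,
    n_discard: int = 0,
) -> np.ndarray:
    """Convert a 4D magnitude series to dR2(t) = -ln(S/S_baseline)/TE.

    The first ``n_discard`` volumes are dropped before anything else
    (pre-steady-state), and ``baseline_range`` indexes the *retained*
    axis.  Non-positive samples are interpolated in time from their
    neighbours before the log.
    """
    s = np.asarray(signal, dtype=float)[..., n_discard:]
    nt = s.shape[-1]
    b0, b1 = baseline_range
    if not (0 <= b0 < b1 <= nt):
        raise ValueError("invalid baseline range")
    bad = ~(s > 0) | ~np.isfinite(s)
    if bad.any():
        s = s.copy()
        t = np.arange(nt, dtype=float)
        for idx in zip(*np.nonzero(bad.any(axis=-1))):
            row = s[idx]
            mask = (row > 0) & np.isfinite(row)
            if not mask.any():
                row[:] = np.nan
                continue
            row[~mask] = np.interp(t[~mask], t[mask], row[mask])
    s_base = s[..., b0:b1].mean(axis=-1)
    if np.any(s_base <= 0):
        s_base = np.where(s_base > 0, s_base, np.nan)
    te_s = te_ms / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.log(s / s_base[..., None]) / te_s


def detect_bolus(
    curve: np.ndarray,
    k: float = 3.0,
    min_sustain: int = 2,
    init_baseline: int = 8,
) -> BolusWindow:
    """Locate the bolus passage on a mean dR2* curve.

    Entrance is the first sample exceeding (baseline mean + k * baseline
    SD) sustained for ``min_sustain`` samples; exit is the first
    post-peak sample back below that threshold (else the last sample).
    A provisional baseline of the first ``init_baseline`` samples is
    refined once to [0, t_in - 2) after a first detection pass.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 30:
        raise ValueError("bolus curve needs at least 30 samples")

    def _pass(b0: int, b1: int) -> tuple[int, int, int, float]:
        bm = c[b0:b1].mean()
        bs = c[b0:b1].std()
        thr = bm + k * bs + 1e-12
        above = c > thr
        t_in = None
        for i in range(len(c) - min_sustain + 1):
            if above[i : i + min_sustain].all():
                t_in = i
                break
        if t_in is None:
            raise ValueError("no bolus detected")
        t_peak = t_in + int(np.argmax(c[t_in:]))
        t_out = len(c) - 1
        for i in range(t_peak + 1, len(c)):
            if c[i] < thr:
                t_out = i
                break
        return t_in, t_peak, t_out, thr

    t_in, t_peak, t_out, _ = _pass(0, init_baseline)
    b1 = max(2, t_in - 2)
    t_in, t_peak, t_out, _ = _pass(0, b1)
    b1 = max(2, t_in - 2)
    return BolusWindow(t_in=t_in, t_peak=t_peak, t_out=t_out, baseline_range=(0, b1))


def bsw_leakage_correct(
    dR2star: np.ndarray,
    times_s: np.ndarray,
    window: BolusWindow,
    reference_mask: np.ndarray | None = None,
    k2_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BSW leakage correction of a dR2*(t) series.

    Each voxel curve is fit by least squares to

        dR2*_voxel(t) ~ K1 * R(t) - K2 * int_0^t R(t') dt'

    where R(t) is the mean curve over the reference (non-leaky) mask.
    When no mask is given, a first pass over all finite-signal voxels
    estimates K2 and the reference is rebuilt from voxels with
    |K2| < ``k2_tol``.  The corrected curve adds the leakage term back:
    corrected = measured + K2 * int R.  Returns (corrected, K1, K2).
    """
    d = np.asarray(dR2star, dtype=float)
    finite = np.all(np.isfinite(d), axis=-1)
    if reference_mask is None:
        _, _, k2 = _bsw_fit(d, times_s, finite)
        reference_mask = finite & (np.abs(k2) < k2_tol)
        if not reference_mask.any():
            reference_mask = finite
    if not np.asarray(reference_mask).any():
        raise ValueError("reference mask is empty")
    return _bsw_fit(d, times_s, np.asarray(reference_mask, dtype=bool))


def _bsw_fit(
    d: np.ndarray, times_s: np.ndarray, reference_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = d[reference_mask].mean(axis=0)
    if not np.any(ref != 0):
        raise ValueError("degenerate (all-zero) reference curve")
    cum = cumulative_trapezoid(ref, times_s, initial=0.0)
    # closed-form 2x2 normal equations for [K1, -K2] against [ref, cum]
    a11 = ref @ ref
    a12 = ref @ cum
    a22 = cum @ cum
    det = a11 * a22 - a12 * a12
    y1 = d @ ref
    y2 = d @ cum
    if det <= 1e-300 * max(a11 * a22, 1.0):
        k1 = y1 / a11
        k2 = np.zeros_like(k1)
    else:
        k1 = (a22 * y1 - a12 * y2) / det
        neg_k2 = (-a12 * y1 + a11 * y2) / det
        k2 = -neg_k2
    corrected = d + k2[..., None] * cum
    return corrected, k1, k2


def compute_cbv(
    dR2star: np.ndarray,
    times_s: np.ndarray,
    window: BolusWindow,
    contra_wm_mask: np.ndarray,
) -> np.ndarray:
    """Trapezoidal bolus integral of dR2*(t), normalised to contra-WM.

    Integration runs from bolus entrance to exit; the map is divided by
    its mean over the contralateral white-matter mask so contra-WM
    averages exactly 1.
    """
    contra_wm_mask = np.asarray(contra_wm_mask, dtype=bool)
    if not contra_wm_mask.any():
        raise ValueError("contralateral WM mask is empty")
    sl = slice(window.t_in, window.t_out + 1)
    raw = np.trapezoid(dR2star[..., sl], times_s[sl], axis=-1)
    ref = raw[contra_wm_mask].mean()
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("contralateral WM reference integral is zero")
    return raw / ref


def adc_from_dwi(dwi: np.ndarray, b_values: np.ndarray) -> np.ndarray:
    """ADC (mm^2/s) as minus the OLS slope of ln S against b.

    Requires at least two distinct b-values including 0; voxels with
    non-positive signal at any b are returned as NaN.
    """
    b = np.asarray(b_values, dtype=float)
    if b.min() != 0 or np.unique(b).size < 2:
        raise ValueError("b-values must include 0 and at least one other value")
    if np.any(b < 0):
        raise ValueError("negative b-values are not allowed")
    d = np.asarray(dwi, dtype=float)
    valid = np.all(d > 0, axis=-1) & np.all(np.isfinite(d), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnS = np.where(valid[..., None], np.log(np.where(d > 0, d, 1.0)), 0.0)
    bc = b - b.mean()
    denom = np.sum(bc**2)
    slope = np.sum((lnS - lnS.mean(axis=-1, keepdims=True)) * bc, axis=-1) / denom
    adc = -slope
    adc[~valid] = np.nan
    return adc


def vessel_size_map(
    cbv: np.ndarray,
    adc: np.ndarray,
    dR2star_peak: np.ndarray,
    dR2_peak: np.ndarray,
    cbv_floor: float = 0.05,
) -> np.ndarray:
    """Kiselev-model mean vessel size (um).

    vessel_size = 0.867*sqrt(CBV*ADC)*dR2*_peak/dR2_peak^1.5, evaluated
    where dR2_peak > 0 and normalised CBV exceeds ``cbv_floor`` (guards
    the 0/0 regime in avascular voxels); elsewhere NaN.  The bare
    formula yields mm with ADC in mm^2/s; the returned map is in um.
    """
    cbv = np.asarray(cbv, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vs_mm = 0.867 * np.sqrt(cbv * adc) * dR2star_peak / dR2_peak**1.5
    vs = vs_mm * 1000.0
    bad = ~(dR2_peak > 0) | ~(cbv > cbv_floor) | ~np.isfinite(vs)
    vs = np.where(bad, np.nan, vs)
    return vs


def perfusion_pipeline(
    series: DscSeries,
    dwi: np.ndarray | None,
    b_values: np.ndarray | None,
    contra_wm_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
    adc: np.ndarray | None = None,
    cbv_floor: float = 0.05,
) -> PerfusionMaps:
    """Full DSC/VSI chain: dR2 conversion, bolus detection, BSW, CBV, VS.

    The bolus window is detected once on the brain-mean GRE dR2* curve;
    peaks are taken within the window from the leakage-corrected GRE
    curve and the raw SE curve.  ``adc`` may be supplied directly in
    place of DWI data.
    """
    if brain_mask is None:
        brain_mask = series.gre[..., 0] > 0
    # provisional conversion with an initial baseline to locate the bolus
    prov = delta_r2(series.gre, (0, 8), series.te_gre_ms, series.n_discard)
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(prov[brain_mask], axis=0)
    window = detect_bolus(mean_curve)

    dr2s = delta_r2(series.gre, window.baseline_range, series.te_gre_ms, series.n_discard)
    dr2 = delta_r2(series.se, window.baseline_range, series.te_se_ms, series.n_discard)
    times = series.times_s

    ref_mask = reference_mask if reference_mask is not None else None
    corrected, k1, k2 = bsw_leakage_correct(dr2s, times, window, ref_mask)

    cbv = compute_cbv(corrected, times, window, contra_wm_mask)
    sl = slice(window.t_in, window.t_out + 1)
    p_star = corrected[..., sl].max(axis=-1)
    p_se = dr2[..., sl].max(axis=-1)

    if adc is None:
        if dwi is None or b_values is None:
            raise ValueError("either adc or (dwi, b_values) must be provided")
        adc = adc_from_dwi(dwi, b_values)
    vs = vessel_size_map(cbv, adc, p_star, p_se, cbv_floor)
    return PerfusionMaps(
        CBV=cbv, vessel_size=vs, dR2star_peak=p_star, dR2_peak=p_se, K1=k1, K2=k2, ADC=adc
    )
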