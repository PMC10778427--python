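"""Streamlined qBOLD (sqBOLD) model fitting for FLAIR-ASE data.

The asymmetric spin echo (ASE) sequence displaces the spin echo from the
echo time by a shift tau, sensitising the signal to the reversible
transverse relaxation rate R2' caused by mesoscopic field perturbations
around deoxygenated vessels.  With FLAIR preparation suppressing CSF, the
log-signal follows a piecewise model in tau:

    ln S(tau) = ln S0 - R2*TE - 0.3*(R2'*tau)**2 / DBV      tau <  tau_c
    ln S(tau) = ln S0 - R2*TE + DBV - R2'*tau               tau >= tau_c

where DBV is the deoxygenated blood volume fraction and tau_c is the
transition between the quadratic (short-tau) and linear (long-tau)
regimes, fixed at 16 ms.  The oxygen extraction fraction follows from

    OEF = 3*R2' / (4*pi * gamma * B0 * dchi0 * Hct * DBV)

with gamma the proton gyromagnetic ratio, B0 the field strength, dchi0
the susceptibility difference between fully oxygenated and deoxygenated
red cells, and Hct the hematocrit.

Two estimators are provided: a closed-form log-linear fit using tau = 0
and the linear-regime points (tau >= tau_c), and a bounded nonlinear
least-squares fit of the full piecewise model initialised from the
log-linear solution.  Voxels whose signal is inconsistent with the model
are collected into a binary error mask and zeroed in all parameter maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "TAUS_MS_DEFAULT",
    "QBoldConstants",
    "AseSeries",
    "QBoldMaps",
    "FailureThresholds",
    "log_signal",
    "fit_loglinear",
    "fit_nonlinear",
    "compute_oef",
    "classify_failures",
    "fit_qbold",
]

#: ASE shift scheme (ms): tau = 0 then 16..60 ms in steps of 4 ms.
TAUS_MS_DEFAULT: tuple[float, ...] = (
    0.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0, 40.0, 44.0, 48.0, 52.0, 56.0, 60.0,
)


@dataclass(frozen=True)
class QBoldConstants:
    """Physical constants entering the OEF calculation.

    gamma : proton gyromagnetic ratio, rad T^-1 s^-1
    B0 : main field strength, T
    delta_chi0_ppm : susceptibility difference between fully oxygenated
        and fully deoxygenated red blood cells, ppm (cgs convention; the
        4*pi cgs->SI factor appears explicitly in the OEF formula)
    Hct : hematocrit fraction
    tau_c_ms : quadratic/linear transition shift, ms
    """

    gamma: float = 267.5e6
    B0: float = 3.0
    delta_chi0_ppm: float = 0.264
    Hct: float = 0.4
    tau_c_ms: float = 16.0

    def __post_init__(self) -> None:
        for name in ("gamma", "B0", "delta_chi0_ppm", "Hct", "tau_c_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QBoldConstants.{name} must be positive")

    @property
    def oef_denominator_scale(self) -> float:
        """4*pi*gamma*B0*dchi0*Hct with dchi0 in absolute units (s^-1)."""
        return 4.0 * np.pi * self.gamma * self.B0 * self.delta_chi0_ppm * 1e-6 * self.Hct


@dataclass
class AseSeries:
    """A 4D FLAIR-ASE magnitude acquisition with its tau-shift axis.

    data : array (x, y, z, n_tau) of non-negative magnitudes
    taus_ms : strictly increasing shifts, first element 0
    te_ms : echo time
    ti_ms : inversion time (metadata only)
    affine : 4x4 voxel-to-world mapping
    """

    data: np.ndarray
    taus_ms: np.ndarray
    te_ms: float
    ti_ms: float | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.taus_ms = np.asarray(self.taus_ms, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("AseSeries.data must be 4D (x, y, z, tau)")
        if self.data.shape[-1] != self.taus_ms.size:
            raise ValueError("tau axis length mismatch between data and taus_ms")
        if self.taus_ms[0] != 0.0:
            raise ValueError("taus_ms must start at 0")
        if np.any(np.diff(self.taus_ms) <= 0):
            raise ValueError("taus_ms must be strictly increasing")
        if np.any(self.taus_ms[1:] <= 0):
            raise ValueError("tau values other than the first must be positive")
        if self.te_ms <= float(self.taus_ms.max()):
            raise ValueError("TE must exceed the largest tau shift")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("magnitude data must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class QBoldMaps:
    """Voxel-wise sqBOLD parameter maps plus fit bookkeeping.

    ``baseline_ln`` holds the nuisance combination ln(S0) - R2*TE, the
    only form in which proton density and R2 are identifiable from a
    single-TE ASE acquisition.
    """

    R2prime: np.ndarray
    DBV: np.ndarray
    OEF: np.ndarray
    baseline_ln: np.ndarray
    fit_residual: np.ndarray
    error_mask: np.ndarray
    evaluated: np.ndarray


@dataclass(frozen=True)
class FailureThresholds:
    """Criteria used to mark sqBOLD failure voxels.

    residual_frac : flag when the RMS fit residual exceeds this fraction
        of the voxel's ln-signal range.
    dbv_max : upper admissible DBV (fraction).
    smooth_radius : optional uniform smoothing (in tau samples) applied
        before locating the signal peak.
    """

    residual_frac: float = 0.05
    dbv_max: float = 0.5
    smooth_radius: int = 0


def log_signal(series: AseSeries) -> np.ndarray:
    """Natural log of the magnitude signal; non-positive samples -> NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(series.data)
    out[~np.isfinite(out)] = np.nan
    return out


def _evaluation_mask(series: AseSeries, signal_floor_frac: float) -> np.ndarray:
    """Voxels with usable signal: tau=0 magnitude above an intensity floor."""
    s0 = series.data[..., 0]
    robust_max = np.percentile(s0[np.isfinite(s0)], 98)
    floor = signal_floor_frac * robust_max
    return np.isfinite(s0) & (s0 > floor) & np.all(np.isfinite(series.data), axis=-1)


def compute_oef(
    R2prime: np.ndarray | float,
    DBV: np.ndarray | float,
    consts: QBoldConstants = QBoldConstants(),
) -> np.ndarray | float:
    """Oxygen extraction fraction from R2' (s^-1) and DBV (fraction).

    OEF = 3*R2' / (4*pi*gamma*B0*dchi0*Hct*DBV).  The result is a
    fraction and is *not* clamped to [0, 1]; physiologically impossible
    values are left for the error-mask logic to flag.  R2' = 0 yields
    OEF = 0 regardless of DBV (including the degenerate flat-signal case
    DBV = 0); DBV <= 0 with R2' != 0 is undefined (NaN).
    """
    r2p = np.asarray(R2prime, dtype=float)
    dbv = np.asarray(DBV, dtype=float)
    # snap sub-machine-noise estimates (exactly flat signals fit to ~1e-30)
    r2p = np.where(np.abs(r2p) < 1e-12, 0.0, r2p)
    dbv = np.where(np.abs(dbv) < 1e-12, 0.0, dbv)
    k = consts.oef_denominator_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        oef = 3.0 * r2p / (k * dbv)
    oef = np.where(r2p == 0.0, 0.0, oef)
    oef = np.where((dbv <= 0) & (r2p != 0.0), np.nan, oef)
    if np.isscalar(R2prime) and np.isscalar(DBV):
        return float(oef)
    return oef


def fit_loglinear(
    series: AseSeries,
    consts: QBoldConstants = QBoldConstants(),
    signal_floor_frac: float = 0.05,
) -> QBoldMaps:
    """Closed-form sqBOLD fit from the linear regime.

    Ordinary least squares of ln S against tau over the samples with
    tau >= tau_c gives slope -R2' and intercept c = ln S0 - R2*TE + DBV;
    the tau = 0 sample supplies ln S0 - R2*TE directly, so
    DBV = c - ln S(0).  Exact on noiseless model data because every
    fitted point then lies on the linear branch.
    """
    taus_s = series.taus_ms / 1000.0
    lin = series.taus_ms >= consts.tau_c_ms
    if lin.sum() < 3:
        raise ValueError("need at least 3 tau samples with tau >= tau_c")

    eval_mask = _evaluation_mask(series, signal_floor_frac)
    lnS = log_signal(series)

    t = taus_s[lin]
    y = np.where(eval_mask[..., None], lnS[..., lin], 0.0)
    t_mean = t.mean()
    y_mean = np.mean(y, axis=-1)
    tc = t - t_mean
    denom = np.sum(tc**2)
    slope = np.sum((y - y_mean[..., None]) * tc, axis=-1) / denom
    intercept = y_mean - slope * t_mean

    r2p = -slope
    baseline = lnS[..., 0]
    dbv = intercept - baseline
    oef = compute_oef(r2p, dbv, consts)

    fitted = intercept[..., None] + slope[..., None] * t
    residual = np.sqrt(np.mean((y - fitted) ** 2, axis=-1))

    nan = np.full(series.shape, np.nan)
    maps = QBoldMaps(
        R2prime=np.where(eval_mask, r2p, nan),
        DBV=np.where(eval_mask, dbv, nan),
        OEF=np.where(eval_mask, oef, nan),
        baseline_ln=np.where(eval_mask, baseline, nan),
        fit_residual=np.where(eval_mask, residual, nan),
        error_mask=np.zeros(series.shape, dtype=bool),
        evaluated=eval_mask,
    )
    return maps


def _piecewise_lnsignal(params: np.ndarray, taus_s: np.ndarray, tau_c_s: float) -> np.ndarray:
    base, r2p, dbv = params
    quad = taus_s < tau_c_s
    out = np.empty_like(taus_s)
    out[quad] = base - 0.3 * (r2p * taus_s[quad]) ** 2 / dbv
    out[~quad] = base + dbv - r2p * taus_s[~quad]
    return out


def fit_nonlinear(
    series: AseSeries,
    consts: QBoldConstants = QBoldConstants(),
    init: QBoldMaps | None = None,
    signal_floor_frac: float = 0.05,
    r2p_bounds: tuple[float, float] = (0.0, 100.0),
    dbv_bounds: tuple[float, float] = (1e-6, 0.5),
) -> QBoldMaps:
    """Bounded nonlinear least-squares fit of the full piecewise model.

    Fits (ln S0 - R2*TE, R2', DBV) per voxel over both tau regimes, with
    the tau = tau_c sample assigned to the linear branch.  Initialised
    from :func:`fit_loglinear` (clipped into bounds) unless ``init`` is
    given.  Voxels where the optimiser fails are flagged in the error
    mask rather than raising.
    """
    if init is None:
        init = fit_loglinear(series, consts, signal_floor_frac)
    taus_s = series.taus_ms / 1000.0
    tau_c_s = consts.tau_c_ms / 1000.0
    lnS = log_signal(series)

    maps = QBoldMaps(
        R2prime=init.R2prime.copy(),
        DBV=init.DBV.copy(),
        OEF=init.OEF.copy(),
        baseline_ln=init.baseline_ln.copy(),
        fit_residual=init.fit_residual.copy(),
        error_mask=init.error_mask.copy(),
        evaluated=init.evaluated.copy(),
    )

    lo = np.array([-np.inf, r2p_bounds[0], dbv_bounds[0]])
    hi = np.array([np.inf, r2p_bounds[1], dbv_bounds[1]])
    voxels = np.argwhere(init.evaluated)
    for ix, iy, iz in voxels:
        y = lnS[ix, iy, iz]
        if not np.all(np.isfinite(y)):
            maps.error_mask[ix, iy, iz] = True
            continue
        x0 = np.array(
            [
                init.baseline_ln[ix, iy, iz],
                np.clip(init.R2prime[ix, iy, iz], lo[1], hi[1]),
                np.clip(init.DBV[ix, iy, iz], lo[2], hi[2]),
            ]
        )
        if not np.all(np.isfinite(x0)):
            maps.error_mask[ix, iy, iz] = True
            continue
        try:
            sol = least_squares(
                lambda p: _piecewise_lnsignal(p, taus_s, tau_c_s) - y,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=200,
            )
        except Exception:
            maps.error_mask[ix, iy, iz] = True
            continue
        if not sol.success:
            maps.error_mask[ix, iy, iz] = True
            continue
        base, r2p, dbv = sol.x
        maps.baseline_ln[ix, iy, iz] = base
        maps.R2prime[ix, iy, iz] = r2p
        maps.DBV[ix, iy, iz] = dbv
        maps.OEF[ix, iy, iz] = compute_oef(r2p, dbv, consts)
        maps.fit_residual[ix, iy, iz] = np.sqrt(np.mean(sol.fun**2))
    return maps


def classify_failures(
    series: AseSeries,
    maps: QBoldMaps,
    thresholds: FailureThresholds = FailureThresholds(),
    consts: QBoldConstants = QBoldConstants(),
) -> np.ndarray:
    """Build the sqBOLD error mask and zero flagged voxels in all maps.

    A voxel is flagged when any of the following hold:

    * the (optionally smoothed) signal attains its maximum at a shift
      strictly beyond tau_c.  Under the piecewise model the ln-signal
      maximum can only occur at tau = 0 or — when DBV > R2'*tau_c, which
      the fitted tissue values readily allow — at the first
      linear-regime sample tau = tau_c, because the linear branch
      strictly decreases.  A peak beyond tau_c (e.g. the shifted-peak
      behaviour seen in some metastases) cannot arise from the model.
    * fitted parameters are non-finite, R2' < 0, DBV < 0,
      DBV > ``dbv_max``, or DBV = 0 with non-zero R2';
    * the normalised RMS fit residual exceeds ``residual_frac`` of the
      voxel's ln-signal range;
    * the voxel was excluded from evaluation (sub-floor signal).

    Flagged voxels are zeroed in R2prime/DBV/OEF/baseline maps, matching
    the convention of zeroing out failure voxels in displayed maps.
    Returns the boolean error mask (also stored on ``maps``).
    """
    sig = series.data
    if thresholds.smooth_radius > 0:
        size = 2 * thresholds.smooth_radius + 1
        sig = ndimage.uniform_filter1d(sig, size=size, axis=-1, mode="nearest")
    peak_tau = series.taus_ms[np.argmax(sig, axis=-1)]
    flagged = peak_tau > consts.tau_c_ms

    r2p, dbv = maps.R2prime, maps.DBV
    with np.errstate(invalid="ignore"):
        tol = 1e-12  # ignore machine-noise negatives from exactly flat fits
        flagged |= ~np.isfinite(r2p) | ~np.isfinite(dbv)
        flagged |= np.nan_to_num(r2p, nan=-1.0) < -tol
        flagged |= np.nan_to_num(dbv, nan=-1.0) < -tol
        flagged |= np.nan_to_num(dbv, nan=0.0) > thresholds.dbv_max
        flagged |= (np.abs(np.nan_to_num(dbv, nan=0.0)) <= tol) & (
            np.nan_to_num(r2p, nan=0.0) > tol
        )

        if thresholds.residual_frac is not None:
            lnS = np.where(maps.evaluated[..., None], log_signal(series), 0.0)
            rng = np.max(lnS, axis=-1) - np.min(lnS, axis=-1)
            norm_res = maps.fit_residual / np.maximum(rng, 1e-12)
            flagged |= np.nan_to_num(norm_res, nan=np.inf) > thresholds.residual_frac

    flagged |= ~maps.evaluated

    for arr in (maps.R2prime, maps.DBV, maps.OEF, maps.baseline_ln, maps.fit_residual):
        arr[flagged] = 0.0
    maps.error_mask = flagged
    return flagged


def fit_qbold(
    series: AseSeries,
    method: str = "loglinear",
    consts: QBoldConstants = QBoldConstants(),
    thresholds: FailureThresholds = FailureThresholds(),
    classify: bool = True,
    signal_floor_frac: float = 0.05,
) -> QBoldMaps:
    """Fit the sqBOLD model and (optionally) apply failure classification."""
    if method == "loglinear":
        maps = fit_loglinear(series, consts, signal_floor_frac)
    elif method in ("nls", "nonlinear"):
        maps = fit_nonlinear(series, consts, signal_floor_frac=signal_floor_frac)
    else:
        raise ValueError(f"unknown qBOLD fit method: {method!r}")
    if classify:
        classify_failures(series, maps, thresholds, consts)
    return maps
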