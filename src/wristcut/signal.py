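"""Accelerometer and gas-exchange signal processing.

Turns raw 30-Hz tri-axial acceleration, 5-s epoch activity counts and
15-s gas-exchange series into the windowed trial features used for
classification: autocalibration to local gravity, ENMO, vector
magnitude, analysis-window extraction and the steady-state check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationParams",
    "EpochSeries",
    "TrialFeatures",
    "IDENTITY_CALIBRATION",
    "autocalibrate",
    "apply_calibration",
    "compute_enmo",
    "vector_magnitude",
    "extract_window",
    "steady_state_check",
    "summarize_trial",
]

FS_HZ = 30.0  # raw sampling rate

# Analysis windows, seconds from trial start, half-open [start, stop).
# Standard activities use minutes 2.5-4.5; the longer lying-down trial
# uses minutes 7.0-9.0.
WINDOW_DEFAULT = (150.0, 270.0)
WINDOW_LYING = (420.0, 540.0)

# Steady-state tolerances within the analysis window.
HR_TOLERANCE_BPM = 5.0
VO2_TOLERANCE_FRACTION = 0.10

# Autocalibration defaults: still windows are 10-s segments with per-axis
# SD below 13 milli-g; the sphere fit needs enough of them, spread over
# enough of the sphere, to be identifiable.
STILL_WINDOW_S = 10.0
STILL_SD_G = 0.013
MIN_STILL_WINDOWS = 10
SPHERE_COVERAGE_G = 0.3


@dataclass(frozen=True)
class CalibrationParams:
    """Per-axis gain/offset mapping device units onto the unit gravity sphere.

    Calibrated acceleration is ``raw * gain + offset``.  ``residual`` is the
    mean absolute deviation of still-window norms from 1 g after
    calibration.  If the fit could not be attempted or did not converge,
    identity parameters are returned with ``converged=False``.
    """

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    converged: bool = False
    residual: float = 0.0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gains must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    @property
    def implied_distortion(self) -> tuple[np.ndarray, np.ndarray]:
        """The device distortion these parameters undo.

        If the device reported ``g_err * a + o_err`` for true acceleration
        ``a``, the fitted calibration satisfies ``gain = 1/g_err`` and
        ``offset = -o_err/g_err``; this property returns ``(g_err, o_err)``.
        """
        gain = np.asarray(self.gain)
        offset = np.asarray(self.offset)
        return 1.0 / gain, -offset / gain


IDENTITY_CALIBRATION = CalibrationParams()


@dataclass(frozen=True)
class EpochSeries:
    """Values on a regular, half-open epoch grid [t, t + epoch_length)."""

    epoch_length: float
    starts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("epoch starts must be strictly increasing")
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values must have equal length")


@dataclass(frozen=True)
class TrialFeatures:
    """Windowed summary of one activity trial, per wrist side."""

    participant_id: str
    activity_code: str
    mean_va: dict = field(default_factory=dict)  # side -> counts/5 s
    mean_vm: dict = field(default_factory=dict)  # side -> counts/5 s
    mean_enmo: dict = field(default_factory=dict)  # side -> milli-g
    mean_vo2: float = float("nan")  # ml/min
    steady_state: bool = False


def vector_magnitude(va, ml, ap):
    """Euclidean norm of the three per-axis activity counts."""
    va = np.asarray(va, dtype=float)
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if np.any(va < 0) or np.any(ml < 0) or np.any(ap < 0):
        raise ValueError("activity counts must be non-negative")
    return np.sqrt(va**2 + ml**2 + ap**2)


def apply_calibration(raw: np.ndarray, params: CalibrationParams) -> np.ndarray:
    """Apply per-axis gain and offset to an (n, 3) raw series."""
    return raw * np.asarray(params.gain) + np.asarray(params.offset)


def _still_window_means(raw: np.ndarray, fs: float, window_s: float,
                        sd_threshold_g: float) -> np.ndarray:
    n_per = int(round(window_s * fs))
    n_win = raw.shape[0] // n_per
    if n_win == 0:
        return np.empty((0, 3))
    segs = raw[: n_win * n_per].reshape(n_win, n_per, 3)
    sd = segs.std(axis=1)
    still = np.all(sd < sd_threshold_g, axis=1)
    return segs[still].mean(axis=1)


def autocalibrate(
    raw: np.ndarray,
    fs: float = FS_HZ,
    still_sd_g: float = STILL_SD_G,
    window_s: float = STILL_WINDOW_S,
    min_windows: int = MIN_STILL_WINDOWS,
    coverage_g: float = SPHERE_COVERAGE_G,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CalibrationParams:
    """Estimate per-axis gain/offset from still periods of a raw series.

    Low-movement windows (per-axis SD below ``still_sd_g``) should lie on
    the unit gravity sphere; an iterative weighted least-squares sphere
    fit estimates the gain and offset that put them there.  If fewer than
    ``min_windows`` still windows exist, or their orientations do not
    cover the sphere (no axis reaching +/- ``coverage_g``), the fit is not
    identifiable and identity parameters are returned with
    ``converged=False``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw must be an (n, 3) array")
    if raw.shape[0] < 60 * fs:
        raise ValueError("autocalibration needs at least 60 s of signal")

    points = _still_window_means(raw, fs, window_s, still_sd_g)
    if points.shape[0] < min_windows:
        return IDENTITY_CALIBRATION
    if np.any(points.min(axis=0) > -coverage_g) or np.any(points.max(axis=0) < coverage_g):
        return IDENTITY_CALIBRATION

    scale = np.ones(3)
    offset = np.zeros(3)
    prev_res = np.inf
    converged = False
    res = np.inf
    for _ in range(max_iter):
        cur = points * scale + offset
        norms = np.linalg.norm(cur, axis=1)
        res = float(np.mean(np.abs(norms - 1.0)))
        if abs(prev_res - res) < tol:
            converged = True
            break
        prev_res = res
        target = cur / norms[:, None]
        for ax in range(3):
            # closest-point regression per axis: target ~ b0 + b1 * cur
            A = np.column_stack([np.ones(len(cur)), cur[:, ax]])
            b0, b1 = np.linalg.lstsq(A, target[:, ax], rcond=None)[0]
            scale[ax] *= b1
            offset[ax] = offset[ax] * b1 + b0
    if not converged:
        return IDENTITY_CALIBRATION
    return CalibrationParams(gain=tuple(scale), offset=tuple(offset),
                             converged=True, residual=res)


def compute_enmo(raw: np.ndarray, fs: float = FS_HZ,
                 epoch_length: float = 1.0) -> EpochSeries:
    """Euclidean norm minus one of a calibrated series, per epoch, in milli-g.

    Per sample: ``max(0, ||a|| - 1)`` (negative values are clipped to
    zero, correcting for static gravity); averaged over ``epoch_length``
    epochs and scaled to milli-g.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw must be an (n, 3) array")
    enmo = np.maximum(np.linalg.norm(raw, axis=1) - 1.0, 0.0)
    n_per = int(round(epoch_length * fs))
    n_ep = len(enmo) // n_per
    values = enmo[: n_ep * n_per].reshape(n_ep, n_per).mean(axis=1) * 1000.0
    starts = np.arange(n_ep) * epoch_length
    return EpochSeries(epoch_length=epoch_length, starts=starts, values=values)


def extract_window(activity_code: str, duration_s: float) -> tuple[float, float]:
    """Analysis window [start, stop) in seconds for one trial.

    Minutes 2.5-4.5 for all activities except lying down (``"LD"``),
    which uses minutes 7.0-9.0 of its longer protocol.
    """
    window = WINDOW_LYING if activity_code == "LD" else WINDOW_DEFAULT
    if duration_s < window[1]:
        raise ValueError(
            f"trial of {duration_s:.0f} s does not cover the analysis "
            f"window ending at {window[1]:.0f} s"
        )
    return window


def steady_state_check(
    hr: np.ndarray,
    vo2: np.ndarray,
    hr_tol_bpm: float = HR_TOLERANCE_BPM,
    vo2_tol_frac: float = VO2_TOLERANCE_FRACTION,
) -> bool:
    """True iff HR and VO2 are stable within tolerance over the window.

    HR may deviate at most ``hr_tol_bpm`` (default 5 bpm) from its window
    mean; VO2 at most ``vo2_tol_frac`` (default 10%) of its window mean.
    """
    hr = np.asarray(hr, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if hr.size < 2 or vo2.size < 2:
        raise ValueError("steady-state check needs at least 2 samples in the window")
    hr_ok = np.max(np.abs(hr - hr.mean())) <= hr_tol_bpm
    vo2_ok = np.max(np.abs(vo2 - vo2.mean())) <= vo2_tol_frac * vo2.mean()
    return bool(hr_ok and vo2_ok)


def _window_mean_epochs(starts: np.ndarray, values: np.ndarray,
                        window: tuple[float, float]) -> float:
    mask = (starts >= window[0]) & (starts < window[1])
    if not np.any(mask):
        raise ValueError("no epochs fall inside the analysis window")
    return float(np.asarray(values)[mask].mean())


def summarize_trial(trial, calibration: dict | None = None) -> TrialFeatures:
    """Windowed feature summary of one trial recording.

    Parameters
    ----------
    trial : wristcut.synth.TrialRecording
        A recording with raw, counts and gas-exchange series per side.
    calibration : dict, optional
        ``{"left": CalibrationParams, "right": CalibrationParams}``; sides
        missing from the dict use identity calibration.

    Returns
    -------
    TrialFeatures
        Means of VA and VM counts per 5 s, ENMO (milli-g, from calibrated
        raw at 1-s epochs) per side, mean VO2 (ml/min), and the
        steady-state flag from heart rate and VO2 within the window.
    """
    calibration = calibration or {}
    duration = trial.duration_s
    window = extract_window(trial.activity_code, duration)

    mean_va: dict[str, float] = {}
    mean_vm: dict[str, float] = {}
    mean_enmo: dict[str, float] = {}
    for side in ("left", "right"):
        counts = trial.counts(side)
        if counts is not None:
            starts = counts[:, 0]
            va = counts[:, 1]
            vm = vector_magnitude(counts[:, 1], counts[:, 2], counts[:, 3])
            mean_va[side] = _window_mean_epochs(starts, va, window)
            mean_vm[side] = _window_mean_epochs(starts, vm, window)
        raw = trial.raw(side)
        if raw is not None:
            cal = calibration.get(side, IDENTITY_CALIBRATION)
            enmo = compute_enmo(apply_calibration(raw, cal))
            mean_enmo[side] = _window_mean_epochs(enmo.starts, enmo.values, window)

    gas_mask = (trial.gas_t >= window[0]) & (trial.gas_t < window[1])
    vo2_win = trial.vo2[gas_mask]
    hr_win = trial.hr[gas_mask]
    if vo2_win.size == 0:
        raise ValueError("no gas-exchange samples inside the analysis window")
    return TrialFeatures(
        participant_id=trial.participant_id,
        activity_code=trial.activity_code,
        mean_va=mean_va,
        mean_vm=mean_vm,
        mean_enmo=mean_enmo,
        mean_vo2=float(vo2_win.mean()),
        steady_state=steady_state_check(hr_win, vo2_win),
    )
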