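"""Synthetic laboratory cohort generator.

Emulates a calorimetry-referenced validation study: adolescents complete
12 structured activity trials while wearing tri-axial accelerometers on
both wrists and a portable calorimeter.  The generator produces, per
trial, raw 30-Hz acceleration for each wrist, 5-s epoch activity counts
(vertical axis / medio-lateral / anterior-posterior), and VO2 and heart
rate on a 15-s grid.

Trial-level distributions are anchored to the published descriptive
statistics for each activity: Youth METs are drawn from a truncated
normal with the reported mean and SD, and trial-mean VA counts, VM
counts and ENMO from (zero-inflated) lognormal distributions fitted to
the reported median and IQR.  Raw acceleration is gravity orientation
plus band-limited oscillation whose amplitude is tuned so that windowed
ENMO hits the drawn target.  Counts are simulated directly at epoch
level: the proprietary raw-to-counts filter is treated as given device
output, as validation studies themselves do.

Within a trial, energy expenditure and movement level are positively
coupled through a latent Gaussian copula (children who move more during
an activity expend more energy), and the two wrists are correlated
copies of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .config import RunConfig
from .energy import schofield_ree
from .signal import FS_HZ, compute_enmo, extract_window

__all__ = [
    "Participant",
    "ActivityProfile",
    "CalibrationError",
    "TrialRecording",
    "StudyDataset",
    "IDENTITY_ERROR",
    "ACTIVITY_CODES",
    "EXCLUSION_REASONS",
    "builtin_activity_profiles",
    "generate_participants",
    "generate_trial",
    "generate_cohort",
    "ZeroInflatedLognormal",
    "lognormal_from_quartiles",
]

ACTIVITY_CODES = ("LD", "CG", "HW", "LN", "TC", "SW", "CW", "DA", "FW", "TW", "BB", "RU")

EXCLUSION_REASONS = (
    "accelerometer_failure",
    "calorimeter_malfunction",
    "no_steady_state",
    "incomplete_trial",
)

_Z75 = 0.6744897501960817  # standard normal upper quartile
_Z23 = 0.43072729929545756  # standard normal 2/3 quantile
_EPOCH_S = 5.0
_GAS_STEP_S = 15.0
_SETTLE_S = 15.0  # quiet interval at trial start before activity begins
_RAMP_END_S = 45.0


@dataclass(frozen=True)
class Participant:
    id: str
    age: float  # years
    sex: str  # "male" | "female"
    mass: float  # kg
    height: float  # m
    handedness: str  # "left" | "right"

    def __post_init__(self) -> None:
        if not 8.0 <= self.age <= 18.0:
            raise ValueError(f"age {self.age} outside [8, 18]")
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("mass and height must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"unknown handedness {self.handedness!r}")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity generator targets: energy expenditure and movement metrics.

    ``met_mean``/``met_sd`` parameterize the Youth METs draw; the
    median/IQR pairs (counts per 5 s for VA and VM, milli-g for ENMO)
    parameterize the lognormal trial-mean draws.
    """

    code: str
    met_mean: float
    met_sd: float
    va_median: float
    va_iqr: tuple[float, float]
    vm_median: float
    vm_iqr: tuple[float, float]
    enmo_median: float
    enmo_iqr: tuple[float, float]
    posture: str  # "lying" | "sitting" | "upright"
    duration: float  # s

    def __post_init__(self) -> None:
        if self.code not in ACTIVITY_CODES:
            raise ValueError(f"unknown activity code {self.code!r}")
        if self.met_mean <= 0:
            raise ValueError("met_mean must be positive")
        if min(self.va_median, self.vm_median, self.enmo_median) < 0:
            raise ValueError("medians must be non-negative")
        if self.posture not in ("lying", "sitting", "upright"):
            raise ValueError(f"unknown posture {self.posture!r}")


def builtin_activity_profiles() -> list[ActivityProfile]:
    """The 12 structured activity trials with their reported statistics.

    Youth METs mean (SD) and median (IQR) of trial-mean VA counts/5 s,
    VM counts/5 s and ENMO (milli-g), per activity.  Postures: lying
    down is lying; handwriting and computer game are seated; all other
    activities are upright.  The lying-down trial lasts 10 min, every
    other trial 5 min.
    """
    rows = [
        # code, met_mean, met_sd, va_med, va_iqr, vm_med, vm_iqr, enmo_med, enmo_iqr, posture, dur
        ("LD", 1.3, 0.3, 0, (0, 20), 0, (0, 56), 21.3, (10.7, 25.1), "lying", 600.0),
        ("CG", 1.4, 0.2, 5, (0, 11), 22, (5, 37), 8.5, (1.8, 21.1), "sitting", 300.0),
        ("HW", 1.5, 0.2, 7, (2, 9), 35, (24, 56), 0.0, (0.0, 20.7), "sitting", 300.0),
        ("LN", 2.4, 0.4, 1039, (922, 1222), 1583, (1470, 1732), 290.1, (163.9, 334.2), "upright", 300.0),
        ("TC", 2.6, 0.7, 520, (459, 624), 923, (783, 1089), 55.9, (33.6, 83.6), "upright", 300.0),
        ("SW", 2.9, 0.5, 394, (307, 462), 573, (462, 622), 26.1, (18.9, 62.8), "upright", 300.0),
        ("CW", 3.7, 0.6, 250, (220, 287), 327, (287, 381), 67.6, (30.7, 101.2), "upright", 300.0),
        ("DA", 4.3, 0.8, 1663, (1310, 1903), 2151, (1962, 2418), 156.8, (130.0, 255.5), "upright", 300.0),
        ("FW", 4.7, 0.8, 294, (253, 335), 415, (364, 537), 119.5, (77.0, 181.0), "upright", 300.0),
        ("TW", 5.2, 0.9, 283, (213, 337), 393, (341, 521), 144.6, (96.5, 232.0), "upright", 300.0),
        ("BB", 7.2, 1.5, 1246, (1045, 1444), 1930, (1692, 2196), 450.2, (296.5, 598.0), "upright", 300.0),
        ("RU", 9.7, 2.3, 1392, (1156, 1477), 1804, (1595, 1983), 558.7, (396.5, 740.5), "upright", 300.0),
    ]
    return [
        ActivityProfile(code=c, met_mean=mm, met_sd=ms, va_median=float(vam),
                        va_iqr=(float(vaq[0]), float(vaq[1])), vm_median=float(vmm),
                        vm_iqr=(float(vmq[0]), float(vmq[1])), enmo_median=em,
                        enmo_iqr=eq, posture=post, duration=dur)
        for c, mm, ms, vam, vaq, vmm, vmq, em, eq, post, dur in rows
    ]


@dataclass(frozen=True)
class CalibrationError:
    """Per-axis device miscalibration applied to the true acceleration.

    Observed = ``gain * true + offset``; gains within [0.9, 1.1] and
    offsets within 0.1 g of zero.
    """

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(not 0.9 <= g <= 1.1 for g in self.gain):
            raise ValueError("gain outside [0.9, 1.1]")
        if any(abs(o) > 0.1 for o in self.offset):
            raise ValueError("offset magnitude above 0.1 g")


IDENTITY_ERROR = CalibrationError()


@dataclass
class TrialRecording:
    """Time-aligned signals for one participant x activity trial.

    ``raw_left``/``raw_right``: (n, 3) acceleration in g at 30 Hz.
    ``counts_left``/``counts_right``: (m, 4) arrays of
    [epoch_start_s, va, ml, ap] on half-open 5-s epochs.
    ``gas_t``/``vo2``/``hr``: 15-s grid (timestamps at period end),
    VO2 in ml/min, heart rate in bpm.
    """

    participant_id: str
    activity_code: str
    raw_left: np.ndarray | None
    raw_right: np.ndarray | None
    counts_left: np.ndarray | None
    counts_right: np.ndarray | None
    gas_t: np.ndarray
    vo2: np.ndarray
    hr: np.ndarray
    exclusion_flag: str | None = None

    def raw(self, side: str) -> np.ndarray | None:
        return self.raw_left if side == "left" else self.raw_right

    def counts(self, side: str) -> np.ndarray | None:
        return self.counts_left if side == "left" else self.counts_right

    @property
    def duration_s(self) -> float:
        if self.raw_left is not None:
            return self.raw_left.shape[0] / FS_HZ
        return float(self.gas_t[-1])


@dataclass
class StudyDataset:
    """A full simulated study: cohort, activity catalogue and recordings."""

    participants: list[Participant]
    profiles: list[ActivityProfile]
    trials: list[TrialRecording]
    config: RunConfig = field(default_factory=RunConfig)
    seed: int | None = None

    @property
    def profile_by_code(self) -> dict[str, ActivityProfile]:
        return {p.code: p for p in self.profiles}

    @property
    def n_scheduled(self) -> int:
        return len(self.trials)

    @property
    def retained(self) -> list[TrialRecording]:
        return [t for t in self.trials if t.exclusion_flag is None]


# ---------------------------------------------------------------------------
# trial-mean metric distributions


@dataclass(frozen=True)
class ZeroInflatedLognormal:
    """Lognormal with a point mass at zero, fitted to median and IQR."""

    p_zero: float
    mu: float
    sigma: float

    def ppf(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        pos = u > self.p_zero
        if self.sigma > 0:
            v = (u[pos] - self.p_zero) / (1.0 - self.p_zero)
            out[pos] = np.exp(self.mu + self.sigma * ndtri(v))
        return out

    @property
    def median(self) -> float:
        return float(self.ppf(np.array(0.5)))


def lognormal_from_quartiles(median: float, q25: float, q75: float,
                             zero_sigma: float = 0.5) -> ZeroInflatedLognormal:
    """Fit a (zero-inflated) lognormal to a reported median and IQR.

    Non-negative, right-skewed trial means call for a lognormal.  Three
    regimes:

    * positive quartiles: ``mu = ln(median)`` and sigma solves the IQR
      width equation ``q75 - q25 = 2 median sinh(z75 sigma)``;
    * zero lower quartile with positive median: zero inflation 0.25, with
      ``(mu, sigma)`` matching the median and upper quartile of the mixture;
    * zero median: zero inflation 0.5, lognormal median at the reported
      upper quartile and spread ``zero_sigma``.
    """
    if median < 0 or q25 < 0 or q75 < q25:
        raise ValueError("need 0 <= q25 <= q75 and median >= 0")
    if median <= 0:
        if q75 <= 0:
            return ZeroInflatedLognormal(1.0, 0.0, 0.0)
        return ZeroInflatedLognormal(0.5, math.log(q75), zero_sigma)
    if q25 <= 0:
        sigma = math.log(q75 / median) / (2.0 * _Z23)
        mu = math.log(median) + _Z23 * sigma
        return ZeroInflatedLognormal(0.25, mu, sigma)
    sigma = math.asinh((q75 - q25) / (2.0 * median)) / _Z75
    return ZeroInflatedLognormal(0.0, math.log(median), sigma)


# ---------------------------------------------------------------------------
# participants


# Reference median body mass (kg) and height (m) by integer age, used to
# make predicted REE realistic; values approximate growth-chart medians.
_REF_AGES = np.arange(8, 19)
_REF_MASS = {
    "male": np.array([25.6, 28.6, 31.9, 35.7, 40.6, 45.8, 51.0, 56.3, 60.9, 64.4, 66.9]),
    "female": np.array([25.8, 29.1, 32.9, 37.0, 41.5, 45.8, 49.4, 52.0, 53.9, 55.1, 56.2]),
}
_REF_HEIGHT = {
    "male": np.array([1.280, 1.335, 1.385, 1.435, 1.490, 1.560, 1.635, 1.695, 1.730, 1.750, 1.760]),
    "female": np.array([1.275, 1.330, 1.385, 1.440, 1.510, 1.570, 1.600, 1.620, 1.625, 1.630, 1.630]),
}
_MASS_LOG_SD = 0.13
_HEIGHT_LOG_SD = 0.04

AGE_MEAN = 14.6
AGE_SD = 2.4
AGE_RANGE = (8.0, 18.0)


def generate_participants(n: int, seed: int,
                          male_fraction: float = 10.0 / 18.0,
                          handedness_p_right: float = 0.9) -> list[Participant]:
    """Draw a cohort of ``n`` participants.

    Ages are normal(14.6, 2.4) truncated to [8, 18]; the sex split is the
    configured ratio applied deterministically then shuffled; mass and
    height come from age- and sex-indexed reference medians with
    lognormal spread; handedness is right with probability 0.9.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a = (AGE_RANGE[0] - AGE_MEAN) / AGE_SD
    b = (AGE_RANGE[1] - AGE_MEAN) / AGE_SD
    ages = truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng)
    n_male = int(round(n * male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    out = []
    for i in range(n):
        sex = str(sexes[i])
        mass_med = float(np.interp(ages[i], _REF_AGES, _REF_MASS[sex]))
        height_med = float(np.interp(ages[i], _REF_AGES, _REF_HEIGHT[sex]))
        mass = mass_med * math.exp(_MASS_LOG_SD * rng.standard_normal())
        height = height_med * math.exp(_HEIGHT_LOG_SD * rng.standard_normal())
        handed = "right" if rng.random() < handedness_p_right else "left"
        out.append(Participant(id=f"P{i + 1:02d}", age=float(ages[i]), sex=sex,
                               mass=mass, height=height, handedness=handed))
    return out


# ---------------------------------------------------------------------------
# raw-signal synthesis


def _orientation_path(n: int, rng: np.random.Generator) -> np.ndarray:
    """Slowly drifting unit gravity vector, random base orientation."""
    base = rng.standard_normal(3)
    base /= np.linalg.norm(base)
    sos = sp_signal.butter(2, 0.03, "lowpass", fs=FS_HZ, output="sos")
    drift = sp_signal.sosfilt(sos, rng.standard_normal((n, 3)), axis=0)
    rms = np.sqrt(np.mean(drift**2)) or 1.0
    drift *= 0.05 / rms
    u = base[None, :] + drift
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _movement_basis(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited (0.3-4 Hz) oscillation with random axis mix."""
    sos = sp_signal.butter(2, (0.3, 4.0), "bandpass", fs=FS_HZ, output="sos")
    m = sp_signal.sosfilt(sos, rng.standard_normal((n, 3)), axis=0)
    m *= rng.uniform(0.4, 1.0, size=3)
    rms = np.sqrt(np.mean(np.sum(m**2, axis=1)))
    return m / (rms or 1.0)


def _envelope(n: int) -> np.ndarray:
    """Activity envelope: quiet settle-in, ramp to full amplitude."""
    t = np.arange(n) / FS_HZ
    env = np.clip((t - _SETTLE_S) / (_RAMP_END_S - _SETTLE_S), 0.0, 1.0)
    return env


def _window_enmo_mg(sig: np.ndarray) -> float:
    return float(compute_enmo(sig).values.mean())


def _synth_raw(duration: float, target_enmo_mg: float, window: tuple[float, float],
               rng: np.random.Generator, device_noise_g: float) -> np.ndarray:
    n = int(round(duration * FS_HZ))
    u = _orientation_path(n, rng)
    m = _movement_basis(n, rng)
    env = _envelope(n)[:, None]
    noise = device_noise_g * rng.standard_normal((n, 3))
    i0, i1 = int(window[0] * FS_HZ), int(window[1] * FS_HZ)
    u_w, m_w, env_w, noise_w = u[i0:i1], m[i0:i1], env[i0:i1], noise[i0:i1]

    def win_enmo(amp: float) -> float:
        return _window_enmo_mg(u_w + amp * env_w * m_w + noise_w)

    amp = 0.0
    if win_enmo(0.0) < target_enmo_mg:
        lo, hi = 0.0, 8.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if win_enmo(mid) < target_enmo_mg:
                lo = mid
            else:
                hi = mid
        amp = 0.5 * (lo + hi)
    return u + amp * env * m + noise


def _epoch_counts(duration: float, va_mean: float, vm_mean: float,
                  window: tuple[float, float], rng: np.random.Generator,
                  epoch_noise_sigma: float) -> np.ndarray:
    """Per-5-s [start, va, ml, ap] integer counts matching the drawn means."""
    n_ep = int(round(duration / _EPOCH_S))
    starts = np.arange(n_ep) * _EPOCH_S
    s = epoch_noise_sigma
    burst = np.exp(s * rng.standard_normal(n_ep) - 0.5 * s * s)
    va = va_mean * burst
    vm = vm_mean * burst * np.exp(0.1 * rng.standard_normal(n_ep))
    in_win = (starts >= window[0]) & (starts < window[1])
    # make the analysis-window mean equal the trial-level draw
    for arr, mean in ((va, va_mean), (vm, vm_mean)):
        w = arr[in_win].mean()
        if w > 0:
            arr[in_win] *= mean / w
    vm = np.maximum(vm, va)
    resid = np.sqrt(np.maximum(vm**2 - va**2, 0.0))
    theta = rng.uniform(0.0, np.pi / 2.0, n_ep)
    ml = resid * np.cos(theta)
    ap = resid * np.sin(theta)
    out = np.column_stack([starts, np.rint(va), np.rint(ml), np.rint(ap)])
    out[:, 1:] = np.maximum(out[:, 1:], 0.0)
    return out


def generate_trial(participant: Participant, profile: ActivityProfile,
                   err: CalibrationError = IDENTITY_ERROR, seed: int = 0,
                   err_right: CalibrationError | None = None,
                   config: RunConfig | None = None) -> TrialRecording:
    """Simulate one activity trial for one participant.

    Draws trial Youth METs from a truncated normal (>= 1), builds a VO2
    trace ramping onto the implied steady state, heart rate as an affine
    map of METs plus noise, per-5-s counts and raw acceleration whose
    windowed metrics match lognormal draws anchored to the activity
    profile, and finally distorts each wrist's raw signal by its device
    calibration error (``err`` for the left wrist; ``err_right`` defaults
    to the same error).  Deterministic given ``seed``.
    """
    cfg = config or RunConfig()
    err_l = err
    err_r = err_right if err_right is not None else err
    rng = np.random.default_rng(seed)
    window = extract_window(profile.code, profile.duration)

    # latent coupling: energy <- trial movement level -> per-side metrics
    z_met = rng.standard_normal()
    r_em = cfg.met_movement_correlation
    z_move = r_em * z_met + math.sqrt(1.0 - r_em**2) * rng.standard_normal()
    a_lr = math.sqrt(cfg.lr_correlation)
    b_m = 0.95  # metric loading on the side latent
    z_metric: dict[str, dict[str, float]] = {}
    for side in ("left", "right"):
        z_side = a_lr * z_move + math.sqrt(1.0 - cfg.lr_correlation) * rng.standard_normal()
        z_metric[side] = {
            m: b_m * z_side + math.sqrt(1.0 - b_m**2) * rng.standard_normal()
            for m in ("va", "vm", "enmo")
        }

    # energy expenditure
    lo = (1.0 - profile.met_mean) / profile.met_sd
    mets = float(truncnorm.ppf(ndtr(z_met), lo, np.inf,
                               loc=profile.met_mean, scale=profile.met_sd))
    ree = schofield_ree(participant.sex, participant.age, participant.mass,
                        participant.height, cfg.o2_energy_kj_per_l)
    vo2_rest = ree.ree_vo2 * participant.mass  # ml/min at 1 Youth MET
    vo2_ss = mets * vo2_rest
    gas_t = np.arange(_GAS_STEP_S, profile.duration + 1e-9, _GAS_STEP_S)
    ramp = 1.0 - np.exp(-gas_t / cfg.ramp_tau_s)
    vo2_clean = vo2_rest + (vo2_ss - vo2_rest) * ramp
    s_v = cfg.vo2_noise
    vo2 = vo2_clean * np.exp(s_v * rng.standard_normal(gas_t.size) - 0.5 * s_v * s_v)
    met_t = 1.0 + (mets - 1.0) * ramp
    hr = cfg.hr_intercept + cfg.hr_slope * (met_t - 1.0) \
        + cfg.hr_noise_bpm * rng.standard_normal(gas_t.size)

    # per-side counts and raw acceleration
    fit_va = lognormal_from_quartiles(profile.va_median, *profile.va_iqr, cfg.zero_median_sigma)
    fit_vm = lognormal_from_quartiles(profile.vm_median, *profile.vm_iqr, cfg.zero_median_sigma)
    fit_enmo = lognormal_from_quartiles(profile.enmo_median, *profile.enmo_iqr, cfg.zero_median_sigma)
    counts: dict[str, np.ndarray] = {}
    raws: dict[str, np.ndarray] = {}
    for side, dev_err in (("left", err_l), ("right", err_r)):
        z = z_metric[side]
        va_mean = float(fit_va.ppf(np.array(ndtr(z["va"]))))
        vm_mean = float(fit_vm.ppf(np.array(ndtr(z["vm"]))))
        vm_mean = max(vm_mean, va_mean)
        counts[side] = _epoch_counts(profile.duration, va_mean, vm_mean, window,
                                     rng, cfg.epoch_noise_sigma)
        enmo_target = float(fit_enmo.ppf(np.array(ndtr(z["enmo"]))))
        raw = _synth_raw(profile.duration, enmo_target, window, rng, cfg.device_noise_g)
        raws[side] = raw * np.asarray(dev_err.gain) + np.asarray(dev_err.offset)

    return TrialRecording(
        participant_id=participant.id, activity_code=profile.code,
        raw_left=raws["left"], raw_right=raws["right"],
        counts_left=counts["left"], counts_right=counts["right"],
        gas_t=gas_t, vo2=vo2, hr=hr,
    )


def generate_cohort(config: RunConfig | None = None, seed: int = 0) -> StudyDataset:
    """Simulate the full study: every participant x activity trial.

    Each trial is independently excluded with the configured dropout
    probability and assigned a reason sampled from the four failure modes
    of such protocols (device failure, calorimeter malfunction, failure
    to reach steady state, incomplete trial).  Deterministic given
    (config, seed).
    """
    cfg = config or RunConfig()
    master = np.random.default_rng(np.random.SeedSequence(seed))
    part_seed = int(master.integers(2**31))
    participants = generate_participants(cfg.n_participants, part_seed,
                                         cfg.male_fraction, cfg.handedness_p_right)
    profiles = builtin_activity_profiles()

    def device_error(rng: np.random.Generator) -> CalibrationError:
        if cfg.calibration_gain_halfrange == 0 and cfg.calibration_offset_halfrange_g == 0:
            return IDENTITY_ERROR
        gain = 1.0 + rng.uniform(-cfg.calibration_gain_halfrange,
                                 cfg.calibration_gain_halfrange, 3)
        off = rng.uniform(-cfg.calibration_offset_halfrange_g,
                          cfg.calibration_offset_halfrange_g, 3)
        return CalibrationError(gain=tuple(gain), offset=tuple(off))

    trials: list[TrialRecording] = []
    for p in participants:
        err_l = device_error(master)
        err_r = device_error(master)
        for prof in profiles:
            tseed = int(master.integers(2**31))
            rec = generate_trial(p, prof, err_l, seed=tseed, err_right=err_r, config=cfg)
            if master.random() < cfg.dropout:
                rec.exclusion_flag = str(master.choice(EXCLUSION_REASONS))
            trials.append(rec)
    return StudyDataset(participants=participants, profiles=profiles,
                        trials=trials, config=cfg, seed=seed)
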