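"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the simulated study and of the evaluation pipeline.

    Cohort defaults reproduce the laboratory protocol being emulated:
    18 participants (10 boys, 8 girls), 12 activity trials each, and an
    independent per-trial dropout probability of 34/216 so that roughly
    182 of the 216 scheduled trials are retained.
    """

    # cohort
    n_participants: int = 18
    male_fraction: float = 10.0 / 18.0
    handedness_p_right: float = 0.9
    dropout: float = 34.0 / 216.0

    # trial-level coupling (latent Gaussian copula)
    lr_correlation: float = 0.8  # left vs right wrist, same trial
    met_movement_correlation: float = 0.7  # energy expenditure vs movement level

    # gas exchange and heart rate
    ramp_tau_s: float = 45.0  # VO2 on-kinetics time constant
    vo2_noise: float = 0.02  # multiplicative SD on 15-s VO2 samples
    hr_intercept: float = 70.0  # bpm at 1 Youth MET
    hr_slope: float = 12.0  # bpm per Youth MET above rest
    hr_noise_bpm: float = 1.5

    # accelerometer signal
    device_noise_g: float = 0.003
    epoch_noise_sigma: float = 0.25  # within-trial count burstiness (log scale)
    zero_median_sigma: float = 0.5  # lognormal sigma for zero-median metrics
    calibration_gain_halfrange: float = 0.0  # per-axis gain error, uniform +/-
    calibration_offset_halfrange_g: float = 0.0  # per-axis offset error, uniform +/-

    # energy and analysis
    o2_energy_kj_per_l: float = 20.9
    weighting: str = "linear"  # kappa weighting: linear | quadratic | unweighted

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.weighting not in ("linear", "quadratic", "unweighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
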