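"""Energy expenditure: predicted REE, Youth METs and intensity labels.

Youth METs express exercise oxygen uptake as a multiple of the child's
*predicted* resting energy expenditure (REE), rather than the adult
convention of 3.5 ml O2.kg-1.min-1.  REE is predicted from sex, age, body
mass and height with the Schofield weight-and-height equations for
children, and converted to an oxygen uptake using the energy equivalent
of oxygen (default 20.9 kJ per litre O2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Intensity",
    "ReePrediction",
    "schofield_ree",
    "youth_mets",
    "label_intensity",
    "SCHOFIELD_COEFFICIENTS",
    "O2_ENERGY_KJ_PER_L",
]


class Intensity(enum.IntEnum):
    """Ordered physical-activity intensity categories."""

    SED = 0
    LPA = 1
    MPA = 2
    VPA = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Schofield weight-and-height equations for children, MJ/day.
#: REE = wm * mass_kg + hm * height_m + c, keyed by (sex, age band).
#: Coefficients from Schofield's predictive equations for basal
#: metabolic rate (weight + height variant).
SCHOFIELD_COEFFICIENTS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("male", "3-10"): (0.082, 0.545, 1.736),
    ("female", "3-10"): (0.071, 0.677, 1.553),
    ("male", "10-18"): (0.068, 0.574, 2.157),
    ("female", "10-18"): (0.035, 1.948, 0.837),
}

#: Energy equivalent of oxygen, kJ per litre O2 (configurable).
O2_ENERGY_KJ_PER_L = 20.9

_MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class ReePrediction:
    """Predicted resting energy expenditure.

    Attributes
    ----------
    ree_mj_day : float
        REE in MJ/day from the Schofield equation.
    ree_vo2 : float
        The same REE expressed as oxygen uptake, ml O2.kg-1.min-1.
    equation_band : str
        Age band of the equation used, ``"3-10"`` or ``"10-18"``.
    """

    ree_mj_day: float
    ree_vo2: float
    equation_band: str

    def __post_init__(self) -> None:
        if self.ree_mj_day <= 0 or self.ree_vo2 <= 0:
            raise ValueError("REE must be positive")


def schofield_ree(
    sex: str,
    age: float,
    mass: float,
    height: float,
    o2_energy_kj_per_l: float = O2_ENERGY_KJ_PER_L,
) -> ReePrediction:
    """Predict resting energy expenditure for a child or adolescent.

    Parameters
    ----------
    sex : {"male", "female"}
    age : float
        Age in years; must lie in [3, 18].
    mass : float
        Body mass in kg.
    height : float
        Height in metres.
    o2_energy_kj_per_l : float
        Energy equivalent of oxygen used to convert MJ/day to an oxygen
        uptake; default 20.9 kJ/L.

    Returns
    -------
    ReePrediction
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 3.0 <= age <= 18.0:
        raise ValueError(f"age {age} outside the 3-18 y equation bands")
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be positive")
    band = "3-10" if age < 10.0 else "10-18"
    wm, hm, c = SCHOFIELD_COEFFICIENTS[(sex, band)]
    ree_mj_day = wm * mass + hm * height + c
    # MJ/day -> kJ/day -> L O2/day -> ml O2 per kg per min
    litres_per_day = ree_mj_day * 1e3 / o2_energy_kj_per_l
    ree_vo2 = litres_per_day * 1e3 / _MIN_PER_DAY / mass
    return ReePrediction(ree_mj_day=ree_mj_day, ree_vo2=ree_vo2, equation_band=band)


def youth_mets(mean_vo2: float, mass: float, ree: ReePrediction) -> float:
    """Youth METs: mass-relative VO2 divided by predicted resting VO2.

    Parameters
    ----------
    mean_vo2 : float
        Mean oxygen uptake over the analysis window, ml/min (absolute).
    mass : float
        Body mass, kg.
    ree : ReePrediction
    """
    if mean_vo2 <= 0:
        raise ValueError("mean_vo2 must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (mean_vo2 / mass) / ree.ree_vo2


def label_intensity(mets: float, posture: str) -> Intensity:
    """Assign the measured intensity category from Youth METs and posture.

    Sedentary requires both a lying or sitting posture and METs < 1.5;
    an upright trial below 1.5 METs is light.  Category boundaries are
    lower-inclusive for MPA (3 METs) and VPA (6 METs), and 1.5 METs
    itself is light, not sedentary.
    """
    if mets <= 0:
        raise ValueError("mets must be positive")
    if posture not in ("lying", "sitting", "upright"):
        raise ValueError(f"unknown posture {posture!r}")
    if mets >= 6.0:
        return Intensity.VPA
    if mets >= 3.0:
        return Intensity.MPA
    if mets < 1.5 and posture in ("lying", "sitting"):
        return Intensity.SED
    return Intensity.LPA
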