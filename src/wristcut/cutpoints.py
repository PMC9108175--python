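"""The seven published youth wrist cut-point sets and trial classification.

Each cut-point set is a threshold classifier on a single accelerometer
metric — vertical-axis (VA) counts per 5 s, vector-magnitude (VM) counts
per 5 s, or ENMO in milli-g — calibrated for a specific wrist (dominant
for the Crouter sets, non-dominant for Chandler and Hildebrand).  The two
Crouter regression sets additionally carry the linear METs prediction
equation from which their moderate and vigorous thresholds derive.

Boundary semantics differ between authors and are stored per set: the
Crouter and Chandler sets treat the sedentary threshold as inclusive
(x <= sed_upper is sedentary), Hildebrand as exclusive (x < sed_upper).
Moderate and vigorous thresholds are lower-inclusive for every set.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .energy import Intensity

__all__ = [
    "CutPointSet",
    "Regression",
    "builtin_cutpoints",
    "regression_mets",
    "invert_regression",
    "classify_value",
    "classify_trial",
    "cutpoints_to_yaml",
    "cutpoints_from_yaml",
]

METRICS = ("va", "vm", "enmo")


@dataclass(frozen=True)
class Regression:
    """Linear METs prediction: mets = intercept + slope * counts/5 s."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("regression slope must be positive")


@dataclass(frozen=True)
class CutPointSet:
    """A named intensity cut-point classifier for the wrist.

    ``sed_upper`` is the sedentary boundary in metric units; whether it is
    itself sedentary is governed by ``sed_inclusive``.  ``mpa_lower`` and
    ``vpa_lower`` are lower-inclusive moderate/vigorous boundaries.
    """

    name: str
    metric: str  # "va" | "vm" | "enmo"
    wrist: str  # "dominant" | "non-dominant"
    sed_upper: float
    mpa_lower: float
    vpa_lower: float
    sed_inclusive: bool = True
    regression: Regression | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.wrist not in ("dominant", "non-dominant"):
            raise ValueError(f"unknown wrist {self.wrist!r}")
        if not (self.sed_upper <= self.mpa_lower < self.vpa_lower):
            raise ValueError("thresholds must satisfy sed_upper <= mpa_lower < vpa_lower")


def builtin_cutpoints() -> list[CutPointSet]:
    """The seven published youth wrist cut-point sets for the ActiGraph.

    Thresholds are in counts per 5 s for the count-based sets and
    milli-g (1-s epochs) for the ENMO set, exactly as published.
    """
    return [
        CutPointSet("CR_ROC_VA", "va", "dominant", 105, 262, 565),
        CutPointSet("CR_ROC_VM", "vm", "dominant", 275, 416, 778),
        CutPointSet(
            "CR_REG_VA", "va", "dominant", 35, 361, 1130,
            regression=Regression(1.592, 0.0039),
        ),
        CutPointSet(
            "CR_REG_VM", "vm", "dominant", 100, 610, 1810,
            regression=Regression(1.475, 0.0025),
        ),
        # Chandler prints SED < 161 / LPA >= 162 (integer counts): 161 itself
        # is sedentary, values in (161, 162) fall to LPA.
        CutPointSet("CH_ROC_VA", "va", "non-dominant", 161, 530, 1462),
        CutPointSet("CH_ROC_VM", "vm", "non-dominant", 305, 818, 1969),
        CutPointSet("HD_ENMO", "enmo", "non-dominant", 35.6, 201.4, 707.0,
                    sed_inclusive=False),
    ]


def regression_mets(x: float, cps: CutPointSet) -> float:
    """Predicted METs from a Crouter regression set at ``x`` counts/5 s."""
    if cps.regression is None:
        raise ValueError(f"cut-point set {cps.name} has no regression equation")
    if x < 0:
        raise ValueError("counts must be non-negative")
    return cps.regression.intercept + cps.regression.slope * x


def invert_regression(cps: CutPointSet, met_boundary: float) -> int:
    """Counts/5 s at which the regression predicts ``met_boundary`` METs.

    Returns the nearest integer, reproducing how the published count
    thresholds derive from the regression equations at 3 and 6 METs.
    """
    if cps.regression is None:
        raise ValueError(f"cut-point set {cps.name} has no regression equation")
    if met_boundary < cps.regression.intercept:
        raise ValueError("MET boundary below the regression intercept")
    return round((met_boundary - cps.regression.intercept) / cps.regression.slope)


def classify_value(x: float, cps: CutPointSet) -> Intensity:
    """Classify a trial-mean metric value with one cut-point set."""
    if x < 0:
        raise ValueError("metric value must be non-negative")
    if x >= cps.vpa_lower:
        return Intensity.VPA
    if x >= cps.mpa_lower:
        return Intensity.MPA
    sed = x <= cps.sed_upper if cps.sed_inclusive else x < cps.sed_upper
    return Intensity.SED if sed else Intensity.LPA


def classify_trial(features, cps: CutPointSet, handedness: str) -> Intensity:
    """Classify a trial from its windowed features, honouring wrist side.

    The dominant wrist is the handedness side; the non-dominant wrist is
    the other side.  ``features`` is a :class:`wristcut.signal.TrialFeatures`
    (or anything with ``mean_va``/``mean_vm``/``mean_enmo`` side dicts).
    """
    if handedness not in ("left", "right"):
        raise ValueError(f"unknown handedness {handedness!r}")
    if cps.wrist == "dominant":
        side = handedness
    else:
        side = "left" if handedness == "right" else "right"
    per_side = {"va": features.mean_va, "vm": features.mean_vm,
                "enmo": features.mean_enmo}[cps.metric]
    if side not in per_side:
        raise ValueError(f"features lack side {side!r} for metric {cps.metric!r}")
    return classify_value(per_side[side], cps)


def cutpoints_to_yaml(sets: list[CutPointSet]) -> str:
    """Serialize cut-point sets to YAML (for export / user overrides)."""
    out = []
    for s in sets:
        d = {
            "name": s.name, "metric": s.metric, "wrist": s.wrist,
            "sed_upper": s.sed_upper, "mpa_lower": s.mpa_lower,
            "vpa_lower": s.vpa_lower, "sed_inclusive": s.sed_inclusive,
        }
        if s.regression is not None:
            d["regression"] = {"intercept": s.regression.intercept,
                               "slope": s.regression.slope}
        out.append(d)
    return yaml.safe_dump(out, sort_keys=False)


def cutpoints_from_yaml(text: str) -> list[CutPointSet]:
    """Load cut-point sets from YAML produced by :func:`cutpoints_to_yaml`."""
    sets = []
    for d in yaml.safe_load(text):
        reg = d.get("regression")
        sets.append(CutPointSet(
            name=d["name"], metric=d["metric"], wrist=d["wrist"],
            sed_upper=float(d["sed_upper"]), mpa_lower=float(d["mpa_lower"]),
            vpa_lower=float(d["vpa_lower"]),
            sed_inclusive=bool(d.get("sed_inclusive", True)),
            regression=Regression(reg["intercept"], reg["slope"]) if reg else None,
        ))
    return sets
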