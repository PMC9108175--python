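"""Agreement between predicted and measured intensity categories.

Weighted Cohen's kappa with a large-sample confidence interval,
confusion matrices (rows = measured by calorimetry, columns = predicted),
per-class accuracy and per-activity misclassification direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .energy import Intensity

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "confusion_matrix",
    "weighted_kappa",
    "per_class_accuracy",
    "direction_summary",
    "landis_koch",
]

N_CLASSES = 4
CLASS_NAMES = tuple(i.name for i in Intensity)

#: Landis-Koch qualitative bands for kappa, lower-inclusive.
LANDIS_KOCH_BANDS = (
    (0.8, "almost perfect"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "fair"),
    (-np.inf, "poor"),
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 tally: rows measured (SED..VPA), columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASS_NAMES),
                            columns=list(CLASS_NAMES))


@dataclass(frozen=True)
class KappaResult:
    """Weighted kappa with large-sample SE, 95% CI and qualitative rating.

    ``kappa`` is NaN with ``degenerate=True`` when the table has a single
    occupied row and column (chance agreement is then 1 and kappa is
    undefined).
    """

    kappa: float
    se: float
    ci95: tuple[float, float]
    weighting: str
    landis_koch: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
                raise ValueError("kappa outside [-1, 1]")
            if not self.ci95[0] <= self.kappa + 1e-12 or not self.kappa - 1e-12 <= self.ci95[1]:
                raise ValueError("kappa outside its own CI")


def confusion_matrix(truth: Sequence[Intensity], predicted: Sequence[Intensity]) -> ConfusionMatrix:
    """Tally paired (measured, predicted) labels into the 4x4 grid."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(truth, predicted):
        counts[int(t), int(p)] += 1
    return ConfusionMatrix(counts=counts)


def landis_koch(kappa: float) -> str:
    """Qualitative rating of a kappa value."""
    for lower, name in LANDIS_KOCH_BANDS:
        if kappa >= lower:
            return name
    raise AssertionError("unreachable")


def _disagreement_weights(weighting: str) -> np.ndarray:
    i = np.arange(N_CLASSES)
    d = np.abs(i[:, None] - i[None, :]) / (N_CLASSES - 1)
    if weighting == "linear":
        return d
    if weighting == "quadratic":
        return d**2
    if weighting == "unweighted":
        return (d > 0).astype(float)
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_kappa(m: ConfusionMatrix, weighting: str = "linear") -> KappaResult:
    """Chance-corrected ordinal agreement from a confusion matrix.

    ``kappa_w = 1 - sum(w o) / sum(w e)`` with disagreement weights ``w``
    (linear ``|i-j|/3``, quadratic ``((i-j)/3)^2``, or 0/1 unweighted),
    observed cell proportions ``o`` and chance proportions ``e`` from the
    products of the row and column marginals.  The standard error uses
    the large-sample (Fleiss-Cohen-Everitt) variance and the 95%
    confidence interval is the normal interval clipped to [-1, 1].
    """
    n = m.n
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    p = m.counts / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.count_nonzero(r) == 1 and np.count_nonzero(c) == 1:
        return KappaResult(kappa=float("nan"), se=float("nan"),
                           ci95=(float("nan"), float("nan")), weighting=weighting,
                           landis_koch="undefined", degenerate=True)
    d = _disagreement_weights(weighting)
    e = np.outer(r, c)
    kappa = 1.0 - float(np.sum(d * p)) / float(np.sum(d * e))

    # large-sample variance on the agreement-weight scale
    v = 1.0 - d
    po = float(np.sum(v * p))
    pe = float(np.sum(v * e))
    v_row = (v * c[None, :]).sum(axis=1)  # weighted column marginals, per row
    v_col = (v * r[:, None]).sum(axis=0)  # weighted row marginals, per column
    term = v * (1.0 - pe) - (v_row[:, None] + v_col[None, :]) * (1.0 - po)
    var = (float(np.sum(p * term**2)) - (po * pe - 2.0 * pe + po) ** 2) \
        / (n * (1.0 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    lo = max(kappa - 1.959963984540054 * se, -1.0)
    hi = min(kappa + 1.959963984540054 * se, 1.0)
    return KappaResult(kappa=kappa, se=se, ci95=(lo, hi), weighting=weighting,
                       landis_koch=landis_koch(kappa))


def per_class_accuracy(m: ConfusionMatrix) -> dict[str, float]:
    """Correct predictions divided by total, per measured class.

    Classes with no measured trials are reported as NaN, not zero.
    """
    row_sums = m.counts.sum(axis=1)
    diag = np.diag(m.counts)
    out = {}
    for i, name in enumerate(CLASS_NAMES):
        out[name] = float(diag[i] / row_sums[i]) if row_sums[i] > 0 else float("nan")
    return out


def direction_summary(truth: Sequence[Intensity], predicted: Sequence[Intensity],
                      activity_codes: Sequence[str]) -> pd.DataFrame:
    """Per-activity fractions over-, correctly- and under-classified.

    Uses the SED < LPA < MPA < VPA ordering: a prediction above the
    measured category counts as overestimation, below as
    underestimation.  Fractions sum to 1 over the classified trials of
    each activity.
    """
    if not (len(truth) == len(predicted) == len(activity_codes)):
        raise ValueError("inputs must have equal length")
    rows: dict[str, list[int]] = {}
    for t, p, code in zip(truth, predicted, activity_codes):
        tallies = rows.setdefault(code, [0, 0, 0])
        if int(p) > int(t):
            tallies[0] += 1
        elif int(p) == int(t):
            tallies[1] += 1
        else:
            tallies[2] += 1
    records = []
    for code, (over, correct, under) in rows.items():
        total = over + correct + under
        records.append({"activity": code, "over": over / total,
                        "correct": correct / total, "under": under / total,
                        "n": total})
    return pd.DataFrame.from_records(records).set_index("activity")
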