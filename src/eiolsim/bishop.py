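"""Cervical favorability and the cesarean-rate-versus-Bishop-score curve.

The modified Bishop score (dilation, effacement, station; composite range
0-12) classifies the cervix as unfavorable ("unripe", score <= 4) or
favorable (score >= 5).  Because observed cesarean rates per Bishop score at
41 weeks are not directly available, they are projected by fitting a
monotone two-parameter logistic curve to (score, rate) points; the fitted
curve supplies the cesarean probability of the scheduled 41-week induction.

Fitting is ordinary least squares on the logit scale, which is linear in the
coefficients and therefore exact, deterministic and invariant to the order
of the input points.  A non-negative fitted slope is clamped to zero so the
predicted rate is always non-increasing in the score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "Favorability",
    "CervixState",
    "CsCurveModel",
    "classify_cervix",
    "fit_cs_curve",
    "predict_cs_rate",
    "UNFAVORABLE_MAX_SCORE",
    "SCORE_MIN",
    "SCORE_MAX",
]

UNFAVORABLE_MAX_SCORE = 4
SCORE_MIN = 0
SCORE_MAX = 12

_EPS = 1e-9  # clip rates away from {0,1} before taking logits


class Favorability(str, enum.Enum):
    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"


@dataclass(frozen=True)
class CervixState:
    modified_bishop: int

    def __post_init__(self) -> None:
        if not (SCORE_MIN <= self.modified_bishop <= SCORE_MAX):
            raise ValueError(
                f"modified Bishop score {self.modified_bishop} outside "
                f"[{SCORE_MIN}, {SCORE_MAX}]"
            )

    @property
    def favorability(self) -> Favorability:
        return classify_cervix(self.modified_bishop)


def classify_cervix(score: int) -> Favorability:
    """Classify a modified Bishop score: unfavorable iff score <= 4."""
    score = int(score)
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return (
        Favorability.UNFAVORABLE
        if score <= UNFAVORABLE_MAX_SCORE
        else Favorability.FAVORABLE
    )


@dataclass
class CsCurveModel:
    """Fitted logistic model: P(cesarean) = expit(intercept + slope * score)."""

    intercept: float
    slope: float
    fit_points: list[tuple[float, float]] = field(default_factory=list)
    goodness_of_fit: float = float("nan")  # SSE on the rate scale
    week: int = 41
    form: str = "logistic"

    def predict(self, score) -> np.ndarray | float:
        score = np.asarray(score, dtype=float)
        out = expit(self.intercept + self.slope * score)
        return float(out) if out.ndim == 0 else out

    def band_means(self) -> tuple[float, float]:
        """Mean predicted rate over the unfavorable (0-4) and favorable
        (5-12) score bands, scores uniform within band."""
        unfav = float(np.mean(self.predict(np.arange(0, UNFAVORABLE_MAX_SCORE + 1))))
        fav = float(np.mean(self.predict(np.arange(UNFAVORABLE_MAX_SCORE + 1, SCORE_MAX + 1))))
        return unfav, fav


def fit_cs_curve(points) -> CsCurveModel:
    """Fit the monotone logistic cesarean curve to (score, rate) points.

    Accepts an iterable of (score, rate) pairs; requires at least three
    points with distinct scores and rates in [0, 1].
    """
    pts = [(float(s), float(r)) for s, r in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 fit points, got {len(pts)}")
    s = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite fit points")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("rates must lie in [0, 1]")
    if len(np.unique(s)) != len(s):
        raise ValueError("scores must be distinct")

    # deterministic order (also makes the fit permutation-invariant by
    # construction; OLS is order-invariant anyway)
    order = np.argsort(s)
    s, r = s[order], r[order]
    y = logit(np.clip(r, _EPS, 1.0 - _EPS))
    X = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if slope > 0.0:
        # monotone constraint: flat curve at the mean logit is the
        # least-squares solution under slope <= 0
        slope = 0.0
        intercept = float(np.mean(y))
    model = CsCurveModel(intercept=intercept, slope=slope, fit_points=list(zip(s, r)))
    model.goodness_of_fit = float(np.sum((model.predict(s) - r) ** 2))
    return model


def predict_cs_rate(model: CsCurveModel, score: int) -> float:
    """Predicted cesarean probability at a single Bishop score."""
    if model is None or not np.isfinite(model.intercept):
        raise ValueError("model is not fitted")
    score = int(score)
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return float(model.predict(score))
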