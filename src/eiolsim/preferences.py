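"""Dyad preference weighting and health-state utilities.

A mother/infant dyad's outcome is collapsed to a single value in [0, 1].
Perfect health scores 1 and death 0.  The importance ratio x (mother's over
infant's health) yields dyad weights 1/(1+x) and x/(1+x), which sum to one
by construction.  Morbidity-versus-mortality importance is governed by the
ratios yM (maternal) and yB (infant); y = 1/4 means mortality weighs four
times as much as morbidity.

Maternal morbid states map to utilities through
``1 - w * yM * (1 - floor)`` with floor 0.6 for states managed without
intensive care (utilities in the 0.6-1 range) and 0.5 for ICU-level
morbidity, where w is a severity weight drawn in [0.3, 1] (non-ICU) or
[0.5, 1] (ICU).  Infant morbidity is graded by the five-minute Apgar score
(1-3 severe, 4-7 non-severe, 8-10 healthy) and maps to ``1 - w * yB`` with
w in the band's severity range, so at w = 1 the morbidity disutility is
exactly yB times the mortality disutility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightConvention",
    "ApgarClass",
    "PreferenceWeights",
    "dyad_weights",
    "classify_apgar",
    "maternal_utility",
    "neonatal_utility",
    "dyad_utility",
    "MATERNAL_UTILITY_RANGE",
    "ICU_WEIGHT_RANGE",
    "NONSEVERE_WEIGHT_RANGE",
]

#: AHRQ-style maternal utility range for non-ICU morbid states.
MATERNAL_UTILITY_RANGE = (0.6, 1.0)
#: Severity-weight range for ICU-level morbidity (0.5 = best, 1 = worst).
ICU_WEIGHT_RANGE = (0.5, 1.0)
#: Severity-weight range for non-severe morbidity (0.3 = best, 1 = worst).
NONSEVERE_WEIGHT_RANGE = (0.3, 1.0)

_ICU_FLOOR = 0.5
_NON_ICU_FLOOR = MATERNAL_UTILITY_RANGE[0]


class WeightConvention(str, enum.Enum):
    """Mapping of the importance ratio x onto the dyad weights.

    ``literal``: mother 1/(1+x), infant x/(1+x).  ``swapped`` flips the
    two, reading x > 1 as the mother's health mattering more.  The two
    conventions coincide at x = 1 and sweeps over x cover both.
    """

    LITERAL = "literal"
    SWAPPED = "swapped"


class ApgarClass(str, enum.Enum):
    SEVERE = "severe"          # Apgar 1-3
    NON_SEVERE = "non_severe"  # Apgar 4-7
    HEALTHY = "healthy"        # Apgar 8-10


def dyad_weights(
    x: float, convention: WeightConvention | str = WeightConvention.LITERAL
) -> tuple[float, float]:
    """Dyad weights (wM, wB) from the importance ratio x > 0; wM + wB = 1."""
    if x <= 0:
        raise ValueError(f"importance ratio x must be positive, got {x}")
    convention = WeightConvention(convention)
    wm = 1.0 / (1.0 + x)
    wb = x / (1.0 + x)
    if convention is WeightConvention.SWAPPED:
        wm, wb = wb, wm
    return wm, wb


def classify_apgar(score: int) -> ApgarClass:
    """Band a five-minute Apgar score: 1-3 severe, 4-7 non-severe, 8-10 healthy."""
    score = int(score)
    if not (1 <= score <= 10):
        raise ValueError(f"Apgar score {score} outside [1, 10]")
    if score <= 3:
        return ApgarClass.SEVERE
    if score <= 7:
        return ApgarClass.NON_SEVERE
    return ApgarClass.HEALTHY


@dataclass(frozen=True)
class PreferenceWeights:
    """Preference parameters of the dyad utility.

    x is the mother:infant importance ratio, y_maternal / y_neonatal the
    morbidity:mortality ratios, and the w_* fields the realized severity
    weights used when no explicit draw is supplied.
    """

    x: float = 1.0
    y_maternal: float = 0.25
    y_neonatal: float = 0.25
    w_icu: float = 0.75
    w_ld: float = 0.65
    w_mild: float = 0.65
    w_neo_severe: float = 0.75
    w_neo_mild: float = 0.65
    maternal_utility_floor: float = _NON_ICU_FLOOR
    convention: WeightConvention = WeightConvention.LITERAL

    def weights(self) -> tuple[float, float]:
        return dyad_weights(self.x, self.convention)

    @classmethod
    def from_realized(cls, rp, convention=WeightConvention.LITERAL) -> "PreferenceWeights":
        """Build from a realized parameter vector (scalar values)."""
        return cls(
            x=float(rp["pref_x"]),
            y_maternal=float(rp["pref_y_maternal"]),
            y_neonatal=float(rp["pref_y_neonatal"]),
            w_icu=float(rp["mat_sev_weight_icu"]),
            w_ld=float(rp["mat_sev_weight_ld"]),
            w_mild=float(rp["mat_sev_weight_mild"]),
            w_neo_severe=float(rp["neo_sev_weight_severe"]),
            w_neo_mild=float(rp["neo_sev_weight_mild"]),
            maternal_utility_floor=float(rp["maternal_utility_floor"]),
            convention=WeightConvention(convention),
        )


def _check_range(draw: float, lo: float, hi: float, label: str) -> None:
    if not (lo <= draw <= hi):
        raise ValueError(f"severity draw {draw} outside [{lo}, {hi}] for {label}")


def maternal_utility(
    state: str, pw: PreferenceWeights, severity_draw: float | None = None
) -> float:
    """Utility of a terminal maternal state.

    ``state`` is one of no_complication, morbidity, severe_morbidity_LD,
    severe_morbidity_ICU, death.  The optional ``severity_draw`` overrides
    the realized severity weight and must fall in the state's range.
    """
    if state == "no_complication":
        return 1.0
    if state == "death":
        return 0.0
    floor = pw.maternal_utility_floor
    if state == "severe_morbidity_ICU":
        w = pw.w_icu if severity_draw is None else severity_draw
        _check_range(w, *ICU_WEIGHT_RANGE, label=state)
        floor = _ICU_FLOOR
    elif state == "severe_morbidity_LD":
        w = pw.w_ld if severity_draw is None else severity_draw
        _check_range(w, *NONSEVERE_WEIGHT_RANGE, label=state)
    elif state == "morbidity":
        w = pw.w_mild if severity_draw is None else severity_draw
        _check_range(w, *NONSEVERE_WEIGHT_RANGE, label=state)
    else:
        raise ValueError(f"unknown maternal state {state!r}")
    return float(np.clip(1.0 - w * pw.y_maternal * (1.0 - floor), 0.0, 1.0))


_STATE_BAND = {
    "no_complication": ApgarClass.HEALTHY,
    "morbidity": ApgarClass.NON_SEVERE,
    "severe_morbidity": ApgarClass.SEVERE,
}


def neonatal_utility(
    state: str,
    apgar_class: ApgarClass | None,
    pw: PreferenceWeights,
    severity_draw: float | None = None,
) -> float:
    """Utility of a terminal neonatal state.

    ``state`` is one of no_complication, morbidity, severe_morbidity,
    death, not_applicable (stillbirth; utility 0).  For live morbid states
    the Apgar class must match the state's band.
    """
    if state in ("death", "not_applicable"):
        return 0.0
    expected_band = _STATE_BAND.get(state)
    if expected_band is None:
        raise ValueError(f"unknown neonatal state {state!r}")
    if apgar_class is not None and ApgarClass(apgar_class) is not expected_band:
        raise ValueError(
            f"neonatal state {state!r} inconsistent with Apgar class {apgar_class}"
        )
    if state == "no_complication":
        return 1.0
    if state == "severe_morbidity":
        w = pw.w_neo_severe if severity_draw is None else severity_draw
        _check_range(w, *ICU_WEIGHT_RANGE, label=state)
    else:
        w = pw.w_neo_mild if severity_draw is None else severity_draw
        _check_range(w, *NONSEVERE_WEIGHT_RANGE, label=state)
    return float(np.clip(1.0 - w * pw.y_neonatal, 0.0, 1.0))


def dyad_utility(traj, pw: PreferenceWeights) -> float:
    """Weighted dyad utility of one complete trajectory.

    A stillbirth contributes infant utility 0.  The result is the convex
    combination wM * maternal + wB * infant and lies in [0, 1].
    """
    wm, wb = pw.weights()
    um = maternal_utility(traj.maternal_state, pw)
    if traj.fetal_survival == "stillbirth":
        ub = 0.0
    else:
        apgar = None if traj.apgar5 is None else classify_apgar(traj.apgar5)
        ub = neonatal_utility(traj.neonatal_state, apgar, pw)
    return wm * um + wb * ub


# -- vectorised utilities over a trajectory frame -----------------------


def utilities_frame(df, pw: PreferenceWeights):
    """Maternal, infant and dyad utility arrays for a trajectory frame."""
    mat = np.ones(len(df))
    ms = df["maternal_state"].to_numpy()
    mat[ms == "death"] = 0.0
    mat[ms == "morbidity"] = maternal_utility("morbidity", pw)
    mat[ms == "severe_morbidity_LD"] = maternal_utility("severe_morbidity_LD", pw)
    mat[ms == "severe_morbidity_ICU"] = maternal_utility("severe_morbidity_ICU", pw)

    neo = np.ones(len(df))
    ns = df["neonatal_state"].to_numpy()
    neo[ns == "death"] = 0.0
    neo[ns == "not_applicable"] = 0.0
    neo[ns == "morbidity"] = neonatal_utility("morbidity", None, pw)
    neo[ns == "severe_morbidity"] = neonatal_utility("severe_morbidity", None, pw)

    wm, wb = pw.weights()
    return mat, neo, wm * mat + wb * neo
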