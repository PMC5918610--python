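"""Micro-simulation engine: individual trajectories through the two arms.

Each simulated woman/fetus dyad is assigned to one of two mutually exclusive
management strategies at 39 weeks of an uncomplicated nulliparous pregnancy:

* ``eIOL_39`` — elective induction of labor at 39 weeks; delivery is at 39
  weeks by induction and ends in a vaginal or cesarean birth.
* ``EM_41`` — expectant management: at 39 and again at 40 weeks the woman
  may labor spontaneously or require a medically indicated induction; if
  still undelivered she undergoes a scheduled induction at 41 weeks.
  Antepartum stillbirth risk applies only while the pregnancy continues
  (weeks 39->40 and 40->41), so the elective-induction arm carries no
  stillbirth exposure by construction.

The cesarean probability of each labor event is conditioned on the onset
type, the week and cervical favorability; the scheduled 41-week induction
uses the fitted Bishop-score curve.  Maternal and neonatal terminal states
are drawn after the mode of delivery, conditional on mode.  Each patient
consumes a fixed block of uniforms from a counter-based (Philox) stream, so
patient *i*'s trajectory depends only on (seed, i) — results are
reproducible and independent of cohort size or iteration order, and common
random numbers across arms and parameter settings come for free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import bishop
from .params import ParameterSet, RealizedParameters, realize_points, sample_parameters

__all__ = [
    "Arm",
    "PatientTrajectory",
    "MATERNAL_MORBIDITY_COMPONENTS",
    "MATERNAL_SEVERE_LD_COMPONENTS",
    "NEONATAL_MORBIDITY_COMPONENTS",
    "NEONATAL_SEVERE_COMPONENTS",
    "simulate_patient",
    "simulate_cohort",
    "run_to_saturation",
    "expected_arm_rates",
    "frame_to_trajectories",
]


class Arm(str, enum.Enum):
    EIOL_39 = "eIOL_39"
    EM_41 = "EM_41"


# Outcome taxonomies (documentation of what the composite states stand for;
# individual components are not simulated separately).
MATERNAL_MORBIDITY_COMPONENTS = frozenset(
    {"blood transfusion", "chorioamnionitis", "preeclampsia"}
)
MATERNAL_SEVERE_LD_COMPONENTS = frozenset(
    {
        "eclampsia",
        "hemorrhage",
        "uterine rupture",
        "septic shock",
        "unplanned hysterectomy",
        "unplanned operation",
        "thromboembolic event",
    }
)
NEONATAL_MORBIDITY_COMPONENTS = frozenset(
    {"meconium-stained amniotic fluid", "shoulder dystocia without lasting damage"}
)
NEONATAL_SEVERE_COMPONENTS = frozenset(
    {"major-comorbidity composite", "respiratory composite"}
)

MATERNAL_STATES = (
    "no_complication",
    "morbidity",
    "severe_morbidity_LD",
    "severe_morbidity_ICU",
    "death",
)
NEONATAL_STATES = ("no_complication", "morbidity", "severe_morbidity", "death", "not_applicable")

#: Fixed per-patient uniform draw slots (one block per patient).
_N_SLOTS = 13
(
    _U_FAV,
    _U_SCORE,
    _U_AGE,
    _U_W39,
    _U_SB1,
    _U_W40,
    _U_SB2,
    _U_MODE,
    _U_MAT,
    _U_MAT_SEV,
    _U_MAT_ICU,
    _U_NEO,
    _U_APGAR,
) = range(_N_SLOTS)

TRAJECTORY_COLUMNS = [
    "arm",
    "maternal_age",
    "bishop_score",
    "favorability",
    "delivery_week",
    "labor_onset",
    "mode",
    "maternal_state",
    "fetal_survival",
    "neonatal_state",
    "apgar5",
]


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated woman/fetus dyad's complete path through the model."""

    arm: str
    maternal_age: float
    bishop_score: int
    favorability: str
    delivery_week: int
    labor_onset: str
    mode: str
    maternal_state: str
    fetal_survival: str
    neonatal_state: str
    apgar5: int | None


def _patient_uniforms(seed: int, n: int) -> np.ndarray:
    """(n, slots) uniform block; row i depends only on (seed, i)."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(seed))))
    return rng.random((n, _N_SLOTS))


def _curve_from_ps(ps: ParameterSet) -> bishop.CsCurveModel | None:
    if ps.bishop_curve_points:
        return bishop.fit_cs_curve(ps.bishop_curve_points)
    return None


def _kernel(arm: Arm, v, curve: bishop.CsCurveModel | None, u: np.ndarray) -> pd.DataFrame:
    """Vectorised trajectory kernel.

    ``v`` maps parameter names to scalars or length-n arrays (the latter for
    per-patient probabilistic sensitivity draws); ``u`` is the (n, slots)
    uniform block.
    """
    n = u.shape[0]
    unfav = u[:, _U_FAV] < v["p_unfavorable_cervix"]
    score = np.where(
        unfav,
        np.floor(u[:, _U_SCORE] * 5),
        5 + np.floor(u[:, _U_SCORE] * 8),
    ).astype(int)
    # maternal age: normal quantile transform of the age slot around the
    # realized location; under PSA the realized per-patient draw already
    # carries the normal spread, so the slot perturbation is skipped there.
    if np.ndim(v["maternal_age"]) == 0:
        if "maternal_age_sd" in v:
            age = float(v["maternal_age"]) + float(v["maternal_age_sd"]) * ndtri(
                np.clip(u[:, _U_AGE], 1e-12, 1 - 1e-12)
            )
        else:
            age = np.full(n, float(v["maternal_age"]))
    else:
        age = np.asarray(v["maternal_age"], dtype=float)

    if arm is Arm.EIOL_39:
        week = np.full(n, 39)
        onset = np.full(n, "elective_induction", dtype=object)
        stillbirth = np.zeros(n, dtype=bool)
        p_cs = np.where(unfav, v["p_cs_eiol_unfav"], v["p_cs_eiol_fav"])
    else:
        s39 = np.broadcast_to(np.asarray(v["p_spont_labor_39"], dtype=float), (n,))
        i39 = np.broadcast_to(np.asarray(v["p_indicated_iol_39"], dtype=float), (n,))
        sbp1 = np.broadcast_to(np.asarray(v["p_stillbirth_39_40"], dtype=float), (n,))
        s40 = np.broadcast_to(np.asarray(v["p_spont_labor_40"], dtype=float), (n,))
        i40 = np.broadcast_to(np.asarray(v["p_indicated_iol_40"], dtype=float), (n,))
        sbp2 = np.broadcast_to(np.asarray(v["p_stillbirth_40_41"], dtype=float), (n,))

        spont39 = u[:, _U_W39] < s39
        ind39 = ~spont39 & (u[:, _U_W39] < s39 + i39)
        cont39 = ~spont39 & ~ind39
        sb1 = cont39 & (u[:, _U_SB1] < sbp1)
        reach40 = cont39 & ~sb1
        spont40 = reach40 & (u[:, _U_W40] < s40)
        ind40 = reach40 & ~spont40 & (u[:, _U_W40] < s40 + i40)
        cont40 = reach40 & ~spont40 & ~ind40
        sb2 = cont40 & (u[:, _U_SB2] < sbp2)
        reach41 = cont40 & ~sb2

        week = np.select(
            [spont39 | ind39, spont40 | ind40 | sb1, reach41 | sb2], [39, 40, 41]
        )
        # the three conditions partition the arm, so the default is unreachable
        onset = np.select(
            [spont39 | spont40, ind39 | ind40 | sb1, reach41 | sb2],
            ["spontaneous", "indicated_induction", "scheduled_41wk_induction"],
            default="",
        ).astype(object)
        stillbirth = sb1 | sb2

        def ctx(name):
            return np.where(unfav, v[f"p_{name}_unfav"], v[f"p_{name}_fav"])

        if curve is not None:
            p41 = curve.predict(score)
        else:
            p41 = np.where(unfav, v["p_cs_ind_41_unfav"], v["p_cs_ind_41_fav"])
        p_cs = np.select(
            [spont39, ind39, sb1 | ind40, spont40, reach41 | sb2],
            [ctx("cs_spont_39"), ctx("cs_ind_39"), ctx("cs_ind_40"), ctx("cs_spont_40"), p41],
        )

    cesarean = u[:, _U_MODE] < p_cs

    p_mat_death = np.where(cesarean, v["p_mat_death_cesarean"], v["p_mat_death_vaginal"])
    p_mat_morb = np.where(cesarean, v["p_mat_morb_cesarean"], v["p_mat_morb_vaginal"])
    mat_death = u[:, _U_MAT] < p_mat_death
    mat_morb = ~mat_death & (u[:, _U_MAT] < p_mat_death + p_mat_morb)
    mat_severe = mat_morb & (u[:, _U_MAT_SEV] < v["p_mat_severe_given_morb"])
    mat_icu = mat_severe & (u[:, _U_MAT_ICU] < v["p_mat_icu_given_severe"])
    maternal_state = np.select(
        [mat_death, mat_icu, mat_severe, mat_morb],
        ["death", "severe_morbidity_ICU", "severe_morbidity_LD", "morbidity"],
        default="no_complication",
    ).astype(object)

    p_neo_death = np.where(cesarean, v["p_neo_death_cesarean"], v["p_neo_death_vaginal"])
    p_neo_sev = np.where(cesarean, v["p_neo_severe_cesarean"], v["p_neo_severe_vaginal"])
    p_neo_morb = np.where(cesarean, v["p_neo_morb_cesarean"], v["p_neo_morb_vaginal"])
    live = ~stillbirth
    neo_death = live & (u[:, _U_NEO] < p_neo_death)
    neo_sev = live & ~neo_death & (u[:, _U_NEO] < p_neo_death + p_neo_sev)
    neo_morb = live & ~neo_death & ~neo_sev & (
        u[:, _U_NEO] < p_neo_death + p_neo_sev + p_neo_morb
    )
    neonatal_state = np.select(
        [stillbirth, neo_death, neo_sev, neo_morb],
        ["not_applicable", "death", "severe_morbidity", "morbidity"],
        default="no_complication",
    ).astype(object)

    # Apgar sampled uniformly within the band implied by the neonatal state
    apgar = np.full(n, np.nan)
    ua = u[:, _U_APGAR]
    apgar[neo_sev] = 1 + np.floor(ua[neo_sev] * 3)
    apgar[neo_morb] = 4 + np.floor(ua[neo_morb] * 4)
    healthy = live & ~neo_death & ~neo_sev & ~neo_morb
    apgar[healthy] = 8 + np.floor(ua[healthy] * 3)

    return pd.DataFrame(
        {
            "arm": arm.value,
            "maternal_age": np.round(np.broadcast_to(age, (n,)), 3),
            "bishop_score": score,
            "favorability": np.where(unfav, "unfavorable", "favorable"),
            "delivery_week": week.astype(int),
            "labor_onset": onset,
            "mode": np.where(cesarean, "cesarean", "vaginal"),
            "maternal_state": maternal_state,
            "fetal_survival": np.where(stillbirth, "stillbirth", "live_birth"),
            "neonatal_state": neonatal_state,
            "apgar5": apgar,
        }
    )


def _augment_age_sd(ps: ParameterSet, values: dict) -> dict:
    """Expose the age spread for the point-valued (non-PSA) path."""
    dist = ps.entries["maternal_age"].dist if "maternal_age" in ps.entries else None
    if dist is not None and dist.kind == "normal":
        values = dict(values)
        values["maternal_age_sd"] = dist.params["sd"]
    return values


def simulate_patient(
    arm: Arm | str, rp: RealizedParameters, seed: int, curve: bishop.CsCurveModel | None = None
) -> PatientTrajectory:
    """Simulate a single trajectory; identical (arm, rp, seed) give
    identical output."""
    arm = Arm(arm)
    u = _patient_uniforms(seed, 1)
    df = _kernel(arm, rp.values, curve, u)
    return frame_to_trajectories(df)[0]


def simulate_cohort(
    arm: Arm | str,
    n: int,
    ps: ParameterSet,
    seed: int,
    psa: bool = False,
) -> pd.DataFrame:
    """Simulate ``n`` independent trajectories through one arm.

    With ``psa=True`` every parameter is redrawn per patient from its
    uncertainty distribution; otherwise point values are used.  Returns a
    one-row-per-patient trajectory frame (see
    :func:`frame_to_trajectories` for dataclass conversion).
    """
    arm = Arm(arm)
    n = int(n)
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if psa:
        rp = sample_parameters(ps, seed, size=n)
        values = rp.values
    else:
        values = _augment_age_sd(ps, realize_points(ps, seed).values)
    curve = _curve_from_ps(ps)
    u = _patient_uniforms(seed, n)
    return _kernel(arm, values, curve, u)


def frame_to_trajectories(df: pd.DataFrame) -> list[PatientTrajectory]:
    """Convert a trajectory frame to a list of dataclasses."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PatientTrajectory(
                arm=row.arm,
                maternal_age=float(row.maternal_age),
                bishop_score=int(row.bishop_score),
                favorability=row.favorability,
                delivery_week=int(row.delivery_week),
                labor_onset=row.labor_onset,
                mode=row.mode,
                maternal_state=row.maternal_state,
                fetal_survival=row.fetal_survival,
                neonatal_state=row.neonatal_state,
                apgar5=None if np.isnan(row.apgar5) else int(row.apgar5),
            )
        )
    return out


_SATURATION_RATES = (
    "cesarean",
    "maternal_morbidity",
    "stillbirth",
    "neonatal_death",
    "neonatal_severe_morbidity",
)


def run_to_saturation(
    ps: ParameterSet,
    seed: int,
    tol: float = 0.002,
    n_start: int = 100_000,
    n_max: int = 1_000_000,
    psa: bool = False,
):
    """Double the cohort size until the headline rates stabilise.

    Starts at ``n_start`` and doubles (capped at ``n_max``) until every
    headline rate changes by less than ``tol`` between consecutive stages.
    A first stage whose headline rates all have zero binomial variance
    (every rate exactly 0 or 1) is already saturated and stops immediately.
    Returns ``((summary_eiol, summary_em), n_used)``.
    """
    from .compare import summarize  # local import to avoid a module cycle
    from .preferences import PreferenceWeights

    pw = PreferenceWeights.from_realized(
        realize_points(ps), ps.preferences.get("weight_convention", "literal")
    )

    def stage(n):
        a = summarize(simulate_cohort(Arm.EIOL_39, n, ps, seed, psa=psa), pw)
        b = summarize(simulate_cohort(Arm.EM_41, n, ps, seed, psa=psa), pw)
        return a, b

    n = int(n_start)
    prev = stage(n)
    degenerate = all(
        s.rates[r] in (0.0, 1.0) for s in prev for r in _SATURATION_RATES
    )
    if degenerate:
        return prev, n
    while n < n_max:
        n_next = min(2 * n, n_max)
        cur = stage(n_next)
        delta = max(
            abs(cur[i].rates[r] - prev[i].rates[r])
            for i in (0, 1)
            for r in _SATURATION_RATES
        )
        n, prev = n_next, cur
        if delta < tol:
            break
    return prev, n


# -- analytic expectation of the tree (closed-form rates) ---------------


def expected_arm_rates(values, curve: bishop.CsCurveModel | None = None) -> dict:
    """Exact expected arm-level rates under scalar parameter values.

    Evaluates the decision tree's path probabilities in closed form —
    no simulation — and returns, per arm, the expected cesarean rate
    (overall and in the unfavorable-cervix subgroup), stillbirth,
    maternal morbidity/death and neonatal death/severe-morbidity/morbidity
    rates.  Serves as the calibration objective and as an independent
    cross-check of the micro-simulation.
    """
    v = values
    u = float(v["p_unfavorable_cervix"])
    f = 1.0 - u
    if curve is not None:
        c41_unfav, c41_fav = curve.band_means()
    else:
        c41_unfav, c41_fav = float(v["p_cs_ind_41_unfav"]), float(v["p_cs_ind_41_fav"])

    def maternal(cs):
        morb = cs * v["p_mat_morb_cesarean"] + (1 - cs) * v["p_mat_morb_vaginal"]
        death = cs * v["p_mat_death_cesarean"] + (1 - cs) * v["p_mat_death_vaginal"]
        return morb, death

    def neonatal(cs_live, live):
        dead = cs_live * v["p_neo_death_cesarean"] + (live - cs_live) * v["p_neo_death_vaginal"]
        sev = cs_live * v["p_neo_severe_cesarean"] + (live - cs_live) * v["p_neo_severe_vaginal"]
        morb = cs_live * v["p_neo_morb_cesarean"] + (live - cs_live) * v["p_neo_morb_vaginal"]
        return dead, sev, morb

    # eIOL arm
    cs_eiol_unfav = float(v["p_cs_eiol_unfav"])
    cs_eiol = u * cs_eiol_unfav + f * v["p_cs_eiol_fav"]
    morb_e, death_e = maternal(cs_eiol)
    nd_e, nsv_e, nmb_e = neonatal(cs_eiol, 1.0)
    eiol = {
        "cesarean": cs_eiol,
        "cesarean_unfavorable": cs_eiol_unfav,
        "stillbirth": 0.0,
        "maternal_morbidity": morb_e,
        "maternal_death": death_e,
        "neonatal_death": nd_e,
        "neonatal_severe_morbidity": nsv_e,
        "neonatal_morbidity": nmb_e,
    }

    # EM arm path probabilities (identical across favorability strata)
    s39, i39 = float(v["p_spont_labor_39"]), float(v["p_indicated_iol_39"])
    sbp1 = float(v["p_stillbirth_39_40"])
    s40, i40 = float(v["p_spont_labor_40"]), float(v["p_indicated_iol_40"])
    sbp2 = float(v["p_stillbirth_40_41"])
    c39 = 1.0 - s39 - i39
    p_sb1 = c39 * sbp1
    r40 = c39 * (1.0 - sbp1)
    p_sp40, p_in40 = r40 * s40, r40 * i40
    c40 = r40 * (1.0 - s40 - i40)
    p_sb2 = c40 * sbp2
    p_41 = c40 * (1.0 - sbp2)
    stillbirth = p_sb1 + p_sb2

    def cs_em(g):  # g in {"unfav", "fav"}
        c41 = c41_unfav if g == "unfav" else c41_fav
        return (
            s39 * v[f"p_cs_spont_39_{g}"]
            + i39 * v[f"p_cs_ind_39_{g}"]
            + (p_sb1 + p_in40) * v[f"p_cs_ind_40_{g}"]
            + p_sp40 * v[f"p_cs_spont_40_{g}"]
            + (p_sb2 + p_41) * c41
        )

    def cs_em_sb(g):  # cesarean probability mass on stillbirth paths
        c41 = c41_unfav if g == "unfav" else c41_fav
        return p_sb1 * v[f"p_cs_ind_40_{g}"] + p_sb2 * c41

    cs_u, cs_f = cs_em("unfav"), cs_em("fav")
    cs_total = u * cs_u + f * cs_f
    cs_sb = u * cs_em_sb("unfav") + f * cs_em_sb("fav")
    morb_m, death_m = maternal(cs_total)
    live = 1.0 - stillbirth
    nd_m, nsv_m, nmb_m = neonatal(cs_total - cs_sb, live)
    em = {
        "cesarean": cs_total,
        "cesarean_unfavorable": cs_u,
        "stillbirth": stillbirth,
        "maternal_morbidity": morb_m,
        "maternal_death": death_m,
        "neonatal_death": nd_m,
        "neonatal_severe_morbidity": nsv_m,
        "neonatal_morbidity": nmb_m,
    }
    return {Arm.EIOL_39.value: eiol, Arm.EM_41.value: em}
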