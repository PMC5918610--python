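"""Arm summaries, contingency contrasts and sensitivity analyses.

Outcome rates are contrasted between the two arms with the uncorrected
(1 degree of freedom) chi-square test on the 2x2 table of event counts —
without the Yates continuity correction, which the rare-event contrasts
(e.g. 0 versus 1 maternal death per 100,000) are sensitive to; a flag
restores it for comparison, and an exact (Fisher) p-value is reported
alongside whenever the table has an empty cell.  Rate differences are
reported per 100,000 deliveries.

One-way sensitivity sweeps re-run both arms under common random numbers at
each grid value of a preference or weighting parameter and declare the
strategy with the higher mean dyad utility optimal; probabilistic
sensitivity analysis (PSA) redraws the full parameter vector per replicate
and reports how often each strategy wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort_sim
from .cohort_sim import Arm, simulate_cohort
from .params import ParameterSet, sample_parameters, realize_points
from .preferences import PreferenceWeights, utilities_frame

__all__ = [
    "ArmSummary",
    "ComparisonResult",
    "SensitivityResult",
    "PsaResult",
    "OUTCOMES",
    "SWEEPABLE_PARAMETERS",
    "summarize",
    "compare_arms",
    "comparison_table",
    "cesareans_averted_per_100k",
    "cost_savings",
    "one_way_sensitivity",
    "psa",
    "chi_square_2x2",
]

log = logging.getLogger(__name__)

#: Outcomes tracked in every arm summary.  ``cesarean_unfavorable`` is the
#: cesarean rate *within* the unfavorable-cervix subgroup (subgroup
#: denominator); all others use the full arm as denominator.
OUTCOMES = (
    "cesarean",
    "cesarean_unfavorable",
    "maternal_morbidity",
    "maternal_death",
    "stillbirth",
    "neonatal_death",
    "neonatal_severe_morbidity",
    "neonatal_morbidity",
)

_MATERNAL_MORBID = {"morbidity", "severe_morbidity_LD", "severe_morbidity_ICU"}

#: Parameters accepted by :func:`one_way_sensitivity`.
SWEEPABLE_PARAMETERS = (
    "pref_x",
    "pref_y_maternal",
    "pref_y_neonatal",
    "maternal_age",
    "mat_sev_weight_icu",
    "mat_sev_weight_ld",
    "mat_sev_weight_mild",
    "neo_sev_weight_severe",
    "neo_sev_weight_mild",
)


@dataclass
class ArmSummary:
    """Counts, rates and utility moments of one simulated arm."""

    arm: str
    n: int
    counts: dict[str, int]
    denominators: dict[str, int]
    mean_dyad_utility: float
    sd_dyad_utility: float
    maternal_state_counts: dict[str, int] = field(default_factory=dict)
    neonatal_state_counts: dict[str, int] = field(default_factory=dict)

    @property
    def rates(self) -> dict[str, float]:
        return {
            k: (self.counts[k] / self.denominators[k] if self.denominators[k] else math.nan)
            for k in self.counts
        }


def _as_frame(trajs) -> pd.DataFrame:
    if isinstance(trajs, pd.DataFrame):
        return trajs
    rows = list(trajs)
    if not rows:
        return pd.DataFrame(columns=cohort_sim.TRAJECTORY_COLUMNS)
    return pd.DataFrame(
        {
            col: [
                (np.nan if getattr(t, col) is None else getattr(t, col))
                for t in rows
            ]
            for col in cohort_sim.TRAJECTORY_COLUMNS
        }
    )


def summarize(trajs, pw: PreferenceWeights) -> ArmSummary:
    """Aggregate a single-arm trajectory collection into an ArmSummary."""
    df = _as_frame(trajs)
    if len(df) == 0:
        raise ValueError("cannot summarize an empty trajectory list")
    arms = df["arm"].unique()
    if len(arms) != 1:
        raise ValueError(f"mixed arms in one summary: {sorted(arms)}")
    n = len(df)
    cesarean = df["mode"].to_numpy() == "cesarean"
    unfav = df["favorability"].to_numpy() == "unfavorable"
    ms = df["maternal_state"].to_numpy()
    ns = df["neonatal_state"].to_numpy()
    counts = {
        "cesarean": int(cesarean.sum()),
        "cesarean_unfavorable": int((cesarean & unfav).sum()),
        "maternal_morbidity": int(np.isin(ms, list(_MATERNAL_MORBID)).sum()),
        "maternal_death": int((ms == "death").sum()),
        "stillbirth": int((df["fetal_survival"].to_numpy() == "stillbirth").sum()),
        "neonatal_death": int((ns == "death").sum()),
        "neonatal_severe_morbidity": int((ns == "severe_morbidity").sum()),
        "neonatal_morbidity": int((ns == "morbidity").sum()),
    }
    denominators = {k: n for k in counts}
    denominators["cesarean_unfavorable"] = int(unfav.sum())
    _, _, dyad = utilities_frame(df, pw)
    return ArmSummary(
        arm=str(arms[0]),
        n=n,
        counts=counts,
        denominators=denominators,
        mean_dyad_utility=float(np.mean(dyad)),
        sd_dyad_utility=float(np.std(dyad, ddof=1)) if n > 1 else 0.0,
        maternal_state_counts={s: int((ms == s).sum()) for s in cohort_sim.MATERNAL_STATES},
        neonatal_state_counts={s: int((ns == s).sum()) for s in cohort_sim.NEONATAL_STATES},
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Chi-square statistic and p-value for the 2x2 table [[a, b], [c, d]].

    Uncorrected by default; ``yates=True`` applies the continuity
    correction.  A table with an empty margin has no information and
    returns (0, 1).
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        log.warning("degenerate 2x2 table (empty margin): statistic set to 0")
        return 0.0, 1.0
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    statistic = n * num * num / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass
class ComparisonResult:
    """Per-outcome contrast between the two arms."""

    outcome: str
    rate_eiol: float
    rate_em: float
    difference_per_100k: float  # EM minus eIOL
    chi_square: float
    p_value: float
    p_value_exact: float | None = None  # Fisher, reported when a cell is empty


def _split_arms(a: ArmSummary, b: ArmSummary) -> tuple[ArmSummary, ArmSummary]:
    by_arm = {s.arm: s for s in (a, b)}
    if set(by_arm) != {Arm.EIOL_39.value, Arm.EM_41.value}:
        raise ValueError(f"need one summary per arm, got {sorted(by_arm)}")
    return by_arm[Arm.EIOL_39.value], by_arm[Arm.EM_41.value]


def compare_arms(
    a: ArmSummary, b: ArmSummary, outcome: str, yates: bool = False
) -> ComparisonResult:
    """Chi-square contrast of one outcome between the two arm summaries."""
    eiol, em = _split_arms(a, b)
    for s in (eiol, em):
        if outcome not in s.counts:
            raise KeyError(f"outcome {outcome!r} not in summary for arm {s.arm}")
        if s.denominators[outcome] == 0:
            raise ValueError(f"zero denominator for {outcome!r} in arm {s.arm}")
    k_e, n_e = eiol.counts[outcome], eiol.denominators[outcome]
    k_m, n_m = em.counts[outcome], em.denominators[outcome]
    statistic, p = chi_square_2x2(k_e, n_e - k_e, k_m, n_m - k_m, yates=yates)
    exact = None
    if 0 in (k_e, n_e - k_e, k_m, n_m - k_m):
        exact = float(
            stats.fisher_exact([[k_e, n_e - k_e], [k_m, n_m - k_m]])[1]
        )
    rate_e, rate_m = k_e / n_e, k_m / n_m
    return ComparisonResult(
        outcome=outcome,
        rate_eiol=rate_e,
        rate_em=rate_m,
        difference_per_100k=(rate_m - rate_e) * 100_000.0,
        chi_square=statistic,
        p_value=p,
        p_value_exact=exact,
    )


def comparison_table(a: ArmSummary, b: ArmSummary, yates: bool = False) -> pd.DataFrame:
    """One comparison row per tracked outcome."""
    rows = []
    for outcome in OUTCOMES:
        r = compare_arms(a, b, outcome, yates=yates)
        rows.append(
            {
                "outcome": r.outcome,
                "rate_eiol": r.rate_eiol,
                "rate_em": r.rate_em,
                "difference_per_100k": r.difference_per_100k,
                "chi_square": r.chi_square,
                "p_value": r.p_value,
                "p_value_exact": r.p_value_exact,
            }
        )
    return pd.DataFrame(rows)


def cesareans_averted_per_100k(a: ArmSummary, b: ArmSummary) -> int:
    """Cesarean sections avoided per 100,000 deliveries by electing
    induction at 39 weeks (EM rate minus eIOL rate, scaled)."""
    eiol, em = _split_arms(a, b)
    diff = em.rates["cesarean"] - eiol.rates["cesarean"]
    return int(round(diff * 100_000.0))


def cost_savings(averted: int, unit_cost_delta: float) -> float:
    """Gross savings = averted cesareans x excess cost per cesarean."""
    if averted < 0 or unit_cost_delta < 0:
        raise ValueError("averted count and unit cost difference must be non-negative")
    return float(averted) * float(unit_cost_delta)


@dataclass
class SensitivityResult:
    """Verdicts of a one-way sweep over one parameter."""

    parameter: str
    grid: list[float]
    verdicts: list[str]  # per grid value: arm label or "indifferent"
    mean_utility_eiol: list[float]
    mean_utility_em: list[float]
    crossovers: list[tuple[float, float]] = field(default_factory=list)


_TIE_TOL = 1e-12


def one_way_sensitivity(
    param: str,
    grid: Sequence[float],
    ps: ParameterSet,
    n: int = 100_000,
    seed: int = 0,
) -> SensitivityResult:
    """Sweep one preference/weighting parameter over a grid.

    Both arms are re-simulated at each grid value with the same seed
    (common random numbers), and the strategy with the higher mean dyad
    utility is recorded; ties within 1e-12 are reported as indifferent.
    """
    if param not in SWEEPABLE_PARAMETERS:
        raise KeyError(
            f"unknown sweep parameter {param!r}; choose one of {SWEEPABLE_PARAMETERS}"
        )
    if len(grid) == 0:
        raise ValueError("sweep grid is empty")
    grid = sorted(float(g) for g in grid)
    verdicts, mu_e, mu_m = [], [], []
    convention = ps.preferences.get("weight_convention", "literal")
    for g in grid:
        ps_g = ps.with_points({param: g})
        pw = PreferenceWeights.from_realized(realize_points(ps_g), convention)
        s_e = summarize(simulate_cohort(Arm.EIOL_39, n, ps_g, seed), pw)
        s_m = summarize(simulate_cohort(Arm.EM_41, n, ps_g, seed), pw)
        diff = s_e.mean_dyad_utility - s_m.mean_dyad_utility
        if abs(diff) < _TIE_TOL:
            verdicts.append("indifferent")
        else:
            verdicts.append(Arm.EIOL_39.value if diff > 0 else Arm.EM_41.value)
        mu_e.append(s_e.mean_dyad_utility)
        mu_m.append(s_m.mean_dyad_utility)
    crossovers = [
        (grid[i], grid[i + 1])
        for i in range(len(grid) - 1)
        if "indifferent" not in (verdicts[i], verdicts[i + 1])
        and verdicts[i] != verdicts[i + 1]
    ]
    return SensitivityResult(
        parameter=param,
        grid=list(grid),
        verdicts=verdicts,
        mean_utility_eiol=mu_e,
        mean_utility_em=mu_m,
        crossovers=crossovers,
    )


@dataclass
class PsaResult:
    """Winner frequencies of the probabilistic sensitivity analysis."""

    n_draws: int
    n_per_draw: int
    frequencies: dict[str, float]
    winners: list[str] = field(default_factory=list)


def psa(
    ps: ParameterSet, n_draws: int, n_per_draw: int = 10_000, seed: int = 0
) -> PsaResult:
    """Redraw the full parameter vector per replicate and tally winners.

    Each draw samples every parameter from its distribution, simulates both
    arms, and records the strategy with the higher mean dyad utility.  Draw
    *d* derives its own substream from (seed, d), so frequencies do not
    depend on draw order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    convention = ps.preferences.get("weight_convention", "literal")
    curve = cohort_sim._curve_from_ps(ps)
    winners = []
    for d in range(int(n_draws)):
        sub = int(np.random.SeedSequence([int(seed), d]).generate_state(1)[0] % (2**31))
        rp = sample_parameters(ps, sub)
        pw = PreferenceWeights.from_realized(rp, convention)
        u = cohort_sim._patient_uniforms(sub, int(n_per_draw))
        s_e = summarize(cohort_sim._kernel(Arm.EIOL_39, rp.values, curve, u), pw)
        s_m = summarize(cohort_sim._kernel(Arm.EM_41, rp.values, curve, u), pw)
        diff = s_e.mean_dyad_utility - s_m.mean_dyad_utility
        if abs(diff) < _TIE_TOL:
            winners.append("indifferent")
        else:
            winners.append(Arm.EIOL_39.value if diff > 0 else Arm.EM_41.value)
    freq = {
        label: winners.count(label) / len(winners)
        for label in (Arm.EIOL_39.value, Arm.EM_41.value, "indifferent")
    }
    return PsaResult(
        n_draws=int(n_draws),
        n_per_draw=int(n_per_draw),
        frequencies=freq,
        winners=winners,
    )
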