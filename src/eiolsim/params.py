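"""Parameter space of the induction-timing model.

The model is driven by a named set of variables — branch probabilities of the
decision tree, morbidity-severity splits, preference weights and maternal
demographics — each carrying a point estimate plus an uncertainty
distribution (point mass, beta, triangular or normal).  A small declarative
rule language (complement / product / mixture) expresses the derived
quantities (complements of chance-node branches, path-reach probabilities,
mixture rates) so that chance-node normalisation can be audited mechanically.

The canonical model schema has 41 primary variables and 14 derived rules;
configuration files are flat JSON documents that transcribe one variable per
key, so an external baseline-probability table can be entered cell by cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "MissingVariableError",
    "RangeError",
    "NormalizationError",
    "DependencyError",
    "SamplingError",
    "DistributionSpec",
    "ParameterEntry",
    "DerivedRule",
    "ParameterSet",
    "RealizedParameters",
    "load_parameters",
    "save_parameters",
    "sample_parameters",
    "apply_derived_rules",
    "MODEL_VARIABLES",
    "MODEL_DERIVED_COUNT",
    "NODE_SUM_TOL",
]

NODE_SUM_TOL = 1e-9
_MAX_RESAMPLE = 1000

ROLES = ("branch_probability", "severity_split", "preference_weight", "demographic")

#: Canonical variable schema of the model: name -> role.  41 primary variables.
MODEL_VARIABLES: dict[str, str] = {
    # demographics
    "maternal_age": "demographic",
    # preference / utility weights
    "pref_x": "preference_weight",
    "pref_y_maternal": "preference_weight",
    "pref_y_neonatal": "preference_weight",
    "mat_sev_weight_icu": "preference_weight",
    "mat_sev_weight_ld": "preference_weight",
    "mat_sev_weight_mild": "preference_weight",
    "neo_sev_weight_severe": "preference_weight",
    "neo_sev_weight_mild": "preference_weight",
    "maternal_utility_floor": "preference_weight",
    # cervical status at 39 weeks
    "p_unfavorable_cervix": "branch_probability",
    # expectant-management weekly progression
    "p_spont_labor_39": "branch_probability",
    "p_indicated_iol_39": "branch_probability",
    "p_stillbirth_39_40": "branch_probability",
    "p_spont_labor_40": "branch_probability",
    "p_indicated_iol_40": "branch_probability",
    "p_stillbirth_40_41": "branch_probability",
    # cesarean probability per labor context (onset type x favorability x week)
    "p_cs_eiol_fav": "branch_probability",
    "p_cs_eiol_unfav": "branch_probability",
    "p_cs_spont_39_fav": "branch_probability",
    "p_cs_spont_39_unfav": "branch_probability",
    "p_cs_ind_39_fav": "branch_probability",
    "p_cs_ind_39_unfav": "branch_probability",
    "p_cs_spont_40_fav": "branch_probability",
    "p_cs_spont_40_unfav": "branch_probability",
    "p_cs_ind_40_fav": "branch_probability",
    "p_cs_ind_40_unfav": "branch_probability",
    "p_cs_ind_41_fav": "branch_probability",
    "p_cs_ind_41_unfav": "branch_probability",
    # maternal outcome given mode of delivery
    "p_mat_morb_vaginal": "branch_probability",
    "p_mat_morb_cesarean": "branch_probability",
    "p_mat_death_vaginal": "branch_probability",
    "p_mat_death_cesarean": "branch_probability",
    "p_mat_severe_given_morb": "severity_split",
    "p_mat_icu_given_severe": "severity_split",
    # neonatal outcome given mode of delivery (live births)
    "p_neo_morb_vaginal": "branch_probability",
    "p_neo_morb_cesarean": "branch_probability",
    "p_neo_severe_vaginal": "branch_probability",
    "p_neo_severe_cesarean": "branch_probability",
    "p_neo_death_vaginal": "branch_probability",
    "p_neo_death_cesarean": "branch_probability",
}

MODEL_DERIVED_COUNT = 14


class ParameterError(ValueError):
    """Base error for parameter configuration problems."""


class MissingVariableError(ParameterError):
    """A required variable is absent from the configuration."""


class RangeError(ParameterError):
    """A value lies outside its legal range."""


class NormalizationError(ParameterError):
    """A chance node's branch probabilities do not sum to one."""


class DependencyError(ParameterError):
    """A derived rule references an unresolved name."""


class SamplingError(ParameterError):
    """Sampling could not produce a constraint-satisfying draw."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of a single model variable.

    ``kind`` is one of ``point``, ``beta``, ``triangular``, ``normal``;
    ``params`` holds the kind-specific parameters (``value``; ``alpha``/
    ``beta``; ``min``/``mode``/``max``; ``mean``/``sd``).
    """

    kind: str
    params: dict[str, float]

    def validate(self, role: str, name: str = "") -> None:
        label = name or "<anonymous>"
        if self.kind == "point":
            if "value" not in self.params:
                raise ParameterError(f"{label}: point spec needs 'value'")
        elif self.kind == "beta":
            a, b = self.params.get("alpha"), self.params.get("beta")
            if a is None or b is None or a <= 0 or b <= 0:
                raise ParameterError(f"{label}: beta spec needs alpha>0 and beta>0")
        elif self.kind == "triangular":
            lo = self.params.get("min")
            mode = self.params.get("mode")
            hi = self.params.get("max")
            if lo is None or mode is None or hi is None or not (lo <= mode <= hi):
                raise ParameterError(f"{label}: triangular spec needs min <= mode <= max")
            if role in ("branch_probability", "severity_split") and not (0.0 <= lo and hi <= 1.0):
                raise RangeError(
                    f"{label}: triangular support [{lo}, {hi}] must lie within [0, 1] "
                    f"for role {role}"
                )
        elif self.kind == "normal":
            sd = self.params.get("sd")
            if self.params.get("mean") is None or sd is None or sd <= 0:
                raise ParameterError(f"{label}: normal spec needs mean and sd>0")
            if role in ("branch_probability", "severity_split"):
                raise ParameterError(
                    f"{label}: normal distributions are reserved for non-probability "
                    f"quantities (role {role} not allowed)"
                )
        else:
            raise ParameterError(f"{label}: unknown distribution kind {self.kind!r}")

    def support(self) -> tuple[float, float]:
        if self.kind == "point":
            v = self.params["value"]
            return (v, v)
        if self.kind == "beta":
            return (0.0, 1.0)
        if self.kind == "triangular":
            return (self.params["min"], self.params["max"])
        return (-math.inf, math.inf)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "point":
            v = self.params["value"]
            return v if size is None else np.full(size, v)
        if self.kind == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size)
        if self.kind == "triangular":
            lo, mode, hi = self.params["min"], self.params["mode"], self.params["max"]
            if lo == hi:  # numpy rejects a degenerate triangle
                return lo if size is None else np.full(size, lo)
            return rng.triangular(lo, mode, hi, size)
        return rng.normal(self.params["mean"], self.params["sd"], size)

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, **self.params}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistributionSpec":
        d = dict(d)
        kind = d.pop("kind")
        return cls(kind=kind, params={k: float(v) for k, v in d.items()})

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})


@dataclass(frozen=True)
class ParameterEntry:
    role: str
    point: float
    dist: DistributionSpec
    provenance: str = ""

    def validate(self, name: str) -> None:
        if self.role not in ROLES:
            raise ParameterError(f"{name}: unknown role {self.role!r}")
        if self.role in ("branch_probability", "severity_split") and not (
            0.0 <= self.point <= 1.0
        ):
            raise RangeError(
                f"{name}: point value {self.point} outside [0, 1] for role {self.role}"
            )
        self.dist.validate(self.role, name)


@dataclass(frozen=True)
class DerivedRule:
    """One declarative derived calculation.

    ``complement``: 1 - sum(of); ``product``: prod(of); ``mixture``:
    sum(weights[i] * of[i]) with ``weights`` naming other variables.
    """

    name: str
    rule: str
    of: tuple[str, ...]
    weights: tuple[str, ...] = ()

    def evaluate(self, values: Mapping[str, Any]):
        try:
            terms = [values[n] for n in self.of]
            if self.rule == "complement":
                return 1.0 - sum(terms)
            if self.rule == "product":
                return math.prod(terms) if all(np.isscalar(t) for t in terms) else np.prod(
                    np.broadcast_arrays(*terms), axis=0
                )
            if self.rule == "mixture":
                ws = [values[n] for n in self.weights]
                return sum(w * t for w, t in zip(ws, terms))
        except KeyError as exc:
            raise DependencyError(
                f"derived rule {self.name!r} references unresolved name {exc.args[0]!r}"
            ) from None
        raise ParameterError(f"derived rule {self.name!r}: unknown rule {self.rule!r}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"name": self.name, "rule": self.rule, "of": list(self.of)}
        if self.weights:
            d["weights"] = list(self.weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DerivedRule":
        return cls(
            name=d["name"],
            rule=d["rule"],
            of=tuple(d["of"]),
            weights=tuple(d.get("weights", ())),
        )


@dataclass
class ParameterSet:
    """A validated model parameter configuration.

    ``entries`` maps each primary variable to its role, point value,
    distribution and provenance; ``derived_rules`` are applied in order after
    point evaluation or sampling; ``nodes`` lists, per chance node, the
    variables (primary or derived) that must sum to one.
    """

    entries: dict[str, ParameterEntry]
    derived_rules: list[DerivedRule] = field(default_factory=list)
    nodes: dict[str, list[str]] = field(default_factory=dict)
    bishop_curve_points: list[tuple[float, float]] | None = None
    preferences: dict[str, Any] = field(default_factory=dict)
    name: str = ""

    # -- validation -----------------------------------------------------

    def validate(self, schema: Mapping[str, str] | None = None) -> None:
        """Validate entries, rules and node normalisation at point values.

        With ``schema`` (e.g. :data:`MODEL_VARIABLES`) the configuration must
        contain exactly the schema's variables with matching roles.
        """
        if schema is not None:
            missing = sorted(set(schema) - set(self.entries))
            if missing:
                raise MissingVariableError(
                    f"missing required variable(s): {', '.join(missing)}"
                )
            extra = sorted(set(self.entries) - set(schema))
            if extra:
                raise ParameterError(f"unknown variable(s): {', '.join(extra)}")
            for n, role in schema.items():
                if self.entries[n].role != role:
                    raise ParameterError(
                        f"{n}: role {self.entries[n].role!r}, schema expects {role!r}"
                    )
        for n, e in self.entries.items():
            e.validate(n)
        # derived rules must resolve in declared order
        values = self.point_values()
        for rule in self.derived_rules:
            if rule.name in self.entries:
                raise ParameterError(f"derived rule {rule.name!r} shadows a primary variable")
        self._check_nodes(values)

    def _check_nodes(self, values: Mapping[str, float]) -> None:
        for node, members in self.nodes.items():
            try:
                total = sum(values[m] for m in members)
            except KeyError as exc:
                raise DependencyError(
                    f"node {node!r} references unknown variable {exc.args[0]!r}"
                ) from None
            if abs(total - 1.0) > NODE_SUM_TOL:
                raise NormalizationError(
                    f"chance node {node!r} probabilities sum to {total:.12g}, not 1"
                )

    # -- evaluation -----------------------------------------------------

    def point_values(self) -> dict[str, float]:
        """Primary points plus derived values, evaluated in rule order."""
        values: dict[str, float] = {n: e.point for n, e in self.entries.items()}
        for rule in self.derived_rules:
            values[rule.name] = rule.evaluate(values)
        return values

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "schema": "eiolsim-params-v1",
            "variables": {
                n: {
                    "role": e.role,
                    "point": e.point,
                    "dist": e.dist.to_dict(),
                    "provenance": e.provenance,
                }
                for n, e in self.entries.items()
            },
            "derived": [r.to_dict() for r in self.derived_rules],
            "nodes": {k: list(v) for k, v in self.nodes.items()},
            "bishop_curve": (
                {"week": 41, "points": [list(p) for p in self.bishop_curve_points]}
                if self.bishop_curve_points
                else None
            ),
            "preferences": dict(self.preferences),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        entries = {}
        for n, v in d.get("variables", {}).items():
            entries[n] = ParameterEntry(
                role=v["role"],
                point=float(v["point"]),
                dist=DistributionSpec.from_dict(v["dist"]),
                provenance=v.get("provenance", ""),
            )
        curve = d.get("bishop_curve") or None
        points = (
            [(float(s), float(r)) for s, r in curve["points"]] if curve else None
        )
        return cls(
            entries=entries,
            derived_rules=[DerivedRule.from_dict(r) for r in d.get("derived", [])],
            nodes={k: list(v) for k, v in d.get("nodes", {}).items()},
            bishop_curve_points=points,
            preferences=dict(d.get("preferences", {})),
            name=d.get("name", ""),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def with_points(
        self, updates: Mapping[str, float], provenance: str | None = None
    ) -> "ParameterSet":
        """Copy with some point values replaced (point dists follow along)."""
        entries = dict(self.entries)
        for n, v in updates.items():
            old = entries[n]
            dist = (
                DistributionSpec.point(v) if old.dist.kind == "point" else old.dist
            )
            entries[n] = ParameterEntry(
                role=old.role,
                point=float(v),
                dist=dist,
                provenance=provenance if provenance is not None else old.provenance,
            )
        return ParameterSet(
            entries=entries,
            derived_rules=list(self.derived_rules),
            nodes=dict(self.nodes),
            bishop_curve_points=(
                list(self.bishop_curve_points) if self.bishop_curve_points else None
            ),
            preferences=dict(self.preferences),
            name=self.name,
        )


@dataclass
class RealizedParameters:
    """One resolved draw of the parameter vector.

    ``values`` maps every primary and derived name to a float (or, for
    per-patient probabilistic sensitivity draws, an ndarray).
    """

    values: dict[str, Any]
    rng_seed: int

    def __getitem__(self, name: str):
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values


def load_parameters(
    path: str | Path, schema: Mapping[str, str] | None = MODEL_VARIABLES
) -> ParameterSet:
    """Load and validate a parameter configuration from a JSON file.

    By default the file must cover the canonical model schema
    (:data:`MODEL_VARIABLES`); pass ``schema=None`` for free-form sets.
    """
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh)
    ps = ParameterSet.from_dict(d)
    ps.validate(schema=schema)
    return ps


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ps.to_dict(), fh, indent=1, sort_keys=False)
        fh.write("\n")


def apply_derived_rules(
    rp: RealizedParameters, rules: Sequence[DerivedRule]
) -> RealizedParameters:
    """Evaluate derived rules in declared order onto a realized vector."""
    values = dict(rp.values)
    for rule in rules:
        values[rule.name] = rule.evaluate(values)
    return RealizedParameters(values=values, rng_seed=rp.rng_seed)


def _constraints_ok(ps: ParameterSet, values: Mapping[str, Any]) -> np.ndarray | bool:
    """Check range and node constraints; vector-aware (returns row mask)."""
    ok: Any = True
    for n, e in ps.entries.items():
        if e.role in ("branch_probability", "severity_split"):
            v = np.asarray(values[n])
            ok = ok & (v >= 0.0) & (v <= 1.0)
    for rule in ps.derived_rules:
        if rule.rule in ("complement", "product"):
            v = np.asarray(values[rule.name])
            ok = ok & (v >= 0.0) & (v <= 1.0)
    for members in ps.nodes.values():
        total = sum(np.asarray(values[m]) for m in members)
        ok = ok & (np.abs(total - 1.0) <= 1e-6)
    return ok


def sample_parameters(
    ps: ParameterSet, seed: int, size: int | None = None
) -> RealizedParameters:
    """Draw every variable from its distribution and apply derived rules.

    Draws violating range or node constraints are rejected and resampled
    (up to 1000 rounds) rather than clipped, so the stated distributions are
    not distorted.  With ``size`` set, a vector of independent draws per
    variable is produced (used for per-patient probabilistic sensitivity
    analysis); rejection then applies row-wise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))
    order = list(ps.entries)

    def draw(k: int | None):
        return {n: ps.entries[n].dist.sample(rng, k) for n in order}

    if size is None:
        for _ in range(_MAX_RESAMPLE):
            values = draw(None)
            for rule in ps.derived_rules:
                values[rule.name] = rule.evaluate(values)
            if bool(np.all(_constraints_ok(ps, values))):
                return RealizedParameters(values=values, rng_seed=int(seed))
        raise SamplingError(
            f"no constraint-satisfying draw after {_MAX_RESAMPLE} attempts"
        )

    values = draw(size)
    for rule in ps.derived_rules:
        values[rule.name] = rule.evaluate(values)
    bad = ~np.asarray(_constraints_ok(ps, values) & np.ones(size, dtype=bool))
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > _MAX_RESAMPLE:
            raise SamplingError(
                f"rows without constraint-satisfying draw after {_MAX_RESAMPLE} rounds"
            )
        k = int(bad.sum())
        redraw = draw(k)
        for rule in ps.derived_rules:
            redraw[rule.name] = rule.evaluate(redraw)
        for n in redraw:
            arr = np.asarray(values[n], dtype=float).copy()
            arr[bad] = redraw[n]
            values[n] = arr
        bad_mask = ~np.asarray(
            _constraints_ok(ps, values) & np.ones(size, dtype=bool)
        )
        bad = bad_mask
    return RealizedParameters(values=values, rng_seed=int(seed))


def realize_points(ps: ParameterSet, seed: int = 0) -> RealizedParameters:
    """Resolve every variable to its point value (no sampling)."""
    return RealizedParameters(values=ps.point_values(), rng_seed=int(seed))
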