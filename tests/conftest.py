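import copy

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from eiolsim.params import ParameterSet, realize_points
from eiolsim.preferences import PreferenceWeights
from eiolsim.synthgen import load_fixture


@pytest.fixture(scope="session")
def paperlike() -> ParameterSet:
    return load_fixture("paperlike")


@pytest.fixture(scope="session")
def synthetic_default() -> ParameterSet:
    return load_fixture("synthetic_default")


@pytest.fixture(scope="session")
def paperlike_pw(paperlike) -> PreferenceWeights:
    return PreferenceWeights.from_realized(realize_points(paperlike))


def strip_curve(ps: ParameterSet) -> ParameterSet:
    """Copy without Bishop-curve points so p_cs_ind_41_* apply directly."""
    out = copy.deepcopy(ps)
    out.bishop_curve_points = None
    return out


_ALL_RISK_VARIABLES = [
    "p_stillbirth_39_40",
    "p_stillbirth_40_41",
    "p_mat_morb_vaginal",
    "p_mat_morb_cesarean",
    "p_mat_death_vaginal",
    "p_mat_death_cesarean",
    "p_neo_morb_vaginal",
    "p_neo_morb_cesarean",
    "p_neo_severe_vaginal",
    "p_neo_severe_cesarean",
    "p_neo_death_vaginal",
    "p_neo_death_cesarean",
]

_ALL_CS_VARIABLES = [
    "p_cs_eiol_fav",
    "p_cs_eiol_unfav",
    "p_cs_spont_39_fav",
    "p_cs_spont_39_unfav",
    "p_cs_ind_39_fav",
    "p_cs_ind_39_unfav",
    "p_cs_spont_40_fav",
    "p_cs_spont_40_unfav",
    "p_cs_ind_40_fav",
    "p_cs_ind_40_unfav",
    "p_cs_ind_41_fav",
    "p_cs_ind_41_unfav",
]


def zero_risk(ps: ParameterSet, **overrides) -> ParameterSet:
    """Degenerate copy: every adverse and cesarean branch probability zero
    (overridable), curve stripped so the 41-week rate is the point value."""
    points = {n: 0.0 for n in _ALL_RISK_VARIABLES + _ALL_CS_VARIABLES}
    points.update(overrides)
    return strip_curve(ps).with_points(points)


def pin_all(ps: ParameterSet) -> ParameterSet:
    """Copy with every uncertainty distribution collapsed to its point value."""
    from eiolsim.params import DistributionSpec, ParameterEntry

    out = copy.deepcopy(ps)
    out.entries = {
        n: ParameterEntry(e.role, e.point, DistributionSpec.point(e.point), e.provenance)
        for n, e in out.entries.items()
    }
    return out


@pytest.fixture()
def zero_risk_ps(paperlike) -> ParameterSet:
    return zero_risk(paperlike)
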