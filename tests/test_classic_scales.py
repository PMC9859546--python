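"""NIOSH lifting equation, RULA and REBA against the published worksheets."""

import math
from dataclasses import replace

import pytest

from mate.classic_scales import (
    Coupling,
    DurationClass,
    NioshInputs,
    RebaInputs,
    RulaInputs,
    lifting_index,
    niosh_rwl,
    reba,
    rula,
)
from mate.errors import ValidationError

IDEAL = NioshInputs(
    load_mass=23.0,
    horizontal=25.0,
    vertical=75.0,
    travel=25.0,
    asymmetry=0.0,
    frequency=0.2,
    duration_class=DurationClass.SHORT,
    coupling=Coupling.GOOD,
)


def test_ideal_lift_rwl_23_li_1():
    res = niosh_rwl(IDEAL)
    assert res.rwl == pytest.approx(23.0)
    assert res.lifting_index == pytest.approx(1.0)
    assert all(m == pytest.approx(1.0) for m in res.multipliers.values())


def test_horizontal_multiplier_halves_rwl():
    res = niosh_rwl(replace(IDEAL, horizontal=50.0))
    assert res.multipliers["hm"] == pytest.approx(0.5)
    assert res.rwl == pytest.approx(11.5)


def test_vertical_multiplier_at_reach_ceiling():
    res = niosh_rwl(replace(IDEAL, vertical=175.0))
    assert res.multipliers["vm"] == pytest.approx(0.7)


def test_horizontal_clamped_below_25cm():
    assert niosh_rwl(replace(IDEAL, horizontal=10.0)).multipliers["hm"] == pytest.approx(1.0)


def test_out_of_reach_lift_flagged_not_zero_li():
    """H beyond 63 cm zeroes the RWL; LI is flagged infinite, never 0."""
    res = niosh_rwl(replace(IDEAL, horizontal=80.0))
    assert res.rwl == 0.0
    assert not res.rwl_defined
    assert math.isinf(res.lifting_index)


@pytest.mark.parametrize(
    "freq, duration, vertical, expected_fm",
    [
        (0.2, DurationClass.LONG, 75.0, 0.85),
        (3.0, DurationClass.LONG, 75.0, 0.55),
        (9.0, DurationClass.LONG, 30.0, 0.00),  # V<75 zeroes the cell
        (9.0, DurationClass.LONG, 75.0, 0.15),
        (15.0, DurationClass.SHORT, 30.0, 0.00),
        (15.0, DurationClass.SHORT, 75.0, 0.28),
        (2.5, DurationClass.MODERATE, 75.0, 0.79),  # banded: next listed freq (3)
        (16.0, DurationClass.SHORT, 75.0, 0.00),
    ],
)
def test_frequency_multiplier_bands(freq, duration, vertical, expected_fm):
    res = niosh_rwl(replace(IDEAL, frequency=freq, duration_class=duration, vertical=vertical))
    assert res.multipliers["fm"] == pytest.approx(expected_fm)


@pytest.mark.parametrize(
    "coupling, vertical, expected_cm",
    [
        (Coupling.GOOD, 30.0, 1.00),
        (Coupling.FAIR, 30.0, 0.95),
        (Coupling.FAIR, 80.0, 1.00),
        (Coupling.POOR, 80.0, 0.90),
    ],
)
def test_coupling_multiplier(coupling, vertical, expected_cm):
    res = niosh_rwl(replace(IDEAL, coupling=coupling, vertical=vertical))
    assert res.multipliers["cm"] == pytest.approx(expected_cm)


@pytest.mark.parametrize(
    "field, worse",
    [
        ("horizontal", 40.0),
        ("vertical", 120.0),
        ("travel", 100.0),
        ("asymmetry", 90.0),
        ("frequency", 6.0),
    ],
)
def test_rwl_non_increasing_as_inputs_worsen(field, worse):
    assert niosh_rwl(replace(IDEAL, **{field: worse})).rwl <= niosh_rwl(IDEAL).rwl


def test_vertical_beyond_equation_domain_rejected():
    with pytest.raises(ValidationError, match="175"):
        NioshInputs(load_mass=5, horizontal=30, vertical=200, travel=30)


NEUTRAL_RULA = RulaInputs(
    upper_arm=1, lower_arm=1, wrist=1, wrist_twist=1, neck=1, trunk=1, legs=1
)
WORST_RULA = RulaInputs(
    upper_arm=6, lower_arm=3, wrist=4, wrist_twist=2, neck=6, trunk=6, legs=2,
    muscle_use_a=1, force_load_a=3, muscle_use_b=1, force_load_b=3,
)
NEUTRAL_REBA = RebaInputs(trunk=1, neck=1, legs=1, upper_arm=1, lower_arm=1, wrist=1)
WORST_REBA = RebaInputs(
    trunk=5, neck=3, legs=4, upper_arm=6, lower_arm=2, wrist=3, load=3, coupling=3, activity=3
)


def test_neutral_postures_score_one():
    assert rula(NEUTRAL_RULA) == 1
    assert reba(NEUTRAL_REBA) == 1


def test_worst_postures_hit_table_maxima():
    assert rula(WORST_RULA) == 7
    assert reba(WORST_REBA) == 15


def test_known_mid_chain_cells():
    # raised arm, neutral elsewhere: table A chain gives the published 4
    raised_arm = replace(NEUTRAL_RULA, upper_arm=5)
    assert rula(raised_arm) == 4  # A=5, B=1 -> C[5][1]=4
    stooped = replace(NEUTRAL_REBA, trunk=4, legs=2)
    assert reba(stooped) == 4  # table A [neck1][trunk4][legs2]=5 -> C[5][1]=4


def test_scores_deterministic_and_in_range(rng):
    for _ in range(50):
        ri = RulaInputs(
            upper_arm=int(rng.integers(1, 7)),
            lower_arm=int(rng.integers(1, 4)),
            wrist=int(rng.integers(1, 5)),
            wrist_twist=int(rng.integers(1, 3)),
            neck=int(rng.integers(1, 7)),
            trunk=int(rng.integers(1, 7)),
            legs=int(rng.integers(1, 3)),
        )
        s = rula(ri)
        assert s == rula(ri)
        assert 1 <= s <= 7
        bi = RebaInputs(
            trunk=int(rng.integers(1, 6)),
            neck=int(rng.integers(1, 4)),
            legs=int(rng.integers(1, 5)),
            upper_arm=int(rng.integers(1, 7)),
            lower_arm=int(rng.integers(1, 3)),
            wrist=int(rng.integers(1, 4)),
            load=int(rng.integers(0, 4)),
            coupling=int(rng.integers(0, 4)),
            activity=int(rng.integers(0, 4)),
        )
        b = reba(bi)
        assert b == reba(bi)
        assert 1 <= b <= 15


def test_posture_descriptor_range_validation():
    with pytest.raises(ValidationError, match="upper_arm"):
        RulaInputs(upper_arm=7, lower_arm=1, wrist=1, wrist_twist=1, neck=1, trunk=1, legs=1)
    with pytest.raises(ValidationError, match="legs"):
        RebaInputs(trunk=1, neck=1, legs=5, upper_arm=1, lower_arm=1, wrist=1)
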