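"""Vertebral strength, S-N interpolation and the max-cycles search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mate.errors import ValidationError
from mate.io_types import FatigueTable, SubjectProfile, TaskSchedule
from mate.spine_risk import (
    UcsModel,
    assess_spine,
    classify_spine,
    cycle_count,
    default_fatigue_table,
    default_ucs_model,
    failure_probability,
    max_cycles_before_risk,
    ultimate_compressive_strength,
)

FIXTURE_MODEL = UcsModel(c0=10.0, c_age=0.5, c_sex=0.0, b0=1.0, b1=0.0)


def _subject(age, bmi=25.0, sex="female"):
    return SubjectProfile(age=age, bmi=bmi, sex=sex)


def test_ucs_linear_fixture():
    # 10 kN baseline minus 0.5 kN/decade at age 40 -> 8 kN
    assert ultimate_compressive_strength(_subject(40), FIXTURE_MODEL) == pytest.approx(8000.0)


def test_ucs_declines_with_age():
    assert ultimate_compressive_strength(
        _subject(60), FIXTURE_MODEL
    ) < ultimate_compressive_strength(_subject(20), FIXTURE_MODEL)


def test_ucs_sex_offset():
    male = ultimate_compressive_strength(_subject(40, sex="male"), UcsModel(10, 0.5, c_sex=1.5))
    female = ultimate_compressive_strength(_subject(40, sex="female"), UcsModel(10, 0.5, c_sex=1.5))
    assert male - female == pytest.approx(1500.0)


def test_ucs_bmi_area_factor_ratio():
    model = UcsModel(c0=10.0, c_age=0.0, b0=0.8, b1=0.01)
    hi = ultimate_compressive_strength(_subject(40, bmi=30), model)
    lo = ultimate_compressive_strength(_subject(40, bmi=20), model)
    assert hi / lo == pytest.approx((0.8 + 0.3) / (0.8 + 0.2))


def test_ucs_model_rejects_nonpositive_domain():
    with pytest.raises(ValidationError, match="unsuitable|non-positive"):
        UcsModel(c0=3.0, c_age=0.5)  # negative for an age-100 female


@pytest.mark.parametrize(
    "reps, minutes, expected", [(3, 120, 360), (0.2, 120, 24), (0, 120, 0)]
)
def test_cycle_count(reps, minutes, expected):
    assert cycle_count(TaskSchedule(6, reps, minutes)) == expected


def _hand_bilinear(table, load, n):
    """Independent oracle: textbook bilinear formula in (load, log10 n)."""
    L, C, P = table.load_levels, np.log10(table.cycle_levels), table.probability
    if load < L[0]:
        return 0.0
    load = min(load, L[-1])
    x = np.clip(np.log10(max(n, 1.0)), C[0], C[-1])
    i = np.clip(np.searchsorted(L, load) - 1, 0, len(L) - 2)
    j = np.clip(np.searchsorted(C, x) - 1, 0, len(C) - 2)
    u = (load - L[i]) / (L[i + 1] - L[i])
    v = (x - C[j]) / (C[j + 1] - C[j])
    return (
        P[i, j] * (1 - u) * (1 - v)
        + P[i + 1, j] * u * (1 - v)
        + P[i, j + 1] * (1 - u) * v
        + P[i + 1, j + 1] * u * v
    )


def test_interpolation_exact_at_nodes(toy_table):
    assert failure_probability(50, 1000, toy_table) == pytest.approx(0.6)
    assert failure_probability(30, 10, toy_table) == pytest.approx(0.0)


def test_interpolation_hand_midpoint(toy_table):
    # load midway between 30 and 50; 100 cycles midway in log10 between 10 and 1000
    assert failure_probability(40, 100, toy_table) == pytest.approx(0.225)


def test_below_endurance_region_is_zero(toy_table):
    assert failure_probability(10, 10**6, toy_table) == 0.0


def test_above_top_load_clamps_to_top_row(toy_table):
    assert failure_probability(90, 1000, toy_table) == pytest.approx(0.6)


def test_zero_cycles_is_zero(toy_table):
    assert failure_probability(50, 0, toy_table) == 0.0


def test_interpolation_matches_oracle_on_random_queries(toy_table, rng):
    tables = [toy_table, default_fatigue_table()]
    for table in tables:
        for _ in range(200):
            load = rng.uniform(0, 120)
            n = 10 ** rng.uniform(0, 6)
            assert failure_probability(load, n, table) == pytest.approx(
                _hand_bilinear(table, load, n), abs=1e-12
            )


def test_probability_doubly_monotone(rng):
    table = default_fatigue_table()
    loads = np.sort(rng.uniform(0, 110, size=30))
    cycles = np.sort(10 ** rng.uniform(0, 5.5, size=30))
    for n in cycles[::6]:
        p = [failure_probability(l, n, table) for l in loads]
        assert all(b >= a - 1e-12 for a, b in zip(p, p[1:]))
    for l in loads[::6]:
        p = [failure_probability(l, n, table) for n in cycles]
        assert all(b >= a - 1e-12 for a, b in zip(p, p[1:]))


@given(
    c0=st.floats(min_value=8.0, max_value=12.0),
    c_age=st.floats(min_value=0.0, max_value=0.7),
    b1=st.floats(min_value=0.0, max_value=0.02),
    age_young=st.floats(min_value=15, max_value=60),
    delta=st.floats(min_value=1.0, max_value=40.0),
    force=st.floats(min_value=500.0, max_value=8000.0),
)
def test_older_subject_never_safer(c0, c_age, b1, age_young, delta, force):
    """With any valid strength model, age cannot reduce failure probability."""
    model = UcsModel(c0=c0, c_age=c_age, b0=0.8, b1=b1)
    table = default_fatigue_table()
    schedule = TaskSchedule(6, 3, 120)
    young = assess_spine(force, _subject(age_young), schedule, model, table)
    old = assess_spine(force, _subject(min(age_young + delta, 100)), schedule, model, table)
    assert old.failure_probability >= young.failure_probability - 1e-12


@pytest.mark.parametrize("p, expected", [(0.25, True), (0.10, False), (0.0, False)])
def test_classify_strict_ten_percent_cutoff(p, expected):
    assert classify_spine(p) is expected


def _max_cycles_scan(rel_load, table, threshold):
    """Brute-force oracle over the integer cycle grid."""
    best = 0
    for n in range(1, int(table.cycle_levels[-1]) + 1):
        if failure_probability(rel_load, n, table) <= threshold:
            best = n
    return best


def test_max_cycles_matches_scan_oracle(toy_table):
    model = FIXTURE_MODEL
    subject = _subject(40)  # UCS 8000 N
    for force in [1000.0, 3200.0, 4000.0, 4800.0, 8000.0]:
        rel = 100.0 * force / 8000.0
        expected = _max_cycles_scan(rel, toy_table, 0.10)
        got = max_cycles_before_risk(force, subject, model, toy_table, 0.10)
        if failure_probability(rel, toy_table.cycle_levels[-1], toy_table) <= 0.10:
            expected = int(toy_table.cycle_levels[-1])
        assert got == expected


def test_max_cycles_edge_cases(toy_table):
    subject = _subject(40)
    # 10% of UCS: below the lowest load level, never at risk
    assert max_cycles_before_risk(800.0, subject, FIXTURE_MODEL, toy_table) == 1000
    # top-row table whose single cycle already exceeds the cutoff
    hot = FatigueTable([30.0, 50.0], [10.0, 1000.0], [[0.2, 0.3], [0.5, 0.9]])
    assert max_cycles_before_risk(8000.0, subject, FIXTURE_MODEL, hot, 0.10) == 0


def test_max_cycles_decreases_with_age():
    """Older workers tolerate fewer cycles at the same L5 force."""
    table = default_fatigue_table()
    model = default_ucs_model()
    force = 3500.0
    cycles = [
        max_cycles_before_risk(force, _subject(age, bmi=23), model, table)
        for age in [25, 40, 55, 70]
    ]
    assert all(b <= a for a, b in zip(cycles, cycles[1:]))
    assert cycles[-1] < cycles[0]


def test_assess_spine_composition():
    table = default_fatigue_table()
    sa = assess_spine(4000.0, _subject(40, bmi=23), TaskSchedule(6, 3, 120), default_ucs_model(), table)
    assert sa.relative_load == pytest.approx(100 * 4000 / sa.ucs)
    assert sa.n_cycles == 360
    assert sa.failure_probability == pytest.approx(
        failure_probability(sa.relative_load, 360, table)
    )
    assert sa.high_risk == (sa.failure_probability > 0.10)
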