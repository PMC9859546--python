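"""Cutoff calibration on labeled tasks, checked against brute-force sweeps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mate.calibration import (
    LabeledTask,
    RiskLabel,
    calibrate,
    candidate_thresholds,
    evaluate_threshold,
    load_tasks_csv,
    sweep,
)
from mate.errors import ValidationError


def _tasks(pairs):
    return [
        LabeledTask(f"t{i}", p, RiskLabel(lbl)) for i, (p, lbl) in enumerate(pairs)
    ]


def test_perfectly_separated_pair():
    res = evaluate_threshold(_tasks([(0.05, "low"), (0.20, "high")]), 0.10)
    assert res.overall_accuracy == 1.0
    assert res.high_risk_accuracy == 1.0
    assert res.low_risk_accuracy == 1.0
    assert res.confusion == {"tp": 1, "fp": 0, "tn": 1, "fn": 0}


def test_inverted_pair_scores_zero():
    res = evaluate_threshold(_tasks([(0.05, "high"), (0.20, "low")]), 0.10)
    assert res.overall_accuracy == 0.0


def test_empty_and_single_class():
    with pytest.raises(ValidationError):
        evaluate_threshold([], 0.1)
    res = evaluate_threshold(_tasks([(0.2, "high"), (0.3, "high")]), 0.1)
    assert res.overall_accuracy == 1.0
    assert res.low_risk_accuracy is None  # absent class flagged as undefined


def _brute_force_best(tasks, grid=None):
    """Oracle: dense threshold scan with manual confusion counting."""
    probs = sorted({t.failure_probability for t in tasks})
    if grid is None:
        grid = np.unique(np.concatenate([np.linspace(0, 1, 2001), probs]))
    best = None
    for thr in grid:
        tp = sum(1 for t in tasks if t.failure_probability > thr and t.label is RiskLabel.HIGH)
        tn = sum(1 for t in tasks if t.failure_probability <= thr and t.label is RiskLabel.LOW)
        acc = (tp + tn) / len(tasks)
        if best is None or acc > best:
            best = acc
    return best


SIX_TASKS = _tasks(
    [(0.02, "low"), (0.08, "low"), (0.12, "high"), (0.15, "low"), (0.22, "high"), (0.40, "high")]
)


def test_sweep_matches_enumeration_oracle():
    df = sweep(SIX_TASKS)
    for row in df.itertuples(index=False):
        tp = sum(
            1
            for t in SIX_TASKS
            if t.failure_probability > row.threshold and t.label is RiskLabel.HIGH
        )
        tn = sum(
            1
            for t in SIX_TASKS
            if t.failure_probability <= row.threshold and t.label is RiskLabel.LOW
        )
        assert row.overall_accuracy == pytest.approx((tp + tn) / len(SIX_TASKS))
    assert calibrate(SIX_TASKS).overall_accuracy == pytest.approx(
        _brute_force_best(SIX_TASKS)
    )


def test_separable_set_recovers_a_separating_threshold():
    tasks = _tasks([(0.01, "low"), (0.05, "low"), (0.30, "high"), (0.70, "high")])
    res = calibrate(tasks)
    assert res.overall_accuracy == 1.0
    assert 0.05 < res.threshold < 0.30


def test_constant_probability_majority_vote():
    tasks = _tasks([(0.5, "high"), (0.5, "high"), (0.5, "low")])
    assert calibrate(tasks).overall_accuracy == pytest.approx(2 / 3)


def test_tie_break_prefers_sensitivity_then_low_threshold():
    # thresholds 0.05 and 0.25 both give overall 2/3, but the lower one
    # keeps the high-risk task correctly classified (sensitivity 1 vs 0)
    tasks = _tasks([(0.0, "low"), (0.1, "high"), (0.2, "low")])
    res = calibrate(tasks)
    assert res.overall_accuracy == pytest.approx(2 / 3)
    assert res.high_risk_accuracy == 1.0


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=1, width=32),
            st.sampled_from(["low", "high"]),
        ),
        min_size=2,
        max_size=30,
    ).filter(lambda ps: len({l for _, l in ps}) == 2),
    st.floats(min_value=0, max_value=1),
)
def test_calibrate_is_optimal_on_any_threshold(pairs, user_thr):
    tasks = _tasks(pairs)
    assert (
        calibrate(tasks).overall_accuracy
        >= evaluate_threshold(tasks, user_thr).overall_accuracy
    )


def test_calibrate_invariant_to_reordering(rng):
    pairs = [(float(p), "high" if rng.uniform() < 0.5 else "low") for p in rng.uniform(size=20)]
    tasks = _tasks(pairs)
    shuffled = list(tasks)
    rng.shuffle(shuffled)
    a, b = calibrate(tasks), calibrate(shuffled)
    assert a.threshold == b.threshold
    assert a.overall_accuracy == b.overall_accuracy


def test_inclusive_rule_counts_ties_as_exceedances():
    tasks = _tasks([(0.1, "high"), (0.2, "low")])
    strict = evaluate_threshold(tasks, 0.1, inclusive=False)
    incl = evaluate_threshold(tasks, 0.1, inclusive=True)
    assert strict.confusion["fn"] == 1  # 0.1 > 0.1 is false
    assert incl.confusion["tp"] == 1  # 0.1 >= 0.1 is true


def test_candidate_grid_is_midpoints_plus_bounds():
    grid = candidate_thresholds(_tasks([(0.2, "low"), (0.4, "high"), (0.4, "high")]))
    np.testing.assert_allclose(grid, [0.0, 0.3, 1.0])


def test_load_tasks_csv(tmp_path):
    p = tmp_path / "tasks.csv"
    p.write_text("id,failure_probability,label\na,0.05,low\nb,0.2,high\n")
    tasks = load_tasks_csv(p)
    assert [t.label for t in tasks] == [RiskLabel.LOW, RiskLabel.HIGH]
    bad = tmp_path / "bad.csv"
    bad.write_text("id,prob\na,0.05\n")
    with pytest.raises(ValidationError, match="missing column"):
        load_tasks_csv(bad)
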