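"""Muscle-group risk from duty cycle and maximal acceptable effort (MAE).

The maximal acceptable effort is the activation fraction a worker can sustain
at a given duty cycle without excessive fatigue:

    MAE(DC) = 1 - (DC - 1/28800)^0.24

where the duty cycle DC is the fraction of working time spent executing the
loaded movement.  The constant 1/28800 is one cycle per 8-h shift expressed
as a fraction, i.e. the DC below which a single effort per shift is always
acceptable; at DC = 1/28800 the MAE is exactly 1.  A functional muscle group
is flagged at risk when at least half of its agonists (ceiling for odd group
sizes) have a peak modeled activation strictly above the MAE — the remaining
compensatory reserve is then substantially limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_types import MuscleGroupCatalog, TimeSeriesTrace, TraceKind

__all__ = ["MIN_DUTY_CYCLE", "MuscleGroupVerdict", "duty_cycle", "mae", "group_risk"]

#: One effort per 8-hour shift (1 s of work in 28 800 s), the lower domain
#: bound of the MAE equation.
MIN_DUTY_CYCLE = 1.0 / 28800.0


def duty_cycle(schedule) -> float:
    """Fraction of working time spent executing the task.

    ``cycle_duration * repetitions_per_minute / 60``; the schedule invariant
    guarantees the result lies in [0, 1].
    """
    return schedule.cycle_duration * schedule.repetitions_per_minute / 60.0


def mae(dc: float) -> float:
    """Maximal acceptable effort at duty cycle ``dc``.

    Strictly decreasing on (1/28800, 1]; equals 1 exactly at the lower
    domain bound.

    Raises
    ------
    ValidationError
        If ``dc`` < 1/28800 (the power's base would be negative) or > 1.
    """
    if dc < MIN_DUTY_CYCLE:
        raise ValidationError(
            f"duty cycle {dc:g} below 1/28800 ({MIN_DUTY_CYCLE:.3e}): the "
            "maximal-acceptable-effort equation is undefined there"
        )
    if dc > 1.0:
        raise ValidationError(f"duty cycle must be <= 1 (got {dc:g})")
    return 1.0 - (dc - MIN_DUTY_CYCLE) ** 0.24


@dataclass(frozen=True)
class MuscleGroupVerdict:
    """Risk verdict for one functional muscle group."""

    group: str
    peak_activations: dict  # channel -> peak fraction
    mae: float
    n_exceeding: int
    at_risk: bool

    def __post_init__(self) -> None:
        n = len(self.peak_activations)
        expected = self.n_exceeding >= math.ceil(n / 2)
        if self.at_risk != expected:
            raise ValidationError(
                f"group {self.group!r}: at_risk={self.at_risk} inconsistent with "
                f"{self.n_exceeding}/{n} channels exceeding"
            )


def _peak(values: np.ndarray, window: int | None) -> float:
    if window is not None and window > 1:
        kernel = np.ones(min(window, values.size)) / min(window, values.size)
        values = np.convolve(values, kernel, mode="valid")
    return float(values.max())


def group_risk(
    trace: TimeSeriesTrace,
    catalog: MuscleGroupCatalog,
    mae_threshold: float,
    smoothing_window: int | None = None,
) -> list[MuscleGroupVerdict]:
    """Apply the half-of-agonists rule to every group in the catalog.

    For each group the peak activation of every member channel is compared to
    ``mae_threshold``; the group is at risk when the count of channels whose
    peak strictly exceeds the threshold reaches ``ceil(n/2)``.  ``exceeds``
    is strict: a peak exactly equal to the MAE does not count.

    ``smoothing_window`` (samples, default off) applies a moving average
    before taking the peak, for noisy field recordings; the default matches
    the raw-peak convention.

    Raises
    ------
    ChannelLookupError
        Listing every catalog channel absent from the trace.
    ValidationError
        If the trace does not hold activations.
    """
    if trace.kind is not TraceKind.ACTIVATION:
        raise ValidationError("group_risk requires an activation trace")
    trace.require_channels(catalog.channel_names())
    verdicts = []
    for gname, members in catalog.groups.items():
        peaks = {
            m.name: _peak(trace.channel(m.name), smoothing_window) for m in members
        }
        n_exceeding = sum(1 for p in peaks.values() if p > mae_threshold)
        verdicts.append(
            MuscleGroupVerdict(
                group=gname,
                peak_activations=peaks,
                mae=mae_threshold,
                n_exceeding=n_exceeding,
                at_risk=n_exceeding >= math.ceil(len(members) / 2),
            )
        )
    return verdicts
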