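"""Synthetic inputs for every assessment stage.

The risk layers consume only peak values and schedules, so the trace
generator favours exact peak control over kinematic realism: each channel is
a constant baseline plus a Gaussian bump of known height, time and width,
plus seeded white noise.  The calibration-set generator plants a known
probability boundary and flips labels at a controlled rate, emulating a
labeled low-back-pain incidence table.  Both are fully deterministic under a
fixed seed (numpy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import LabeledTask, RiskLabel
from .errors import ValidationError
from .io_types import TimeSeriesTrace, TraceKind

__all__ = ["ChannelSpec", "TraceSpec", "generate_trace", "generate_calibration_set"]

#: Activations are clipped here; specs may not ask for peaks above it.
ACTIVATION_PEAK_CAP = 1.2


@dataclass(frozen=True)
class ChannelSpec:
    """One synthetic channel: baseline + Gaussian bump at ``peak_time``."""

    name: str
    kind: TraceKind
    baseline: float
    peak_value: float
    peak_time: float  # s
    peak_width: float  # s, Gaussian sigma

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TraceKind(self.kind))
        if self.peak_width <= 0:
            raise ValidationError(f"channel {self.name!r}: peak_width must be > 0 s")
        if self.kind is TraceKind.ACTIVATION:
            if not 0.0 <= self.baseline <= ACTIVATION_PEAK_CAP:
                raise ValidationError(
                    f"channel {self.name!r}: activation baseline outside [0, 1.2]"
                )
            if self.peak_value > ACTIVATION_PEAK_CAP:
                raise ValidationError(
                    f"channel {self.name!r}: activation peak {self.peak_value:g} > 1.2"
                )


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic trial."""

    duration: float  # s
    sample_rate: float  # Hz
    channels: tuple = ()
    noise_sd: float = 0.0  # per-kind units (fraction or N)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValidationError("duration and sample_rate must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        chans = tuple(self.channels)
        if not chans:
            raise ValidationError("at least one channel is required")
        kinds = {c.kind for c in chans}
        if len(kinds) > 1:
            raise ValidationError("all channels in one trace must share a kind")
        names = [c.name for c in chans]
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        for c in chans:
            if not 0.0 <= c.peak_time <= self.duration:
                raise ValidationError(
                    f"channel {c.name!r}: peak_time {c.peak_time:g} outside the "
                    f"{self.duration:g} s trial"
                )
        object.__setattr__(self, "channels", chans)

    @property
    def kind(self) -> TraceKind:
        return self.channels[0].kind


def generate_trace(spec: TraceSpec) -> TimeSeriesTrace:
    """Deterministically synthesize the trial described by ``spec``.

    Samples lie on the uniform grid 0, 1/rate, ..., duration.  Activations
    are clipped to [0, 1.2] after adding noise, so a noiseless activation
    channel with an on-grid peak attains its ``peak_value`` exactly.
    """
    n = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    channels = {}
    for c in spec.channels:
        signal = c.baseline + c.peak_value * np.exp(
            -0.5 * ((t - c.peak_time) / c.peak_width) ** 2
        )
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
        if c.kind is TraceKind.ACTIVATION:
            signal = np.clip(signal, 0.0, ACTIVATION_PEAK_CAP)
        channels[c.name] = signal
    return TimeSeriesTrace(name=spec.name, time=t, channels=channels, kind=spec.kind)


def generate_calibration_set(
    n: int, boundary: float, noise: float, seed: int
) -> list[LabeledTask]:
    """Labeled tasks with a planted probability boundary and label noise.

    Failure probabilities are drawn uniformly on [0, 1]; the true label is
    high iff the probability strictly exceeds ``boundary``; each label is
    then flipped independently with probability ``noise``.  If flipping
    leaves only one class, the task with the most extreme probability on the
    appropriate side is relabeled so both classes are always present (the
    degenerate n=2 case yields one low and one high task).
    """
    if n < 2:
        raise ValidationError(f"need at least 2 tasks (got {n})")
    if not 0.0 < boundary < 1.0:
        raise ValidationError(f"boundary must be in (0, 1) (got {boundary:g})")
    if not 0.0 <= noise < 0.5:
        raise ValidationError(f"label-flip probability must be in [0, 0.5) (got {noise:g})")
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0.0, 1.0, size=n)
    labels = probs > boundary
    flips = rng.uniform(size=n) < noise
    labels = labels ^ flips
    if labels.all():
        labels[np.argmin(probs)] = False
    elif not labels.any():
        labels[np.argmax(probs)] = True
    return [
        LabeledTask(
            id=f"task_{i:04d}",
            failure_probability=float(p),
            label=RiskLabel.HIGH if hi else RiskLabel.LOW,
        )
        for i, (p, hi) in enumerate(zip(probs, labels))
    ]
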