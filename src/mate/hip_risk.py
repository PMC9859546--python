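"""Hip-cartilage risk: peak contact stress versus the endurance limit.

Hip cartilage has an experimentally determined endurance limit — a stress
below which repetitive loading never causes material failure, regardless of
cycle count.  The peak hip contact force is converted to stress by dividing
by an average femoral head area of 1610 mm²; the endurance limit is 9434 N
over that area, i.e. 5.86 MPa (about 30% of cartilage ultimate stress).
Because an endurance limit is repetition-independent by definition, the hip
verdict depends only on peak stress, never on the task schedule.

The canonical stored quantity is the force (9434 N); the stress is derived
from it, which keeps the force/area/stress triple self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io_types import TimeSeriesTrace, TraceKind

__all__ = ["HipThreshold", "peak_hip_stress", "hip_at_risk"]


def _round_sig(x: float, sig: int) -> float:
    from math import floor, log10

    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class HipThreshold:
    """Cartilage endurance limit expressed as force over femoral head area."""

    femoral_head_area: float = 1610.0  # mm²
    endurance_force: float = 9434.0  # N

    def __post_init__(self) -> None:
        if self.femoral_head_area <= 0 or self.endurance_force <= 0:
            raise ValidationError("femoral head area and endurance force must be > 0")

    @property
    def endurance_stress(self) -> float:
        """Endurance limit in MPa (force/area, 4 significant figures)."""
        return _round_sig(self.endurance_force / self.femoral_head_area, 4)


def peak_hip_stress(
    trace: TimeSeriesTrace, channel: str, threshold: HipThreshold = HipThreshold()
) -> float:
    """Peak hip contact stress in MPa for one hip channel.

    Max force over the trial (N) divided by femoral head area (mm²);
    N/mm² = MPa.
    """
    if trace.kind is not TraceKind.FORCE:
        raise ValidationError("peak_hip_stress requires a force trace")
    return trace.peak(channel) / threshold.femoral_head_area


def hip_at_risk(stress: float, threshold: HipThreshold = HipThreshold()) -> bool:
    """True iff peak stress strictly exceeds the endurance limit.

    Stresses at or below the limit cause no failure however often the task
    is repeated, so the verdict is independent of repetition by construction.
    """
    if stress < 0:
        raise ValidationError(f"stress must be >= 0 MPa (got {stress:g})")
    return stress > threshold.endurance_stress
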