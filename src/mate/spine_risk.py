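"""Vertebral fatigue-failure risk for the lower back (L5-S1).

The lower-back layer evaluates the peak L5 compressive contact force against
the ultimate compressive strength (UCS) of the vertebra and, through an S-N
failure-probability surface, against the number of loading cycles the task
schedule implies.  UCS depends on the worker: it declines with age, is higher
in males, and scales with endplate area, for which BMI serves as a linear
proxy.  The resulting failure probability is turned into a low/high-risk
verdict by a cutoff (default 10%) calibrated on labeled material-handling
tasks (see :mod:`mate.calibration`).

Both the UCS regression and the S-N surface are configuration data, not code:
the package ships representative synthetic defaults (``data/*.yaml``) and any
study should substitute its own tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, ValidationError
from .io_types import FatigueTable, Sex, SubjectProfile, TaskSchedule

__all__ = [
    "UcsModel",
    "SpineAssessment",
    "ultimate_compressive_strength",
    "cycle_count",
    "failure_probability",
    "classify_spine",
    "max_cycles_before_risk",
    "default_ucs_model",
    "default_fatigue_table",
]

#: Calibrated failure-probability cutoff separating low- from high-risk tasks.
DEFAULT_RISK_THRESHOLD = 0.10


@dataclass(frozen=True)
class UcsModel:
    """Linear model of vertebral ultimate compressive strength.

    UCS [kN] = (c0 + c_sex·[male] − c_age·age/10) × area_factor(BMI),
    area_factor(BMI) = clip(b0 + b1·BMI, 0.5, 1.5).

    ``c0`` is the female strength extrapolated to age 0, ``c_age`` the decline
    per decade, ``c_sex`` the additive male offset; the BMI factor is a proxy
    for endplate area.  Coefficients must keep UCS positive over the whole
    subject domain (age 15–100, BMI 12–60, both sexes).
    """

    c0: float  # kN
    c_age: float  # kN per decade
    c_sex: float = 0.0  # kN, added for males
    b0: float = 1.0
    b1: float = 0.0  # per kg/m²

    def __post_init__(self) -> None:
        if self.c_age < 0:
            raise ValidationError("c_age must be >= 0 (UCS non-increasing in age)")
        # worst case over the domain: oldest female, smallest area factor
        worst = (self.c0 - self.c_age * 10.0) * self.area_factor_range()[0]
        if worst <= 0:
            raise ValidationError(
                "UCS model yields non-positive strength for an age-100 female; "
                "coefficients unsuitable"
            )

    def area_factor(self, bmi: float) -> float:
        return float(np.clip(self.b0 + self.b1 * bmi, 0.5, 1.5))

    def area_factor_range(self) -> tuple[float, float]:
        corners = [self.area_factor(b) for b in (12.0, 60.0)]
        return min(corners), max(corners)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UcsModel":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                c0=float(raw["c0_kn"]),
                c_age=float(raw["c_age_kn_per_decade"]),
                c_sex=float(raw.get("c_sex_kn", 0.0)),
                b0=float(raw.get("area_b0", 1.0)),
                b1=float(raw.get("area_b1", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"UCS model {path}: missing key {exc}") from None


@dataclass
class SpineAssessment:
    """All intermediate quantities of one lower-back evaluation."""

    ucs: float  # N
    peak_force: float  # N
    relative_load: float  # % of UCS
    n_cycles: int
    failure_probability: float
    high_risk: bool
    risk_threshold: float = DEFAULT_RISK_THRESHOLD

    def __post_init__(self) -> None:
        if abs(self.relative_load - 100.0 * self.peak_force / self.ucs) > 1e-6:
            raise ValidationError("relative_load inconsistent with peak_force/ucs")
        if self.high_risk != (self.failure_probability > self.risk_threshold):
            raise ValidationError("high_risk inconsistent with failure probability")


def ultimate_compressive_strength(subject: SubjectProfile, model: UcsModel) -> float:
    """Subject-specific vertebral UCS in newtons."""
    kn = (
        model.c0
        + (model.c_sex if subject.sex is Sex.MALE else 0.0)
        - model.c_age * subject.age / 10.0
    ) * model.area_factor(subject.bmi)
    if kn <= 0:
        raise ValidationError(
            f"UCS model predicts non-positive strength ({kn:g} kN) for this subject"
        )
    return kn * 1000.0


def cycle_count(schedule: TaskSchedule) -> int:
    """Number of loading cycles in the work bout (rate × duration, rounded)."""
    return int(round(schedule.repetitions_per_minute * schedule.total_duration))


def _interpolator(table: FatigueTable) -> RegularGridInterpolator:
    # grid axes: %UCS (linear) and log10(cycles); S-N behaviour is
    # log-linear in cycles, so interpolation is done on that scale
    return RegularGridInterpolator(
        (table.load_levels, np.log10(table.cycle_levels)),
        table.probability,
        method="linear",
        bounds_error=False,
        fill_value=None,  # unused: queries are clamped before the call
    )


def failure_probability(
    relative_load: float, n_cycles: float, table: FatigueTable
) -> float:
    """Bilinear failure probability at (% of UCS, cycle count).

    Interpolation is linear in %UCS and in log10(cycles).  Loads below the
    table's lowest level lie in the endurance region and return 0; loads
    above the highest level clamp to the top row; cycle counts clamp to the
    table's cycle range.  Zero cycles means the task is never performed and
    returns 0.
    """
    if relative_load < 0:
        raise ValidationError(f"relative_load must be >= 0 (got {relative_load:g})")
    if n_cycles < 0:
        raise ValidationError(f"n_cycles must be >= 0 (got {n_cycles:g})")
    if n_cycles == 0:
        return 0.0
    if relative_load < table.load_levels[0]:
        return 0.0
    load = min(relative_load, float(table.load_levels[-1]))
    logn = float(
        np.clip(
            np.log10(max(n_cycles, 1.0)),
            np.log10(table.cycle_levels[0]),
            np.log10(table.cycle_levels[-1]),
        )
    )
    p = float(_interpolator(table)((load, logn)))
    return float(np.clip(p, 0.0, 1.0))


def classify_spine(p: float, risk_threshold: float = DEFAULT_RISK_THRESHOLD) -> bool:
    """High risk iff the failure probability strictly exceeds the cutoff."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"failure probability must be in [0, 1] (got {p:g})")
    return p > risk_threshold


def assess_spine(
    peak_force: float,
    subject: SubjectProfile,
    schedule: TaskSchedule,
    model: UcsModel,
    table: FatigueTable,
    risk_threshold: float = DEFAULT_RISK_THRESHOLD,
) -> SpineAssessment:
    """Full lower-back evaluation: UCS → relative load → probability → verdict."""
    if peak_force < 0:
        raise ValidationError(
            f"peak L5 force must be a compressive magnitude >= 0 N (got {peak_force:g})"
        )
    ucs = ultimate_compressive_strength(subject, model)
    rel = 100.0 * peak_force / ucs
    n = cycle_count(schedule)
    p = failure_probability(rel, n, table)
    return SpineAssessment(
        ucs=ucs,
        peak_force=peak_force,
        relative_load=rel,
        n_cycles=n,
        failure_probability=p,
        high_risk=classify_spine(p, risk_threshold),
        risk_threshold=risk_threshold,
    )


def max_cycles_before_risk(
    peak_force: float,
    subject: SubjectProfile,
    model: UcsModel,
    table: FatigueTable,
    risk_threshold: float = DEFAULT_RISK_THRESHOLD,
) -> int:
    """Largest cycle count whose failure probability stays at or below the cutoff.

    Drives max-cycles-versus-age curves: for a given L5 peak force, an older
    worker's lower UCS raises the relative load and shrinks the admissible
    number of cycles.  Found by bisection on the integer cycle range of the
    table; returns the table's maximum when the load never becomes risky and
    0 when even a single (clamped) cycle exceeds the cutoff.
    """
    if peak_force <= 0:
        raise ValidationError(f"peak_force must be > 0 N (got {peak_force:g})")
    ucs = ultimate_compressive_strength(subject, model)
    rel = 100.0 * peak_force / ucs
    n_max = int(table.cycle_levels[-1])
    if failure_probability(rel, n_max, table) <= risk_threshold:
        return n_max
    if failure_probability(rel, 1, table) > risk_threshold:
        return 0
    lo, hi = 1, n_max  # p(lo) <= threshold < p(hi); monotone in n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if failure_probability(rel, mid, table) <= risk_threshold:
            lo = mid
        else:
            hi = mid
    return lo


def _data_path(name: str):
    return resources.files("mate.data").joinpath(name)


def default_ucs_model() -> UcsModel:
    """Synthetic default UCS regression shipped with the package.

    Representative coefficients spanning the published 2–12 kN range of
    lumbar vertebral compressive strength; replace with study-specific
    values for real assessments.
    """
    with resources.as_file(_data_path("ucs_model_synthetic.yaml")) as p:
        return UcsModel.from_yaml(p)


def default_fatigue_table() -> FatigueTable:
    """Synthetic default S-N surface shipped with the package.

    Log-linear cycles-to-failure with an endurance region below 30% UCS;
    replace with material-test data for real assessments.
    """
    with resources.as_file(_data_path("fatigue_table_synthetic.yaml")) as p:
        table = FatigueTable.from_yaml(p)
    if table.probability.size == 0:
        raise ConfigurationError("default fatigue table is empty")
    return table
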