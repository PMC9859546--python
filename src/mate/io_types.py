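"""Domain types and file I/O for musculoskeletal-model outputs.

The assessment pipeline consumes time series exported by a musculoskeletal
simulation (muscle activations, joint contact forces) together with a task
schedule, a subject profile and a catalog mapping agonist channels to
functional muscle groups.  This module defines those containers, enforces
their invariants at construction time, and reads/writes the two text dialects
in which such time series circulate: OpenSim motion-storage (STO/MOT, header
terminated by an ``endheader`` line) and plain delimited CSV.

Units are fixed by convention and never guessed: time in seconds, forces in
newtons, activations dimensionless, masses in kg, durations of a work bout in
minutes, stresses in MPa.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ChannelLookupError, ConfigurationError, FormatError, ValidationError

__all__ = [
    "TraceKind",
    "Side",
    "Sex",
    "TimeSeriesTrace",
    "TaskSchedule",
    "SubjectProfile",
    "AgonistChannel",
    "MuscleGroupCatalog",
    "FatigueTable",
    "RiskReport",
    "read_motion_storage",
    "write_motion_storage",
    "read_task_config",
]

#: Activations above 1.0 are tolerated (optimizer overshoot) with a warning;
#: anything above this cap indicates a mis-mapped channel and is rejected.
ACTIVATION_CAP = 1.5
ACTIVATION_WARN = 1.0


class TraceKind(str, enum.Enum):
    ACTIVATION = "activation"
    FORCE = "force"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    CENTRAL = "central"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass
class TimeSeriesTrace:
    """Uniformly or non-uniformly sampled named channels for one trial.

    Parameters
    ----------
    name : str
        Trial identifier (carried into reports).
    time : array of float
        Sample times in seconds, strictly increasing.
    channels : dict of str -> array of float
        One sample vector per channel, same length as ``time``.
        Activations are dimensionless fractions; forces are newtons.
    kind : TraceKind
        Whether the channels hold activations or forces; controls range
        validation.
    """

    name: str
    time: np.ndarray
    channels: dict[str, np.ndarray]
    kind: TraceKind

    def __post_init__(self) -> None:
        self.kind = TraceKind(self.kind)
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValidationError("time must be a non-empty 1-D array")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError(
                f"trace {self.name!r}: time must be strictly increasing"
            )
        clean: dict[str, np.ndarray] = {}
        for ch, values in self.channels.items():
            v = np.asarray(values, dtype=float)
            if v.shape != self.time.shape:
                raise ValidationError(
                    f"trace {self.name!r}: channel {ch!r} has {v.size} samples, "
                    f"expected {self.time.size}"
                )
            if not np.all(np.isfinite(v)):
                raise ValidationError(
                    f"trace {self.name!r}: channel {ch!r} contains non-finite values"
                )
            if self.kind is TraceKind.ACTIVATION:
                if v.min() < 0.0 or v.max() > ACTIVATION_CAP:
                    raise ValidationError(
                        f"trace {self.name!r}: activation channel {ch!r} outside "
                        f"[0, {ACTIVATION_CAP}] (range {v.min():g}..{v.max():g})"
                    )
                if v.max() > ACTIVATION_WARN:
                    warnings.warn(
                        f"trace {self.name!r}: channel {ch!r} peaks at "
                        f"{v.max():.3f} > 1.0 (optimizer overshoot?)",
                        stacklevel=2,
                    )
            clean[ch] = v
        self.channels = clean

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Trial length in seconds (last minus first sample time)."""
        return float(self.time[-1] - self.time[0])

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelLookupError([name], self.channels) from None

    def require_channels(self, names) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ChannelLookupError(missing, self.channels)

    def peak(self, name: str) -> float:
        """Maximum value of a channel over the trial."""
        return float(self.channel(name).max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.channels})


@dataclass(frozen=True)
class TaskSchedule:
    """Work-cycle timing and handled load for one occupational task.

    ``cycle_duration`` is the time actively spent in one execution (s),
    ``repetitions_per_minute`` the cycle rate (1/min), ``total_duration`` the
    length of the work bout (min), ``handled_mass`` the load (kg).  The duty
    cycle and the number of loading cycles both derive from these fields.
    """

    cycle_duration: float
    repetitions_per_minute: float
    total_duration: float
    handled_mass: float = 0.0

    def __post_init__(self) -> None:
        if not self.cycle_duration > 0:
            raise ValidationError(
                f"cycle_duration must be > 0 s (got {self.cycle_duration})"
            )
        if self.repetitions_per_minute < 0:
            raise ValidationError(
                f"repetitions_per_minute must be >= 0 (got {self.repetitions_per_minute})"
            )
        if not self.total_duration > 0:
            raise ValidationError(
                f"total_duration must be > 0 min (got {self.total_duration})"
            )
        if self.handled_mass < 0:
            raise ValidationError(f"handled_mass must be >= 0 kg (got {self.handled_mass})")
        work = self.cycle_duration * self.repetitions_per_minute
        if work > 60.0 + 1e-9:
            raise ValidationError(
                f"cycle_duration x repetitions_per_minute = {work:g} s of work per "
                "minute exceeds 60 s: a minute cannot contain more work than itself"
            )


@dataclass(frozen=True)
class SubjectProfile:
    """Worker characteristics entering the vertebral strength model.

    BMI may be given directly or derived from mass (kg) and height (m); when
    both are supplied they must agree to within 0.05 kg/m².  Sex defaults to
    female, which yields the lower, protective vertebral strength.
    """

    age: float
    sex: Sex = Sex.FEMALE
    bmi: float | None = None
    mass: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if not 15.0 <= self.age <= 100.0:
            raise ValidationError(f"age must be in [15, 100] yr (got {self.age})")
        bmi = self.bmi
        if self.mass is not None or self.height is not None:
            if self.mass is None or self.height is None:
                raise ValidationError("mass and height must be given together")
            if self.mass <= 0 or self.height <= 0:
                raise ValidationError("mass and height must be positive")
            derived = self.mass / self.height**2
            if bmi is not None and abs(bmi - derived) >= 0.05:
                raise ValidationError(
                    f"bmi {bmi:g} inconsistent with mass/height "
                    f"({derived:.2f} kg/m², |delta| >= 0.05)"
                )
            bmi = derived if bmi is None else bmi
        if bmi is None:
            raise ValidationError("either bmi or mass+height is required")
        if not 12.0 <= bmi <= 60.0:
            raise ValidationError(f"bmi must be in [12, 60] kg/m² (got {bmi:.2f})")
        object.__setattr__(self, "bmi", float(bmi))


@dataclass(frozen=True)
class AgonistChannel:
    """One modeled muscle channel belonging to a functional group."""

    name: str
    side: Side = Side.CENTRAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", Side(self.side))


@dataclass
class MuscleGroupCatalog:
    """Mapping of functional muscle groups to their agonist channels.

    A functional group collects agonists sharing a primary action (e.g. the
    left shoulder flexors); the group-level risk rule counts how many of its
    members exceed the maximal acceptable effort.
    """

    groups: dict[str, list[AgonistChannel]]

    def __post_init__(self) -> None:
        for gname, members in self.groups.items():
            if not members:
                raise ValidationError(f"muscle group {gname!r} is empty")
            names = [m.name for m in members]
            if len(set(names)) != len(names):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(
                    f"muscle group {gname!r} lists duplicate channel(s): {', '.join(dupes)}"
                )

    def channel_names(self) -> list[str]:
        out: list[str] = []
        for members in self.groups.values():
            out.extend(m.name for m in members)
        return out


@dataclass
class FatigueTable:
    """S-N probability-of-failure surface for a biomaterial.

    ``probability[i, j]`` is the probability that the material fails within
    ``cycle_levels[j]`` loading cycles at a load of ``load_levels[i]`` percent
    of its ultimate compressive strength.  Both axes are ascending and the
    surface is non-decreasing along each: more load or more cycles never
    lowers the failure probability.
    """

    load_levels: np.ndarray  # % of UCS, ascending
    cycle_levels: np.ndarray  # cycle counts, ascending
    probability: np.ndarray  # shape (len(load_levels), len(cycle_levels))

    def __post_init__(self) -> None:
        self.load_levels = np.asarray(self.load_levels, dtype=float)
        self.cycle_levels = np.asarray(self.cycle_levels, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.load_levels.size == 0 or self.cycle_levels.size == 0:
            raise ConfigurationError(
                "fatigue table must have at least one level per axis"
            )
        if np.any(np.diff(self.load_levels) <= 0):
            raise ValidationError("load_levels must be strictly ascending")
        if np.any(np.diff(self.cycle_levels) <= 0):
            raise ValidationError("cycle_levels must be strictly ascending")
        if np.any(self.cycle_levels < 1):
            raise ValidationError("cycle_levels must be >= 1")
        if self.probability.shape != (self.load_levels.size, self.cycle_levels.size):
            raise ValidationError(
                f"probability matrix shape {self.probability.shape} does not match "
                f"({self.load_levels.size}, {self.cycle_levels.size})"
            )
        if self.probability.min() < 0 or self.probability.max() > 1:
            raise ValidationError("failure probabilities must lie in [0, 1]")
        if np.any(np.diff(self.probability, axis=0) < 0):
            raise ValidationError("failure probability must be non-decreasing in load")
        if np.any(np.diff(self.probability, axis=1) < 0):
            raise ValidationError("failure probability must be non-decreasing in cycles")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FatigueTable":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                load_levels=raw["load_levels"],
                cycle_levels=raw["cycle_levels"],
                probability=raw["probability"],
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"fatigue table {path}: missing key {exc}") from None


@dataclass
class RiskReport:
    """Assembled per-region verdicts plus optional classic-scale scores.

    A region whose input channels were absent is left as ``None`` ("not
    assessed") rather than failing the whole report.  The ``audit`` dict
    echoes every threshold and coefficient used, so a report is reproducible
    from its own content.
    """

    duty_cycle: float | None = None
    mae: float | None = None
    muscle_groups_at_risk: list[str] = field(default_factory=list)
    muscle_details: list[dict] = field(default_factory=list)
    hip_peak_stress: float | None = None  # MPa, worst assessed hip
    hip_at_risk: bool | None = None
    hip_details: list[dict] = field(default_factory=list)
    spine_failure_probability: float | None = None
    spine_high_risk: bool | None = None
    spine_risk_threshold: float = 0.10
    spine_details: dict = field(default_factory=dict)
    classic_scores: dict = field(default_factory=dict)
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spine_failure_probability is not None:
            expected = self.spine_failure_probability > self.spine_risk_threshold
            if self.spine_high_risk is None:
                self.spine_high_risk = expected
            elif self.spine_high_risk != expected:
                raise ValidationError(
                    "spine_high_risk inconsistent with failure probability "
                    f"{self.spine_failure_probability:g} vs threshold "
                    f"{self.spine_risk_threshold:g}"
                )
        if self.hip_peak_stress is not None and self.hip_at_risk is None:
            raise ValidationError("hip_at_risk must accompany hip_peak_stress")

    def to_dict(self) -> dict:
        return {
            "duty_cycle": self.duty_cycle,
            "mae": self.mae,
            "muscle_groups_at_risk": list(self.muscle_groups_at_risk),
            "muscle_details": self.muscle_details,
            "hip_peak_stress": self.hip_peak_stress,
            "hip_at_risk": self.hip_at_risk,
            "hip_details": self.hip_details,
            "spine_failure_probability": self.spine_failure_probability,
            "spine_high_risk": self.spine_high_risk,
            "spine_risk_threshold": self.spine_risk_threshold,
            "spine_details": self.spine_details,
            "classic_scores": self.classic_scores,
            "audit": self.audit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskReport":
        return cls(**{k: d.get(k, v) for k, v in _REPORT_DEFAULTS.items()})


_REPORT_DEFAULTS = {
    "duty_cycle": None,
    "mae": None,
    "muscle_groups_at_risk": [],
    "muscle_details": [],
    "hip_peak_stress": None,
    "hip_at_risk": None,
    "hip_details": [],
    "spine_failure_probability": None,
    "spine_high_risk": None,
    "spine_risk_threshold": 0.10,
    "spine_details": {},
    "classic_scores": {},
    "audit": {},
}


# ---------------------------------------------------------------------------
# Motion-storage / CSV readers and writers
# ---------------------------------------------------------------------------

def _split_row(line: str, delim: str | None) -> list[str]:
    return line.split(",") if delim == "," else line.split()


def read_motion_storage(
    path: str | Path,
    kind: TraceKind | str = TraceKind.FORCE,
    name: str | None = None,
) -> TimeSeriesTrace:
    """Read an OpenSim STO/MOT-dialect or delimited-CSV time series.

    The header is everything up to an ``endheader`` line when one is present;
    otherwise the first row is taken as the column names.  Bodies may be
    tab-, comma- or whitespace-delimited.  The first column must be time in
    seconds, strictly increasing.

    Raises
    ------
    FormatError
        Malformed header, inconsistent column counts (the message names the
        offending line) or non-numeric data.
    ValidationError
        Non-monotone time or out-of-range samples.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_meta: dict[str, str] = {}
    body_start = 0
    has_endheader = False
    for i, raw in enumerate(lines):
        if raw.strip().lower() == "endheader":
            has_endheader = True
            body_start = i + 1
            break
        if i >= 50:
            continue
        if "=" in raw:
            key, _, val = raw.partition("=")
            header_meta[key.strip().lower()] = val.strip()
        elif raw.strip() and "name" not in header_meta:
            # the STO convention: a bare first header line is the trial name
            header_meta["name"] = raw.strip()
    if not has_endheader:
        body_start = 0

    # first non-empty line after the header holds the column names
    while body_start < len(lines) and not lines[body_start].strip():
        body_start += 1
    if body_start >= len(lines):
        raise FormatError(f"{path}: no column-name row found")
    colline = lines[body_start]
    delim = "," if ("," in colline and "\t" not in colline) else None
    columns = [c.strip() for c in _split_row(colline.strip(), delim)]
    if len(columns) < 2:
        raise FormatError(
            f"{path}: line {body_start + 1}: need a time column plus at least "
            f"one data column, got {columns!r}"
        )
    declared = header_meta.get("ncolumns")
    if declared is not None and int(declared) != len(columns):
        raise FormatError(
            f"{path}: header declares nColumns={declared} but the column row "
            f"(line {body_start + 1}) has {len(columns)} names"
        )

    rows: list[list[float]] = []
    for lineno, raw in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not raw.strip():
            continue
        fields = _split_row(raw.strip(), delim)
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(columns)} values, "
                f"got {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    channels = {c: data[:, j] for j, c in enumerate(columns[1:], start=1)}
    return TimeSeriesTrace(
        name=name or header_meta.get("name", path.stem),
        time=data[:, 0],
        channels=channels,
        kind=TraceKind(kind),
    )


def write_motion_storage(
    trace: TimeSeriesTrace, path: str | Path, dialect: str = "sto"
) -> None:
    """Write a trace as STO (tab-delimited, ``endheader``) or CSV.

    Values are printed with 9 significant digits so a read/write round trip
    preserves samples well beyond the documented 6-digit guarantee.
    """
    path = Path(path)
    cols = ["time", *trace.channels.keys()]
    data = np.column_stack([trace.time, *trace.channels.values()])
    if dialect == "sto":
        sep = "\t"
        head = (
            f"{trace.name}\nversion=1\nnRows={data.shape[0]}\n"
            f"nColumns={data.shape[1]}\ninDegrees=no\nendheader\n"
        )
    elif dialect == "csv":
        sep = ","
        head = ""
    else:
        raise ValidationError(f"unknown dialect {dialect!r} (use 'sto' or 'csv')")
    with path.open("w") as fh:
        fh.write(head)
        fh.write(sep.join(cols) + "\n")
        for row in data:
            fh.write(sep.join(f"{x:.9g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Task configuration
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, section: str):
    if key not in mapping:
        raise ValidationError(f"config: missing required key '{section}.{key}'")
    return mapping[key]


def _parse_member(entry) -> AgonistChannel:
    if isinstance(entry, str):
        return AgonistChannel(entry)
    if isinstance(entry, dict):
        if "channel" not in entry:
            raise ValidationError(
                f"config: muscle-group member {entry!r} lacks a 'channel' key"
            )
        side = entry.get("side", "central")
        try:
            return AgonistChannel(entry["channel"], Side(side))
        except ValueError:
            raise ValidationError(
                f"config: side must be left/right/central (got {side!r})"
            ) from None
    raise ValidationError(f"config: cannot parse muscle-group member {entry!r}")


def read_task_config(
    path: str | Path,
) -> tuple[TaskSchedule, SubjectProfile, MuscleGroupCatalog]:
    """Load the YAML task configuration.

    Expected layout::

        task:
          cycle_duration_s: 6
          repetitions_per_minute: 3
          total_duration_min: 120
          handled_mass_kg: 10        # optional, default 0
        subject:
          age: 21
          sex: male                  # optional, default female (protective)
          mass_kg: 71.4              # either mass+height ...
          height_m: 1.75
          # bmi: 23.3                # ... or bmi directly
        muscle_groups:
          shoulder_flexors_r:
            - {channel: delt_ant_r, side: right}
            - ssp_r                  # bare string -> side central
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: top level must be a mapping")
    task = _require(raw, "task", "<root>")
    subject = _require(raw, "subject", "<root>")
    schedule = TaskSchedule(
        cycle_duration=float(_require(task, "cycle_duration_s", "task")),
        repetitions_per_minute=float(_require(task, "repetitions_per_minute", "task")),
        total_duration=float(_require(task, "total_duration_min", "task")),
        handled_mass=float(task.get("handled_mass_kg", 0.0)),
    )
    profile = SubjectProfile(
        age=float(_require(subject, "age", "subject")),
        sex=Sex(subject.get("sex", "female")),
        bmi=None if subject.get("bmi") is None else float(subject["bmi"]),
        mass=None if subject.get("mass_kg") is None else float(subject["mass_kg"]),
        height=None if subject.get("height_m") is None else float(subject["height_m"]),
    )
    groups_raw = raw.get("muscle_groups", {}) or {}
    catalog = MuscleGroupCatalog(
        groups={
            str(g): [_parse_member(m) for m in members]
            for g, members in groups_raw.items()
        }
    )
    return schedule, profile, catalog


def read_channel_map(path: str | Path) -> dict:
    """Optional ``channels:`` section of the config (L5/hip channel names)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    section = raw.get("channels", {}) or {}
    out = {}
    if "l5" in section:
        out["l5"] = str(section["l5"])
    if "hips" in section:
        hips = section["hips"]
        out["hips"] = [str(h) for h in (hips if isinstance(hips, list) else [hips])]
    return out
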