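"""Classic ergonomic scales: NIOSH lifting equation, RULA and REBA.

These table-driven scores are computed for comparison with the
tissue-threshold layers.  The recommended weight limit is

    RWL = LC · HM · VM · DM · AM · FM · CM,   LC = 23 kg

with the horizontal, vertical, distance, asymmetry, frequency and coupling
multipliers from the published standard, and the lifting index
LI = load / RWL.  RULA and REBA are exact lookups through the published
Table A/B/C chains; posture inputs are the worksheet category scores, so
scoring is a deterministic function of its inputs.

The FM/CM bands and the RULA/REBA matrices live in YAML data files with
provenance comments; they are looked up, never interpolated or regenerated
procedurally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .errors import ValidationError

__all__ = [
    "LOAD_CONSTANT",
    "DurationClass",
    "Coupling",
    "NioshInputs",
    "NioshResult",
    "niosh_rwl",
    "lifting_index",
    "RulaInputs",
    "rula",
    "RebaInputs",
    "reba",
]

LOAD_CONSTANT = 23.0  # kg


class DurationClass(str, enum.Enum):
    SHORT = "short"  # <= 1 h
    MODERATE = "moderate"  # <= 2 h
    LONG = "long"  # <= 8 h


class Coupling(str, enum.Enum):
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"


@lru_cache(maxsize=None)
def _load_data(name: str) -> dict:
    text = resources.files("mate.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class NioshInputs:
    """Lifting-equation task descriptors (distances in cm, angles in degrees)."""

    load_mass: float  # kg
    horizontal: float  # cm, hand distance from ankle midpoint
    vertical: float  # cm, hand height at lift origin
    travel: float  # cm, vertical travel distance
    asymmetry: float = 0.0  # degrees of trunk twist
    frequency: float = 0.2  # lifts/min
    duration_class: DurationClass = DurationClass.LONG
    coupling: Coupling = Coupling.GOOD

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration_class", DurationClass(self.duration_class))
        object.__setattr__(self, "coupling", Coupling(self.coupling))
        for fname in ("load_mass", "horizontal", "vertical", "travel", "asymmetry", "frequency"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{fname} must be non-negative")
        if self.vertical > 175.0:
            raise ValidationError(
                f"vertical hand location must be in [0, 175] cm (got {self.vertical:g}); "
                "above 175 cm the lift is outside the equation's domain"
            )


@dataclass(frozen=True)
class NioshResult:
    """RWL with its multiplier decomposition and the lifting index.

    ``rwl_defined`` is False when any multiplier is 0 (lift outside the
    equation's domain): the RWL is then 0 kg and the lifting index is
    reported as infinite rather than the misleading 0.
    """

    rwl: float  # kg
    lifting_index: float
    rwl_defined: bool
    multipliers: dict  # hm, vm, dm, am, fm, cm


def _frequency_multiplier(freq: float, duration: DurationClass, v_low: bool) -> float:
    table = _load_data("niosh_multipliers.yaml")["frequency_multiplier"]
    freqs = table["frequencies"]
    if freq > freqs[-1]:
        return 0.0
    # the standard uses bands: take the nearest listed frequency at or above
    idx = next(i for i, f in enumerate(freqs) if freq <= f)
    return float(table[duration.value]["v_low" if v_low else "v_high"][idx])


def _coupling_multiplier(coupling: Coupling, v_low: bool) -> float:
    table = _load_data("niosh_multipliers.yaml")["coupling_multiplier"]
    return float(table[coupling.value]["v_low" if v_low else "v_high"])


def niosh_rwl(inputs: NioshInputs) -> NioshResult:
    """Recommended weight limit and lifting index for one lift."""
    h = max(inputs.horizontal, 25.0)  # closer than 25 cm counts as 25
    hm = 25.0 / h if h <= 63.0 else 0.0
    vm = max(1.0 - 0.003 * abs(inputs.vertical - 75.0), 0.0)
    d = max(inputs.travel, 25.0)  # shorter travel counts as 25
    dm = min(0.82 + 4.5 / d, 1.0) if d <= 175.0 else 0.0
    am = max(1.0 - 0.0032 * inputs.asymmetry, 0.0) if inputs.asymmetry <= 135.0 else 0.0
    v_low = inputs.vertical < 75.0
    fm = _frequency_multiplier(inputs.frequency, inputs.duration_class, v_low)
    cm = _coupling_multiplier(inputs.coupling, v_low)
    mult = {"hm": hm, "vm": vm, "dm": dm, "am": am, "fm": fm, "cm": cm}
    rwl = LOAD_CONSTANT * hm * vm * dm * am * fm * cm
    defined = rwl > 0.0
    li = inputs.load_mass / rwl if defined else math.inf
    return NioshResult(rwl=rwl, lifting_index=li, rwl_defined=defined, multipliers=mult)


def lifting_index(inputs: NioshInputs) -> float:
    """Load divided by the RWL; infinite when the RWL is undefined (0 kg)."""
    return niosh_rwl(inputs).lifting_index


def _check_range(name: str, value: int, lo: int, hi: int) -> int:
    if not isinstance(value, (int,)) or not lo <= value <= hi:
        raise ValidationError(f"{name} must be an integer in [{lo}, {hi}] (got {value!r})")
    return value


@dataclass(frozen=True)
class RulaInputs:
    """RULA worksheet category scores (adjustments already applied).

    ``muscle_use``/``force_load`` pairs are the worksheet's static/repetitive
    muscle-use point (0–1) and force/load points (0–3), separately for the
    arm-wrist (group A) and neck-trunk-leg (group B) chains.
    """

    upper_arm: int  # 1-6
    lower_arm: int  # 1-3
    wrist: int  # 1-4
    wrist_twist: int  # 1-2
    neck: int  # 1-6
    trunk: int  # 1-6
    legs: int  # 1-2
    muscle_use_a: int = 0
    force_load_a: int = 0
    muscle_use_b: int = 0
    force_load_b: int = 0

    def __post_init__(self) -> None:
        _check_range("upper_arm", self.upper_arm, 1, 6)
        _check_range("lower_arm", self.lower_arm, 1, 3)
        _check_range("wrist", self.wrist, 1, 4)
        _check_range("wrist_twist", self.wrist_twist, 1, 2)
        _check_range("neck", self.neck, 1, 6)
        _check_range("trunk", self.trunk, 1, 6)
        _check_range("legs", self.legs, 1, 2)
        _check_range("muscle_use_a", self.muscle_use_a, 0, 1)
        _check_range("force_load_a", self.force_load_a, 0, 3)
        _check_range("muscle_use_b", self.muscle_use_b, 0, 1)
        _check_range("force_load_b", self.force_load_b, 0, 3)


def rula(inputs: RulaInputs) -> int:
    """Grand RULA score (1–7) via the published Table A/B/C chain."""
    t = _load_data("rula_tables.yaml")
    score_a = t["table_a"][inputs.upper_arm - 1][inputs.lower_arm - 1][
        inputs.wrist - 1
    ][inputs.wrist_twist - 1]
    score_b = t["table_b"][inputs.neck - 1][inputs.trunk - 1][inputs.legs - 1]
    c_row = min(score_a + inputs.muscle_use_a + inputs.force_load_a, 8)
    c_col = min(score_b + inputs.muscle_use_b + inputs.force_load_b, 7)
    return int(t["table_c"][c_row - 1][c_col - 1])


@dataclass(frozen=True)
class RebaInputs:
    """REBA worksheet category scores (adjustments already applied).

    ``load`` is the load/force score (0–3 incl. shock), ``coupling`` the
    grip score (0–3), ``activity`` the activity score (0–3).
    """

    trunk: int  # 1-5
    neck: int  # 1-3
    legs: int  # 1-4
    upper_arm: int  # 1-6
    lower_arm: int  # 1-2
    wrist: int  # 1-3
    load: int = 0
    coupling: int = 0
    activity: int = 0

    def __post_init__(self) -> None:
        _check_range("trunk", self.trunk, 1, 5)
        _check_range("neck", self.neck, 1, 3)
        _check_range("legs", self.legs, 1, 4)
        _check_range("upper_arm", self.upper_arm, 1, 6)
        _check_range("lower_arm", self.lower_arm, 1, 2)
        _check_range("wrist", self.wrist, 1, 3)
        _check_range("load", self.load, 0, 3)
        _check_range("coupling", self.coupling, 0, 3)
        _check_range("activity", self.activity, 0, 3)


def reba(inputs: RebaInputs) -> int:
    """Final REBA score (1–15) via the published Table A/B/C chain."""
    t = _load_data("reba_tables.yaml")
    score_a = (
        t["table_a"][inputs.neck - 1][inputs.trunk - 1][inputs.legs - 1] + inputs.load
    )
    score_b = (
        t["table_b"][inputs.lower_arm - 1][inputs.upper_arm - 1][inputs.wrist - 1]
        + inputs.coupling
    )
    score_c = t["table_c"][min(score_a, 12) - 1][min(score_b, 12) - 1]
    return int(score_c + inputs.activity)
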