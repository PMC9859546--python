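"""Assembling the full risk report and comparing conditions.

``assess`` is a pure composition of the module-level operations: duty cycle →
MAE → muscle-group rule; peak hip force → stress → endurance check per hip
channel; subject UCS → cycle count → failure probability → low/high verdict;
plus the classic scales when their inputs are supplied.  A region whose
channels are absent is reported as not assessed rather than failing the run.
Every threshold and coefficient used is echoed into the report's ``audit``
section so a report is auditable from its own content.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import classic_scales, hip_risk, muscle_risk, spine_risk
from .errors import ValidationError
from .io_types import (
    MuscleGroupCatalog,
    RiskReport,
    SubjectProfile,
    TaskSchedule,
    TimeSeriesTrace,
    read_channel_map,
    read_motion_storage,
    read_task_config,
    TraceKind,
)

__all__ = ["assess", "assess_traces", "compare", "render_text"]


def _find_channels(trace: TimeSeriesTrace | None, needle: str) -> list[str]:
    if trace is None:
        return []
    return [c for c in trace.channels if needle in c.lower()]


def assess_traces(
    schedule: TaskSchedule,
    subject: SubjectProfile,
    catalog: MuscleGroupCatalog,
    activations: TimeSeriesTrace | None = None,
    forces: TimeSeriesTrace | None = None,
    hip_channels: list[str] | None = None,
    l5_channel: str | None = None,
    hip_threshold: hip_risk.HipThreshold | None = None,
    ucs_model: spine_risk.UcsModel | None = None,
    fatigue_table=None,
    risk_threshold: float = spine_risk.DEFAULT_RISK_THRESHOLD,
    niosh_inputs: classic_scales.NioshInputs | None = None,
    rula_inputs: classic_scales.RulaInputs | None = None,
    reba_inputs: classic_scales.RebaInputs | None = None,
) -> RiskReport:
    """Run every applicable risk layer on in-memory objects.

    Hip and L5 channels default to name-based detection on the force trace
    (substring ``hip`` / ``l5``, case-insensitive); pass explicit names when
    the export uses other conventions.
    """
    hip_threshold = hip_threshold or hip_risk.HipThreshold()
    ucs_model = ucs_model or spine_risk.default_ucs_model()
    fatigue_table = fatigue_table if fatigue_table is not None else spine_risk.default_fatigue_table()

    dc = muscle_risk.duty_cycle(schedule)
    mae_value = muscle_risk.mae(dc)

    report = RiskReport(duty_cycle=dc, mae=mae_value, spine_risk_threshold=risk_threshold)

    if activations is not None and catalog.groups:
        verdicts = muscle_risk.group_risk(activations, catalog, mae_value)
        report.muscle_groups_at_risk = [v.group for v in verdicts if v.at_risk]
        report.muscle_details = [asdict(v) for v in verdicts]

    hips = hip_channels if hip_channels is not None else _find_channels(forces, "hip")
    if forces is not None and hips:
        details = []
        for ch in hips:
            stress = hip_risk.peak_hip_stress(forces, ch, hip_threshold)
            details.append(
                {
                    "channel": ch,
                    "peak_stress_mpa": stress,
                    "at_risk": hip_risk.hip_at_risk(stress, hip_threshold),
                }
            )
        report.hip_details = details
        report.hip_peak_stress = max(d["peak_stress_mpa"] for d in details)
        report.hip_at_risk = any(d["at_risk"] for d in details)

    l5 = l5_channel
    if l5 is None:
        found = _find_channels(forces, "l5")
        l5 = found[0] if found else None
    if forces is not None and l5 is not None:
        sa = spine_risk.assess_spine(
            forces.peak(l5), subject, schedule, ucs_model, fatigue_table, risk_threshold
        )
        report.spine_failure_probability = sa.failure_probability
        report.spine_high_risk = sa.high_risk
        report.spine_details = {
            "channel": l5,
            "ucs_n": sa.ucs,
            "peak_force_n": sa.peak_force,
            "relative_load_pct": sa.relative_load,
            "n_cycles": sa.n_cycles,
        }

    scores = {}
    if niosh_inputs is not None:
        res = classic_scales.niosh_rwl(niosh_inputs)
        scores["niosh_rwl"] = res.rwl
        scores["niosh_li"] = res.lifting_index
        scores["niosh_rwl_defined"] = res.rwl_defined
    if rula_inputs is not None:
        scores["rula"] = classic_scales.rula(rula_inputs)
    if reba_inputs is not None:
        scores["reba"] = classic_scales.reba(reba_inputs)
    report.classic_scores = scores

    report.audit = {
        "duty_cycle": dc,
        "mae": mae_value,
        "hip_femoral_head_area_mm2": hip_threshold.femoral_head_area,
        "hip_endurance_force_n": hip_threshold.endurance_force,
        "hip_endurance_stress_mpa": hip_threshold.endurance_stress,
        "ucs_model": asdict(ucs_model),
        "spine_risk_threshold": risk_threshold,
        "fatigue_table_shape": list(fatigue_table.probability.shape),
        "schedule": asdict(schedule),
        "subject": {"age": subject.age, "sex": subject.sex.value, "bmi": subject.bmi},
    }
    return report


def _load_niosh(path) -> classic_scales.NioshInputs:
    raw = yaml.safe_load(Path(path).read_text())
    return classic_scales.NioshInputs(**raw)


def _load_posture(path):
    raw = yaml.safe_load(Path(path).read_text()) or {}
    rula_in = classic_scales.RulaInputs(**raw["rula"]) if "rula" in raw else None
    reba_in = classic_scales.RebaInputs(**raw["reba"]) if "reba" in raw else None
    return rula_in, reba_in


def assess(
    config_file,
    activation_file=None,
    force_file=None,
    fatigue_table_file=None,
    ucs_model_file=None,
    niosh_file=None,
    posture_file=None,
    risk_threshold: float = spine_risk.DEFAULT_RISK_THRESHOLD,
) -> RiskReport:
    """File-level entry point: read inputs, then run :func:`assess_traces`."""
    schedule, subject, catalog = read_task_config(config_file)
    chmap = read_channel_map(config_file)
    activations = (
        read_motion_storage(activation_file, kind=TraceKind.ACTIVATION)
        if activation_file
        else None
    )
    forces = read_motion_storage(force_file, kind=TraceKind.FORCE) if force_file else None
    table = spine_risk.FatigueTable.from_yaml(fatigue_table_file) if fatigue_table_file else None
    model = spine_risk.UcsModel.from_yaml(ucs_model_file) if ucs_model_file else None
    rula_in, reba_in = _load_posture(posture_file) if posture_file else (None, None)
    return assess_traces(
        schedule,
        subject,
        catalog,
        activations=activations,
        forces=forces,
        hip_channels=chmap.get("hips"),
        l5_channel=chmap.get("l5"),
        ucs_model=model,
        fatigue_table=table,
        risk_threshold=risk_threshold,
        niosh_inputs=_load_niosh(niosh_file) if niosh_file else None,
        rula_inputs=rula_in,
        reba_inputs=reba_in,
    )


def _assessed_regions(report: RiskReport) -> set[str]:
    regions = set()
    if report.muscle_details:
        regions.add("muscle")
    if report.hip_peak_stress is not None:
        regions.add("hip")
    if report.spine_failure_probability is not None:
        regions.add("spine")
    return regions


def compare(report_a: RiskReport, report_b: RiskReport) -> dict:
    """Per-region deltas (B minus A) between two reports.

    Both reports must have assessed the same regions; classification changes
    are listed explicitly.  Swapping the arguments negates every delta.
    """
    ra, rb = _assessed_regions(report_a), _assessed_regions(report_b)
    if ra != rb:
        raise ValidationError(
            f"reports assessed different regions: {sorted(ra)} vs {sorted(rb)}"
        )
    delta: dict = {
        "duty_cycle": (
            report_b.duty_cycle - report_a.duty_cycle
            if report_a.duty_cycle is not None and report_b.duty_cycle is not None
            else None
        ),
        "mae": (
            report_b.mae - report_a.mae
            if report_a.mae is not None and report_b.mae is not None
            else None
        ),
    }
    if "muscle" in ra:
        at_a, at_b = set(report_a.muscle_groups_at_risk), set(report_b.muscle_groups_at_risk)
        delta["muscle"] = {
            "n_groups_at_risk": len(at_b) - len(at_a),
            "newly_at_risk": sorted(at_b - at_a),
            "no_longer_at_risk": sorted(at_a - at_b),
        }
    if "hip" in ra:
        delta["hip"] = {
            "peak_stress_mpa": report_b.hip_peak_stress - report_a.hip_peak_stress,
            "classification_changed": report_a.hip_at_risk != report_b.hip_at_risk,
        }
    if "spine" in ra:
        delta["spine"] = {
            "failure_probability": report_b.spine_failure_probability
            - report_a.spine_failure_probability,
            "peak_force_n": (
                report_b.spine_details.get("peak_force_n", 0.0)
                - report_a.spine_details.get("peak_force_n", 0.0)
            ),
            "classification_changed": report_a.spine_high_risk != report_b.spine_high_risk,
        }
    common = set(report_a.classic_scores) & set(report_b.classic_scores)
    numeric = {
        k: report_b.classic_scores[k] - report_a.classic_scores[k]
        for k in sorted(common)
        if isinstance(report_a.classic_scores[k], (int, float))
        and not isinstance(report_a.classic_scores[k], bool)
    }
    if numeric:
        delta["classic_scores"] = numeric
    return delta


def _fmt(x, spec=".4g"):
    return "NA" if x is None else format(x, spec)


def render_text(report: RiskReport) -> str:
    """Human-readable summary of a report."""
    lines = ["=== Ergonomic risk report ==="]
    lines.append(f"duty cycle          : {_fmt(report.duty_cycle)}")
    lines.append(f"maximal accept. eff.: {_fmt(report.mae)}")
    if report.muscle_details:
        lines.append(f"muscle groups at risk: {len(report.muscle_groups_at_risk)}")
        for v in report.muscle_details:
            flag = "AT RISK" if v["at_risk"] else "ok"
            lines.append(
                f"  {v['group']:<28s} {v['n_exceeding']}/{len(v['peak_activations'])} "
                f"above MAE  [{flag}]"
            )
    else:
        lines.append("muscle groups       : not assessed")
    if report.hip_peak_stress is not None:
        for d in report.hip_details:
            flag = "AT RISK" if d["at_risk"] else "ok"
            lines.append(
                f"hip {d['channel']:<16s}: {d['peak_stress_mpa']:.3f} MPa  [{flag}]"
            )
    else:
        lines.append("hip                 : not assessed")
    if report.spine_failure_probability is not None:
        sd = report.spine_details
        flag = "HIGH RISK" if report.spine_high_risk else "low risk"
        lines.append(
            f"spine (L5)          : p_fail={report.spine_failure_probability:.4f} "
            f"({sd.get('relative_load_pct', 0):.1f}% UCS, {sd.get('n_cycles', 0)} cycles) "
            f"[{flag}, cutoff {report.spine_risk_threshold:g}]"
        )
    else:
        lines.append("spine (L5)          : not assessed")
    if report.classic_scores:
        for k, v in report.classic_scores.items():
            lines.append(f"{k:<20s}: {v}")
    return "\n".join(lines)


def write_report(report: RiskReport, out_dir) -> tuple[Path, Path]:
    """Write the machine-readable (JSON) and text forms of a report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "report.json"
    tpath = out / "report.txt"
    jpath.write_text(json.dumps(report.to_dict(), indent=2, default=str) + "\n")
    tpath.write_text(render_text(report) + "\n")
    return jpath, tpath
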