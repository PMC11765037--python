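"""Full study orchestration: records -> beats -> quantifiers -> reports.

``analyze_record`` runs one record through preprocessing (notch filter,
baseline removal, Kors transform, vector modulus), beat processing
(R detection or supplied fiducials, 512 ms windows, median-template
acceptance, RMS gate) and per-beat ordinal quantifiers split by phase.
``run_study`` maps a cohort through it, builds per-phase trajectories,
delta metrics, control-region box and cross-patient section statistics,
and writes the report bundle (CSV tables, JSON summary, QC logs and a
manifest) under an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beats import (
    BeatSet,
    accept_beats,
    build_template,
    detect_r_waves,
    estimate_q_onsets,
    extract_windows,
    rms_noise_gate,
)
from .config import RunConfig
from .ordinal import OrdinalPDF
from .preprocess import (
    MultiLeadECG,
    kors_transform,
    notch_filter,
    remove_baseline,
    vector_modulus,
)
from .trajectory import (
    PhaseSeries,
    Trajectory,
    compare_sections,
    control_region,
    control_sections,
    delta_metrics,
    mean_control_pdf,
    per_beat_quantifiers,
    window_average,
)

__all__ = ["DataError", "RecordAnalysis", "PatientAnalysis", "StudyReport",
           "analyze_record", "analyze_patient", "run_study", "summarize"]

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Invalid or insufficient input data."""


@dataclass(frozen=True)
class RecordAnalysis:
    """Per-record outcome: QC'd beats and per-phase quantifier series."""

    beat_set: BeatSet
    phases: dict  # phase name -> PhaseSeries
    excluded: bool
    exclusion_reason: str | None


@dataclass(frozen=True)
class PatientAnalysis:
    patient_id: str
    artery: str
    mean_control: OrdinalPDF | None
    phases: dict  # phase -> PhaseSeries (JSD attached)
    trajectories: dict  # phase -> Trajectory
    deltas: dict  # phase -> DeltaMetrics
    control_section_means: np.ndarray | None
    excluded: bool
    exclusion_reason: str | None
    qc: dict  # record label -> beat QC DataFrame


@dataclass(frozen=True)
class StudyReport:
    config: RunConfig
    patients: list
    trajectories: pd.DataFrame
    deltas: pd.DataFrame
    sections: pd.DataFrame
    control_box: tuple | None
    summary: dict


def _phase_intervals(ecg: MultiLeadECG) -> "list[tuple[str, float, float]]":
    ann = ecg.annotations
    if ann is None:
        raise DataError("record has no phase annotations")
    out = []
    if ann.control is not None:
        out.append(("control", float(ann.control[0]), float(ann.control[1])))
    if ann.inflation is not None and ann.deflation is not None:
        out.append(("occlusion", float(ann.inflation), float(ann.deflation)))
        end = ann.end if ann.end is not None else ecg.duration
        out.append(("recovery", float(ann.deflation), float(end)))
    if not out:
        raise DataError("annotations delimit no analysable phase")
    return out


def analyze_record(
    ecg: MultiLeadECG,
    config: RunConfig,
    r_samples: np.ndarray | None = None,
    q_samples: np.ndarray | None = None,
) -> RecordAnalysis:
    """Run one annotated 8-lead record through the full per-record pipeline.

    Supplied ``r_samples``/``q_samples`` fiducials bypass the built-in
    detector.  The returned analysis is marked excluded when the record
    fails the pre-Q RMS noise gate or yields no accepted beats.
    """
    intervals = _phase_intervals(ecg)
    clean = notch_filter(ecg, config.line_freq)
    lead_ii = clean.lead("II")

    if r_samples is None:
        r_samples = detect_r_waves(lead_ii, clean.fs)
    r_samples = np.asarray(r_samples, dtype=int)
    if r_samples.size == 0:
        return RecordAnalysis(
            beat_set=BeatSet(r_samples, np.empty((0, 0)), clean.fs),
            phases={},
            excluded=True,
            exclusion_reason="no beats detected",
        )
    if q_samples is None:
        q_samples = estimate_q_onsets(lead_ii, r_samples, clean.fs)
    q_samples = np.asarray(q_samples, dtype=int)

    # baseline knots: midpoint of the pre-Q segment of each beat
    knots = np.unique(q_samples - int(round(config.pre_q_ms / 2000.0 * clean.fs)))
    knots = knots[(knots >= 0) & (knots < clean.n_samples)]
    if knots.size >= 4:
        clean = remove_baseline(clean, knots)
    else:
        log.warning("too few beats for baseline removal; skipping")

    modulus = vector_modulus(kors_transform(clean))
    beat_set = extract_windows(modulus, r_samples, config.window_ms)
    kept = np.isin(r_samples, beat_set.r_samples)
    q_kept = q_samples[kept]

    if beat_set.n_beats < 3:
        return RecordAnalysis(
            beat_set=beat_set,
            phases={},
            excluded=True,
            exclusion_reason="fewer than 3 beats after windowing",
        )
    template = build_template(beat_set.windows)
    beat_set = accept_beats(
        beat_set, template, threshold=config.xcorr_threshold, modulus=modulus
    )
    beat_set = dataclasses.replace(beat_set, q_onsets=q_kept)
    # the noise gate reads the detection lead (II): the vector magnitude
    # compresses additive per-lead noise and would under-report it
    pre = beat_set.window_len // 2
    post = beat_set.window_len - pre
    ii = clean.lead("II")
    ii_set = BeatSet(
        r_samples=beat_set.r_samples,
        windows=np.stack([ii[r - pre : r + post] for r in beat_set.r_samples]),
        fs=clean.fs,
        q_onsets=q_kept,
    )
    ii_set = rms_noise_gate(
        ii_set, pre_q_ms=config.pre_q_ms, limit_uv=config.rms_limit_uv
    )
    beat_set = dataclasses.replace(
        beat_set,
        rms_pre_q=ii_set.rms_pre_q,
        record_passes_rms=ii_set.record_passes_rms,
    )
    if not beat_set.record_passes_rms:
        return RecordAnalysis(
            beat_set=beat_set,
            phases={},
            excluded=True,
            exclusion_reason=(
                f"median pre-Q RMS exceeds {config.rms_limit_uv} uV gate"
            ),
        )

    phases: dict = {}
    acc = beat_set.accepted
    t_beats = beat_set.r_samples / beat_set.fs
    for phase, t0, t1 in intervals:
        sel = acc & (t_beats >= t0) & (t_beats < t1)
        if not np.any(sel):
            continue
        phases[phase] = per_beat_quantifiers(
            beat_set.windows[sel],
            t_beats[sel] - t0,
            phase,
            D=config.D,
            tau=config.tau,
        )
    if not phases:
        return RecordAnalysis(
            beat_set=beat_set,
            phases={},
            excluded=True,
            exclusion_reason="no accepted beats in any annotated phase",
        )
    return RecordAnalysis(
        beat_set=beat_set, phases=phases, excluded=False, exclusion_reason=None
    )


def analyze_patient(
    patient_id: str,
    artery: str,
    control_record: MultiLeadECG,
    ptca_record: MultiLeadECG,
    config: RunConfig,
    fiducials: dict | None = None,
) -> PatientAnalysis:
    """Analyse one patient's control + PTCA record pair.

    ``fiducials`` may map record label ("control"/"ptca") to
    ``(r_samples, q_samples)`` tuples from the annotation sidecar.
    """
    fiducials = fiducials or {}
    analyses = {}
    qc = {}
    for label, record in (("control", control_record), ("ptca", ptca_record)):
        r, q = fiducials.get(label, (None, None))
        analyses[label] = analyze_record(record, config, r_samples=r, q_samples=q)
        qc[label] = analyses[label].beat_set.to_frame()

    excluded = [lbl for lbl, a in analyses.items() if a.excluded]
    if excluded:
        reason = "; ".join(
            f"{lbl}: {analyses[lbl].exclusion_reason}" for lbl in excluded
        )
        return PatientAnalysis(
            patient_id, artery, None, {}, {}, {}, None, True, reason, qc
        )

    control_series = analyses["control"].phases.get("control")
    if control_series is None or control_series.n_beats == 0:
        return PatientAnalysis(
            patient_id, artery, None, {}, {}, {}, None, True,
            "control record yields no control beats", qc,
        )
    reference = mean_control_pdf(control_series)

    phases = {"control": control_series.with_reference(reference)}
    for phase in ("occlusion", "recovery"):
        series = analyses["ptca"].phases.get(phase)
        if series is not None:
            phases[phase] = series.with_reference(reference)

    widths = {
        "control": config.occlusion_window_s,
        "occlusion": config.occlusion_window_s,
        "recovery": config.recovery_window_s,
    }
    trajectories = {
        phase: window_average(series, widths[phase])
        for phase, series in phases.items()
    }
    deltas = {}
    for phase in ("occlusion", "recovery"):
        if phase in trajectories and int(trajectories[phase].nonempty.sum()) >= 2:
            deltas[phase] = delta_metrics(trajectories[phase])

    n_sections = (
        int(trajectories["occlusion"].nonempty.sum())
        if "occlusion" in trajectories
        else 0
    )
    section_means = (
        control_sections(phases["control"], n_sections) if n_sections else None
    )
    return PatientAnalysis(
        patient_id=patient_id,
        artery=artery,
        mean_control=reference,
        phases=phases,
        trajectories=trajectories,
        deltas=deltas,
        control_section_means=section_means,
        excluded=False,
        exclusion_reason=None,
        qc=qc,
    )


def _trajectory_table(patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        if p.excluded:
            continue
        for phase, traj in p.trajectories.items():
            df = traj.to_frame()
            df.insert(0, "patient", p.patient_id)
            df.insert(1, "artery", p.artery)
            rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["patient", "artery", "phase", "window_center_s",
                     "H", "C", "JSD", "n_beats"]
        )
    return pd.concat(rows, ignore_index=True)


def _delta_table(patients) -> pd.DataFrame:
    rows = [
        {
            "patient": p.patient_id,
            "artery": p.artery,
            "phase": phase,
            "delta_H": d.delta_H,
            "delta_C": d.delta_C,
        }
        for p in patients
        if not p.excluded
        for phase, d in p.deltas.items()
    ]
    return pd.DataFrame(rows, columns=["patient", "artery", "phase", "delta_H", "delta_C"])


def _section_table(patients, config: RunConfig) -> pd.DataFrame:
    """Cross-patient occlusion-vs-control section comparisons."""
    rows = []
    n_max = 0
    for p in patients:
        if not p.excluded and "occlusion" in p.trajectories:
            n_max = max(n_max, int(p.trajectories["occlusion"].nonempty.sum()))
    for i in range(n_max):
        occl, ctrl = [], []
        for p in patients:
            if p.excluded or p.control_section_means is None:
                continue
            traj = p.trajectories.get("occlusion")
            if traj is None or i >= traj.jsd_mean.size:
                continue
            if np.isfinite(traj.jsd_mean[i]) and i < p.control_section_means.size:
                occl.append(traj.jsd_mean[i])
                ctrl.append(p.control_section_means[i])
        if len(occl) < 3:
            continue
        cmp_res = compare_sections(occl, ctrl, section_index=i, alpha=config.alpha)
        rows.append(
            {
                "section": i,
                "n_patients": len(occl),
                "mean_occlusion_jsd": float(np.mean(occl)),
                "mean_control_jsd": float(np.nanmean(ctrl)),
                "test_used": cmp_res.test_used,
                "p_value": cmp_res.p_value,
                "significant": cmp_res.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["section", "n_patients", "mean_occlusion_jsd",
                 "mean_control_jsd", "test_used", "p_value", "significant"],
    )


def run_study(config: RunConfig, records, out_dir=None) -> StudyReport:
    """Analyse a cohort and (optionally) write the report bundle.

    ``records`` is a list of objects with ``patient_id``, ``artery``,
    ``control`` and ``ptca`` attributes (e.g. synthetic ``PatientRecord``).
    When ``out_dir`` is given, the bundle is written there: manifest.json,
    trajectories.csv, deltas.csv, sections.csv, summary.json and per-record
    QC tables under qc/.
    """
    records = list(records)
    if not records:
        raise DataError("empty record list")
    patients = [
        analyze_patient(
            r.patient_id, r.artery, r.control, r.ptca, config,
            fiducials=getattr(r, "fiducials", None),
        )
        for r in records
    ]
    for p in patients:
        if p.excluded:
            log.warning("patient %s excluded: %s", p.patient_id, p.exclusion_reason)

    kept = [p for p in patients if not p.excluded]
    traj_df = _trajectory_table(patients)
    delta_df = _delta_table(patients)
    section_df = _section_table(patients, config)
    box = None
    ctrl_trajs = [p.trajectories["control"] for p in kept if "control" in p.trajectories]
    if ctrl_trajs:
        box = control_region(ctrl_trajs)

    summary = {
        "n_patients": len(patients),
        "n_excluded": len(patients) - len(kept),
        "exclusions": {
            p.patient_id: p.exclusion_reason for p in patients if p.excluded
        },
        "control_region": None
        if box is None
        else {"H": list(box[0]), "C": list(box[1])},
        "mean_deltas": {},
        "n_significant_sections": int(section_df["significant"].sum())
        if len(section_df)
        else 0,
    }
    for artery in ("LAD", "RCA"):
        for phase in ("occlusion", "recovery"):
            sel = delta_df[(delta_df.artery == artery) & (delta_df.phase == phase)]
            if len(sel):
                summary["mean_deltas"][f"{artery}_{phase}"] = {
                    "delta_H": float(sel.delta_H.mean()),
                    "delta_C": float(sel.delta_C.mean()),
                    "n": int(len(sel)),
                }

    report = StudyReport(
        config=config,
        patients=patients,
        trajectories=traj_df,
        deltas=delta_df,
        sections=section_df,
        control_box=box,
        summary=summary,
    )
    if out_dir is not None:
        _write_bundle(report, Path(out_dir))
    return report


def _write_bundle(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "qc").mkdir(exist_ok=True)
    manifest = {
        "config": report.config.to_dict(),
        "config_hash": report.config.config_hash,
        "seed": report.config.seed,
        "ecghc_version": __version__,
        "patients": [p.patient_id for p in report.patients],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    report.trajectories.to_csv(out_dir / "trajectories.csv", index=False)
    report.deltas.to_csv(out_dir / "deltas.csv", index=False)
    report.sections.to_csv(out_dir / "sections.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(report.summary, indent=1) + "\n")
    for p in report.patients:
        for label, df in p.qc.items():
            df.to_csv(out_dir / "qc" / f"{p.patient_id}_{label}.csv", index=False)


def summarize(report_or_dir) -> str:
    """Render a human-readable summary of a report bundle.

    Accepts a :class:`StudyReport` or a bundle directory; values are read
    back from the written tables so the summary always reflects the files.
    """
    if isinstance(report_or_dir, StudyReport):
        summary = report_or_dir.summary
        deltas = report_or_dir.deltas
        sections = report_or_dir.sections
    else:
        out = Path(report_or_dir)
        summary = json.loads((out / "summary.json").read_text())
        deltas = pd.read_csv(out / "deltas.csv")
        sections = pd.read_csv(out / "sections.csv")

    lines = [
        "ecghc study summary",
        "===================",
        f"patients analysed: {summary['n_patients']} "
        f"(excluded: {summary['n_excluded']})",
    ]
    if summary.get("control_region"):
        h = summary["control_region"]["H"]
        c = summary["control_region"]["C"]
        lines.append(
            f"control region: H [{h[0]:.3f}, {h[1]:.3f}] x C [{c[0]:.3f}, {c[1]:.3f}]"
        )
    if len(deltas):
        lines.append("")
        lines.append("relative endpoint changes (cohort means):")
        g = deltas.groupby(["artery", "phase"])[["delta_H", "delta_C"]].mean()
        for (artery, phase), row in g.iterrows():
            lines.append(
                f"  {artery:3s} {phase:9s}  dH = {row.delta_H:+.1%}  "
                f"dC = {row.delta_C:+.1%}"
            )
    if len(sections):
        n_sig = int(sections["significant"].sum())
        lines.append("")
        lines.append(
            f"occlusion vs control sections: {n_sig}/{len(sections)} significant"
        )
    return "\n".join(lines) + "\n"
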