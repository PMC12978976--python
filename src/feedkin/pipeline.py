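"""End-to-end orchestration: simulate -> segment -> metrics -> compare.

``run_pipeline`` is deterministic given the config (seeds included) and
writes, under the configured output directory:

* ``segments.json`` — per-trial cycle bounds and phase windows;
* ``metrics.csv`` — tidy per-trial metric table (joint-angle summaries,
  movement times, transport parameters);
* ``comparison.csv`` — Wilcoxon comparison table per (metric, phase, sex);
* ``run_log.txt`` — every threshold in effect;
* ``report.md`` — human-readable summary (via :func:`report`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .channels import PHASES
from .config import PipelineConfig
from .errors import ConfigError, FeedkinError, ParticipantExclusionError
from .hand_metrics import transport_metrics
from .io import read_events, read_motion_csv
from .joint_metrics import summarize_cycle
from .recording import MotionRecording
from .segmentation import (CycleSegmentation, apply_annotations, detect_cycles,
                           segment_phases, select_success_cycle)
from .simulate import CohortSpec, SimConfig, synth_cohort
from .stats import ConditionComparison

log = logging.getLogger(__name__)

TRANSPORT_METRIC_NAMES = (
    "actual_distance_m", "relative_distance", "mean_velocity_mps",
    "max_velocity_mps", "timing_max_velocity_pct", "n_movement_units",
)


@dataclass
class ResultsBundle:
    """Everything a pipeline run produced, re-loadable from disk."""

    out_dir: Path
    metrics: pd.DataFrame
    comparison: pd.DataFrame
    segments: dict = field(default_factory=dict)


class StageError(FeedkinError):
    def __init__(self, stage: str, trial: str, cause: Exception):
        self.stage, self.trial = stage, trial
        super().__init__(f"stage {stage!r} failed for trial {trial!r}: {cause}")


def _trial_metrics(rec: MotionRecording, seg: CycleSegmentation,
                   cfg: PipelineConfig) -> pd.DataFrame:
    """Tidy metric rows (long format) for one selected cycle."""
    rows = []
    angle_tab = summarize_cycle(rec, seg)
    for _, r in angle_tab.iterrows():
        for stem, val in (("max", r.max_deg), ("min", r.min_deg),
                          ("range", r.range_deg)):
            rows.append({"participant_id": rec.participant_id, "sex": rec.sex,
                         "condition": rec.condition, "phase": r.phase,
                         "metric": f"{r.channel}_{stem}_deg", "value": val})
    for phase in PHASES:
        lo, hi = seg.phases[phase]
        rows.append({"participant_id": rec.participant_id, "sex": rec.sex,
                     "condition": rec.condition, "phase": phase,
                     "metric": "movement_time_s",
                     "value": (hi - lo) / seg.sample_rate})
    tm = transport_metrics(rec, seg, cfg.movement_units, cfg.filter_cutoff_hz)
    for name in TRANSPORT_METRIC_NAMES:
        rows.append({"participant_id": rec.participant_id, "sex": rec.sex,
                     "condition": rec.condition, "phase": "Tr",
                     "metric": name, "value": float(getattr(tm, name))})
    return pd.DataFrame(rows)


def _collect_trials(cfg: PipelineConfig) -> list[tuple[MotionRecording, object]]:
    """Load motion files from disk, or simulate the configured cohort."""
    if cfg.motion_dir is not None:
        motion_dir = Path(cfg.motion_dir)
        if not motion_dir.is_dir():
            raise ConfigError(f"motion directory not found: {motion_dir}")
        trials = []
        for path in sorted(motion_dir.glob("*.csv")):
            if path.name == "truth.csv":
                continue
            rec = read_motion_csv(path)
            ev_path = path.with_name(path.stem + "_events.json")
            events = read_events(ev_path) if ev_path.exists() else None
            trials.append((rec, events))
        if not trials:
            raise ConfigError(f"no motion CSVs in {motion_dir}")
        return trials
    sim = dict(cfg.simulate)
    spec_keys = {f.name for f in CohortSpec.__dataclass_fields__.values()} \
        if hasattr(CohortSpec, "__dataclass_fields__") else set()
    spec = CohortSpec(**{k: v for k, v in sim.items() if k in spec_keys})
    sim_cfg_kwargs = {k: v for k, v in sim.items() if k not in spec_keys}
    sim_cfg = SimConfig(seed=cfg.seed, thresholds=cfg.thresholds, **sim_cfg_kwargs)
    dataset, _ = synth_cohort(spec, sim_cfg)
    return [(rec, None) for rec, _truth in dataset]


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Run the full analysis; deterministic for a fixed config."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    trials = _collect_trials(cfg)

    all_metrics = []
    segments_out: dict[str, dict] = {}
    for rec, events in trials:
        trial_id = f"{rec.participant_id}_{rec.condition}"
        try:
            cycles = detect_cycles(rec, cfg.thresholds)
            if events is not None and events.cycles:
                segs = [segment_phases(rec, c, cfg.thresholds, ann)
                        for c, ann in zip(cycles, events.cycles)]
                segs = apply_annotations(segs, events)
            else:
                segs = [segment_phases(rec, c, cfg.thresholds) for c in cycles]
            seg = select_success_cycle(segs)
        except ParticipantExclusionError:
            log.warning("trial %s: no successful cycle; excluded", trial_id)
            continue
        except FeedkinError as exc:
            raise StageError("segment", trial_id, exc) from exc
        segments_out[trial_id] = {
            "cycle_bounds": list(seg.cycle_bounds),
            "phases": {p: list(w) for p, w in seg.phases.items()},
            "pause_detected_in_reach": seg.pause_detected_in_reach,
        }
        try:
            all_metrics.append(_trial_metrics(rec, seg, cfg))
        except FeedkinError as exc:
            raise StageError("metrics", trial_id, exc) from exc

    metrics = pd.concat(all_metrics, ignore_index=True)
    comparison = ConditionComparison(
        metrics, alpha=cfg.alpha, quantile_rule=cfg.quantile_rule).fit().table

    metrics.to_csv(out / "metrics.csv", index=False)
    comparison.to_csv(out / "comparison.csv", index=False)
    with open(out / "segments.json", "w") as fh:
        json.dump(segments_out, fh, indent=1, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("feedkin run configuration\n")
        for key, value in sorted(asdict(cfg.thresholds).items()):
            fh.write(f"segmentation.{key} = {value}\n")
        for key, value in sorted(asdict(cfg.movement_units).items()):
            fh.write(f"hand_metrics.{key} = {value}\n")
        fh.write(f"filter_cutoff_hz = {cfg.filter_cutoff_hz}\n")
        fh.write(f"alpha = {cfg.alpha}\nquantile_rule = {cfg.quantile_rule}\n")
        fh.write(f"seed = {cfg.seed}\n")

    bundle = ResultsBundle(out_dir=out, metrics=metrics, comparison=comparison,
                           segments=segments_out)
    with open(out / "report.md", "w") as fh:
        fh.write(report(bundle))
    return bundle


def load_bundle(out_dir: str | Path) -> ResultsBundle:
    out = Path(out_dir)
    if not (out / "comparison.csv").exists():
        raise ConfigError(f"no pipeline results in {out}")
    segments = {}
    seg_path = out / "segments.json"
    if seg_path.exists():
        with open(seg_path) as fh:
            segments = json.load(fh)
    return ResultsBundle(
        out_dir=out,
        metrics=pd.read_csv(out / "metrics.csv"),
        comparison=pd.read_csv(out / "comparison.csv"),
        segments=segments,
    )


def report(bundle: ResultsBundle) -> str:
    """Markdown summary: per-stratum tables of median (IQR), z, p, r."""
    comp = bundle.comparison
    if comp.empty:
        raise FeedkinError("empty results bundle")
    lines = ["# Paired utensil-condition comparison", ""]
    for stratum, grp in comp.groupby("stratum", sort=True):
        lines.append(f"## Stratum: {stratum}")
        lines.append("")
        lines.append("| metric | phase | chopsticks median (IQR) | "
                     "spoon median (IQR) | z | p | r | category | sig |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for _, r in grp.sort_values(["metric", "phase"]).iterrows():
            a = f"{r.median_a:.2f} ({r.q1_a:.2f} to {r.q3_a:.2f})"
            b = f"{r.median_b:.2f} ({r.q1_b:.2f} to {r.q3_b:.2f})"
            sig = "*" if r.significant else ""
            lines.append(f"| {r.metric} | {r.phase} | {a} | {b} | "
                         f"{r.z:.3f} | {r.p:.3f} | {r.r:.3f} | {r.category} | {sig} |")
        lines.append("")
    return "\n".join(lines)
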