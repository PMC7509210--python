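"""Cohort pipeline driver and aggregation.

Walks a directory of trial CSV/JSON pairs, runs preprocessing, the
direction-resolved correlation/amplitude/contribution analysis, delay
estimation, and the smoothness metrics for every subject, then aggregates
per-subject scalars into cohort statistics (mean, SD, median, quartiles).
A subject that fails any stage is recorded in a partial-failure manifest
and the run continues.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CohortSummary,
    Direction,
    MuscleDirectionResult,
    Trial,
    read_trial,
    write_results,
)
from .correlation import (
    CorrelationParams,
    amplitude_statistic,
    contribution_ratios,
    direction_correlation,
    direction_dependence_test,
    holm_adjust,
)
from .errors import SteerlimbError, UsageError
from .lags import estimate_delay
from .preprocess import (
    PreprocessParams,
    SegmentationParams,
    decimate_series,
    envelope,
    normalize,
    segment_directions,
)
from .smoothness import ApEnParams, SsdParams, smoothness_report

log = logging.getLogger("steerlimb")


@dataclass
class AggregateStats:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n: int


def aggregate(values) -> AggregateStats:
    """Cohort statistics of per-subject scalars: mean, sample SD (n-1),
    median and quartiles by linear interpolation, and n."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise UsageError("aggregate called with no values")
    if not np.all(np.isfinite(values)):
        raise UsageError("aggregate requires finite values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return AggregateStats(
        mean=float(values.mean()), sd=sd, median=float(med), q1=float(q1), q3=float(q3),
        n=int(values.size),
    )


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    correlation: CorrelationParams = field(default_factory=CorrelationParams)
    apen: ApEnParams = field(default_factory=ApEnParams)
    ssd: SsdParams = field(default_factory=SsdParams)
    analysis_fs: float = 100.0  # envelopes/torque are decimated to this rate
    apen_fs: float = 100.0
    max_lag_ms: float = 1000.0
    norm_ref: float | None = None  # used when preprocess.norm_method == reference_value
    per_event: bool = False  # pinned: correlations on concatenated segments
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


@dataclass
class SubjectAnalysis:
    trial: Trial
    results: list[MuscleDirectionResult]
    delays: pd.DataFrame
    smoothness: pd.DataFrame
    direction_r: dict[tuple[str, str], float]  # (muscle, direction) -> r


def discover_trials(input_dir: Path) -> list[Path]:
    """Trial CSVs in a cohort directory (those with a .meta.json sidecar)."""
    paths = []
    for p in sorted(Path(input_dir).glob("*.csv")):
        if p.name == "ground_truth.csv":
            continue
        if p.with_name(p.stem + ".meta.json").exists():
            paths.append(p)
    return paths


def analyze_trial(trial: Trial, config: RunConfig) -> SubjectAnalysis:
    """Run every analysis stage for one trial."""
    pp = config.preprocess
    envs = np.stack([envelope(ch, trial.fs, pp) for ch in trial.emg])
    norm_envs = np.stack(
        [
            normalize(e, pp.norm_method, config.norm_ref)
            for e in envs
        ]
    )
    env_d, fs_d = decimate_series(norm_envs, trial.fs, config.analysis_fs)
    torque_d, _ = decimate_series(trial.torque, trial.fs, config.analysis_fs)
    segs = segment_directions(torque_d, fs_d, config.segmentation)

    delays = []
    for i, muscle in enumerate(trial.channel_labels):
        res = estimate_delay(
            env_d[i], torque_d, fs_d, segs=segs, max_lag_ms=config.max_lag_ms, muscle=muscle
        )
        delays.append(
            {
                "muscle": muscle,
                "tau_ms": res.tau_ms,
                "rho_at_tau": res.rho_at_tau,
                "boundary_flag": res.boundary,
            }
        )
    delays_df = pd.DataFrame(delays)
    tau_by_muscle = dict(zip(delays_df["muscle"], delays_df["tau_ms"]))

    results: list[MuscleDirectionResult] = []
    direction_r: dict[tuple[str, str], float] = {}
    for direction in segs.directions_present:
        rs = np.array(
            [
                direction_correlation(env_d[i], torque_d, segs, direction, config.correlation)
                for i in range(len(trial.channel_labels))
            ]
        )
        amps = np.array(
            [
                amplitude_statistic(env_d[i], segs, direction)
                for i in range(len(trial.channel_labels))
            ]
        )
        cs = contribution_ratios(rs, amps)
        for muscle, r, a, c in zip(trial.channel_labels, rs, amps, cs):
            results.append(
                MuscleDirectionResult(
                    muscle=muscle, direction=direction, r=float(r), a=float(a),
                    c=float(c), tau_ms=float(tau_by_muscle[muscle]),
                ).validate()
            )
            direction_r[(muscle, direction)] = float(r)

    sm = smoothness_report(trial, config.apen, config.ssd, apen_fs=config.apen_fs)
    smooth_df = pd.DataFrame(
        [{"apen": sm.apen, "ssd": sm.ssd, "degenerate": sm.degenerate}]
    )
    return SubjectAnalysis(
        trial=trial, results=results, delays=delays_df, smoothness=smooth_df,
        direction_r=direction_r,
    )


def _condition_key(trial: Trial) -> tuple[str, str, str]:
    return (trial.arm_mode.value, trial.task.value, trial.hand_position)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-subject + cohort analysis over a cohort directory.

    Writes per-subject result files, cohort summary tables, the
    direction-dependence tests, and a manifest of any per-subject failures.
    Deterministic for a fixed seed and input directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)

    paths = discover_trials(config.input_dir)
    if not paths:
        raise UsageError(f"no trial CSV/meta pairs found in {config.input_dir}")

    analyses: list[SubjectAnalysis] = []
    failures = []
    for path in paths:
        try:
            trial = read_trial(path)
            log.info("analyzing subject %s (%s)", trial.subject_id, path.name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                analysis = analyze_trial(trial, config)
        except (SteerlimbError, ValueError, OSError) as exc:
            log.warning("subject file %s failed: %s", path.name, exc)
            failures.append({"file": path.name, "error": f"{type(exc).__name__}: {exc}"})
            continue
        sid = trial.subject_id
        write_results(analysis.results, out / "subjects" / f"{sid}_results.csv")
        analysis.delays.to_csv(
            out / "subjects" / f"{sid}_delays.csv", index=False, lineterminator="\n"
        )
        analysis.smoothness.to_csv(
            out / "subjects" / f"{sid}_smoothness.csv", index=False, lineterminator="\n"
        )
        analyses.append(analysis)

    summaries = _summarize(analyses)
    if summaries:
        write_results(summaries, out / "cohort_summary.csv")
    tests_df = _direction_tests(analyses, config.seed)
    tests_df.to_csv(out / "direction_tests.csv", index=False, lineterminator="\n")

    manifest = {
        "n_subjects_ok": len(analyses),
        "n_subjects_failed": len(failures),
        "failures": failures,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _summarize(analyses: list[SubjectAnalysis]) -> list[CohortSummary]:
    buckets: dict[tuple, list[float]] = {}

    def add(cond, direction, statistic, value):
        buckets.setdefault((*cond, direction, statistic), []).append(value)

    for an in analyses:
        cond = _condition_key(an.trial)
        for res in an.results:
            add(cond, res.direction, f"r_{res.muscle}", res.r)
            add(cond, res.direction, f"a_{res.muscle}", res.a)
            add(cond, res.direction, f"c_{res.muscle}", res.c)
        for row in an.delays.itertuples(index=False):
            add(cond, "all", f"tau_ms_{row.muscle}", row.tau_ms)
        sm = an.smoothness.iloc[0]
        add(cond, "all", "apen", float(sm["apen"]))
        add(cond, "all", "ssd", float(sm["ssd"]))

    summaries = []
    for key in sorted(buckets):
        arm_mode, task, hand_position, direction, statistic = key
        stats = aggregate(buckets[key])
        summaries.append(
            CohortSummary(
                arm_mode=arm_mode, task=task, hand_position=hand_position,
                direction=direction, statistic=statistic, mean=stats.mean, sd=stats.sd,
                median=stats.median, q1=stats.q1, q3=stats.q3, n_subjects=stats.n,
            ).validate()
        )
    return summaries


def _direction_tests(analyses: list[SubjectAnalysis], seed: int) -> pd.DataFrame:
    """Paired cw-vs-ccw permutation test per (condition, muscle), raw + Holm."""
    groups: dict[tuple, dict[str, tuple[list, list]]] = {}
    for an in analyses:
        cond = _condition_key(an.trial)
        per_cond = groups.setdefault(cond, {})
        for muscle in an.trial.channel_labels:
            cw = an.direction_r.get((muscle, Direction.CW.value))
            ccw = an.direction_r.get((muscle, Direction.CCW.value))
            if cw is None or ccw is None:
                continue
            pair = per_cond.setdefault(muscle, ([], []))
            pair[0].append(cw)
            pair[1].append(ccw)

    rows = []
    for cond in sorted(groups):
        muscles = sorted(groups[cond])
        pvals = []
        kept = []
        for muscle in muscles:
            cw_vals, ccw_vals = groups[cond][muscle]
            if len(cw_vals) < 2:
                continue
            p = direction_dependence_test(
                np.array(cw_vals), np.array(ccw_vals), seed=seed
            )
            pvals.append(p)
            kept.append((muscle, len(cw_vals), float(np.mean(cw_vals)), float(np.mean(ccw_vals))))
        if not kept:
            continue
        adjusted = holm_adjust(np.array(pvals))
        for (muscle, n, mean_cw, mean_ccw), p, p_adj in zip(kept, pvals, adjusted):
            rows.append(
                {
                    "arm_mode": cond[0], "task": cond[1], "hand_position": cond[2],
                    "muscle": muscle, "n_subjects": n, "mean_r_cw": mean_cw,
                    "mean_r_ccw": mean_ccw, "p_raw": p, "p_holm": float(p_adj),
                }
            )
    columns = [
        "arm_mode", "task", "hand_position", "muscle", "n_subjects",
        "mean_r_cw", "mean_r_ccw", "p_raw", "p_holm",
    ]
    return pd.DataFrame(rows, columns=columns)
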