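"""File formats, run configuration and the two pipeline orchestrators.

Tabular I/O is plain CSV with documented headers:

* joint angles (wide): ``time`` (s) + 51 channels named ``<segment>_<dof>``;
* outcomes: ``subject, trial, direction_deg, abs_error_deg, success``;
* validation pairs: ``shot, real_deg, virtual_deg``;
* block stats: ``subject, block, n, mu, sigma, df, success_rate,
  corrected_sigma, mean_abs_error, is_partial``.

Manifests and fit reports are JSON. ``run_analysis`` executes
generate -> kinematics prep -> shot performance -> body metrics -> learning
fits, one subject at a time, and is byte-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bodymetrics import (
    dof_count,
    generalized_variance,
    manipulative_complexity,
    pc_spectrum,
    session_vpe,
    trial_covariance,
    vpe_block_variability,
)
from .errors import ConfigurationError, InsufficientDataError, SamplingError, SchemaError
from .kinematics import JointAngleRecording, prepare_trial
from .learning import fit_double_exponential, fit_exponential, learning_delta
from .performance import ShotOutcome, block_statistics, partition_blocks
from .synthetic import (
    CohortConfig,
    channel_names,
    evr_preset,
    generate_session,
    generate_validation_pairs,
    real_world_preset,
)

logger = logging.getLogger("cuelearn")

PRESETS = {"evr": evr_preset, "real_world": real_world_preset}


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    block_size: int = 25
    vpe_exclude_self: bool = True
    complexity_method: str = "participation_ratio"
    out_dir: str = "cuelearn_out"
    preset: str = "evr"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        preset = raw.get("preset", "evr")
        if preset not in PRESETS:
            raise ConfigurationError(f"unknown preset {preset!r}")
        cohort = PRESETS[preset](**cohort_raw)
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# readers / writers


def write_joint_angles(rec: JointAngleRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.angles, columns=rec.channel_names)
    df.insert(0, "time", rec.time)
    df.to_csv(path, index=False)


def read_joint_angles(path: str | Path) -> JointAngleRecording:
    """Read the wide joint-angle CSV; validates schema and time base."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing 'time' column")
    expected = channel_names()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel column(s): {', '.join(missing[:5])}")
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise SamplingError(f"{path}: non-monotone time at row {int(bad[0]) + 2}")
    rate = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    return JointAngleRecording(
        time=t, angles=df[expected].to_numpy(dtype=float), rate=rate, channel_names=expected
    )


def write_outcomes(
    outcomes_by_subject: dict[str, Sequence[ShotOutcome]], path: str | Path
) -> None:
    rows = [
        {
            "subject": sid,
            "trial": o.trial,
            "direction_deg": o.direction,
            "abs_error_deg": o.abs_error,
            "success": int(o.success),
        }
        for sid, outs in outcomes_by_subject.items()
        for o in outs
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_outcomes(path: str | Path) -> dict[str, list[ShotOutcome]]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject", "trial", "direction_deg", "abs_error_deg", "success"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    out: dict[str, list[ShotOutcome]] = {}
    for sid, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        out[str(sid)] = [
            ShotOutcome(
                trial=int(r.trial),
                direction=float(r.direction_deg),
                abs_error=float(r.abs_error_deg),
                success=bool(r.success),
            )
            for r in grp.itertuples()
        ]
    return out


def write_validation_pairs(pairs: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(pairs, columns=["real_deg", "virtual_deg"])
    df.insert(0, "shot", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_validation_pairs(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("real_deg", "virtual_deg"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df[["real_deg", "virtual_deg"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# pipelines


def _analyze_subject(session, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Block stats + per-trial body metrics for one subject."""
    sid = session.subject_id
    stats = block_statistics(session.outcomes, config.block_size)
    block_df = pd.DataFrame([dataclasses.asdict(s) for s in stats])
    block_df.insert(0, "subject", sid)

    trial_rows = []
    mean_vpe_by_trial = None
    if session.kinematics:
        windows, kept = [], []
        for i, rec in enumerate(session.kinematics):
            try:
                tk = prepare_trial(rec)
            except Exception as exc:  # boundary-flagged trials are skipped
                logger.warning("subject %s trial %d flagged: %s", sid, i, exc)
                continue
            windows.append(tk.window)
            kept.append(i)
        flags = [session.outcomes[i].success for i in kept]
        vpe = None
        if any(flags):
            vpe = session_vpe(windows, flags, exclude_self=config.vpe_exclude_self)
        for j, i in enumerate(kept):
            win = windows[j]
            spectrum = pc_spectrum(win)
            row = {
                "subject": sid,
                "trial": i,
                "gv": generalized_variance(trial_covariance(win)),
                "dof_count": dof_count(spectrum),
                "complexity": manipulative_complexity(spectrum, config.complexity_method),
            }
            if vpe is not None:
                row["mean_vpe"] = float(np.nanmean(vpe[j]))
            trial_rows.append(row)
    trial_df = pd.DataFrame(trial_rows)
    extras = {"n_trials_kept": len(trial_rows)}
    return block_df, trial_df, extras


def run_analysis(config: RunConfig, seed: int | None = None) -> dict[str, Any]:
    """Run the full synthetic-cohort analysis pipeline and write all outputs.

    Returns a report dict mirroring what is written to ``config.out_dir``.
    """
    if seed is not None:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort, seed=seed)
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    block_frames, trial_frames = [], []
    outcomes_by_subject: dict[str, list[ShotOutcome]] = {}
    for i in range(config.cohort.n_subjects):
        session = generate_session(i, config.cohort)
        outcomes_by_subject[session.subject_id] = session.outcomes
        b, t, _ = _analyze_subject(session, config)
        block_frames.append(b)
        trial_frames.append(t)
        logger.info("analyzed subject %s (%.1fs)", session.subject_id, _time.time() - t0)
    block_df = pd.concat(block_frames, ignore_index=True)
    trial_df = (
        pd.concat(trial_frames, ignore_index=True) if any(len(t) for t in trial_frames)
        else pd.DataFrame()
    )
    write_outcomes(outcomes_by_subject, out / "outcomes.csv")
    block_df.to_csv(out / "block_stats.csv", index=False)
    if len(trial_df):
        trial_df.to_csv(out / "trial_metrics.csv", index=False)

    # cross-subject block summary
    summary = (
        block_df.groupby("block")[["mu", "sigma", "corrected_sigma", "success_rate",
                                   "mean_abs_error"]]
        .agg(["mean", "std", "sem"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.to_csv(out / "block_summary.csv")

    # learning fits on cross-subject trial means
    fits: dict[str, Any] = {}
    err_by_trial = (
        pd.DataFrame(
            {
                sid: [o.abs_error for o in outs]
                for sid, outs in outcomes_by_subject.items()
            }
        )
        .mean(axis=1)
        .to_numpy()
    )
    fits["abs_error_exponential"] = dataclasses.asdict(fit_exponential(err_by_trial))
    if len(trial_df):
        gv_mean = trial_df.groupby("trial")["gv"].mean().to_numpy()
        if gv_mean.size >= 20:
            fits["gv_double_exponential"] = dataclasses.asdict(
                fit_double_exponential(gv_mean)
            )
        comp_mean = trial_df.groupby("trial")["complexity"].mean().to_numpy()
        if comp_mean.size >= 10:
            fits["complexity_exponential"] = dataclasses.asdict(fit_exponential(comp_mean))

    # first-vs-last block learning delta across subjects
    pivot = block_df[~block_df["is_partial"]].pivot(
        index="subject", columns="block", values="mean_abs_error"
    )
    delta = None
    if pivot.shape[0] >= 2 and pivot.shape[1] >= 2:
        delta = dataclasses.asdict(learning_delta(pivot.to_numpy()))
    report = {
        "n_subjects": config.cohort.n_subjects,
        "n_blocks": int(block_df["block"].max()) + 1,
        "fits": fits,
        "learning_delta": delta,
        "elapsed_s": _time.time() - t0,
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2, default=float)
    manifest = {
        "config": config.to_dict(),
        "seed": config.cohort.seed,
        "version": __version__,
        "elapsed_s": report["elapsed_s"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report


def validation_statistics(pairs: np.ndarray) -> dict[str, float | None]:
    """Pearson r and RMSE between paired real/virtual angle series."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[0] < 3:
        raise InsufficientDataError("need >= 3 pairs")
    real, virtual = pairs[:, 0], pairs[:, 1]
    rmse = float(np.sqrt(np.mean((real - virtual) ** 2)))
    if np.std(real) == 0 or np.std(virtual) == 0:
        return {"r": None, "rmse": rmse, "n": pairs.shape[0]}
    r = float(np.corrcoef(real, virtual)[0, 1])
    return {"r": r, "rmse": rmse, "n": pairs.shape[0]}


def run_validation_twin(
    n_shots: int = 100,
    angle_range: tuple[float, float] = (-50.0, 50.0),
    discrepancy_sd: float = 2.85,
    seed: int = 0,
    pairs: np.ndarray | None = None,
) -> dict[str, Any]:
    """Validation-twin report: generates (or consumes) paired real/virtual
    angles and reports Pearson r and RMSE."""
    if pairs is None:
        pairs = generate_validation_pairs(n_shots, angle_range, discrepancy_sd, seed)
    stats = validation_statistics(pairs)
    stats["discrepancy_sd"] = discrepancy_sd
    return stats
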