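"""Reproducible end-to-end runs: simulate, analyze, fit/compare, recover.

Each stage reads a :class:`RunConfig`, writes CSV outputs plus a JSON
manifest recording the seeds, the config hash and the package version, and
is deterministic for a fixed config. Per-session failures during analysis
or fitting are logged and recorded, not fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    QCConfig,
    direction_stats,
    hallucination_estimates,
    learning_dynamics,
    p_ratio,
    qc_filter,
)
from .fitting import (
    FitSettings,
    estimate_motor_noise,
    fit_model,
    fixed_effects_compare,
    protected_exceedance_probability,
)
from .models import params_from_record, params_to_record
from .simulate import DetectionConfig, SessionData, TimingConfig, simulate_session
from .task import TaskConfig, generate_schedule

logger = logging.getLogger("motionprior")

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_fit_compare"]


@dataclass(frozen=True)
class RunConfig:
    """One configuration object for the whole pipeline.

    Blocks: task design, observer(s) to simulate, analysis thresholds,
    fitting settings. ``observers`` is a list of flat parameter records
    (as produced by :func:`motionprior.models.params_to_record`).
    """

    seed: int = 0
    n_observers: int = 1
    task: dict = field(default_factory=dict)
    observers: list = field(default_factory=lambda: [{
        "variant": "BAYES_P", "theta_p": 32.0, "sigma_p": 15.0,
        "sigma_s": 12.0, "alpha_p": 0.1, "sigma_m": 8.0}])
    detection: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    n_bins: int = 11
    learning_window: int = 110
    learning_step: int = 55
    fit_variants: tuple = ("BAYES_P", "BAYES", "BAYES_varmin", "BAYES_var")
    fit: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "fit_variants" in d:
            d["fit_variants"] = tuple(d["fit_variants"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, command: str, config: RunConfig,
                    extra: dict | None = None) -> None:
    manifest = {"command": command, "seed": config.seed,
                "config_hash": config.config_hash(),
                "version": __version__, **(extra or {})}
    (outdir / f"manifest_{command}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


def _session_paths(outdir: Path) -> list[Path]:
    return sorted(Path(outdir).glob("session_*.csv"))


def run_simulate(config: RunConfig, outdir) -> list[Path]:
    """Generate schedules and simulate ``n_observers`` sessions.

    Observer ``i`` uses the parameter record ``observers[i % len]`` and
    seeds derived deterministically from ``config.seed``. Writes one
    schedule CSV, one session CSV per observer, and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task = TaskConfig(**config.task)
    written = []
    for i in range(config.n_observers):
        rec = config.observers[i % len(config.observers)]
        params, variant = params_from_record(rec)
        sched = generate_schedule(task, seed=config.seed + 1000 * i)
        sess = simulate_session(
            sched, params,
            DetectionConfig(**config.detection),
            seed=config.seed + 1000 * i + 1,
            variant=variant, timing=TimingConfig(**config.timing),
            observer_id=f"obs{i:03d}")
        if i == 0:
            sched.to_csv(outdir / "schedule_obs000.csv")
        path = outdir / f"session_obs{i:03d}.csv"
        sess.to_csv(path)
        written.append(path)
        logger.info("simulated %s (%d trials)", path.name, len(sess.df))
    _write_manifest(outdir, "simulate", config,
                    {"n_sessions": len(written)})
    return written


def run_analyze(config: RunConfig, session_dir, outdir) -> pd.DataFrame:
    """Behavioural summaries for every session CSV in ``session_dir``.

    Writes per-session direction-magnitude summaries, learning-dynamics
    windows, and a session-level table (QC values/flags, hallucination
    count, p_ratio). QC failure flags a session; it is still summarized.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc_cfg = QCConfig(**config.qc)
    session_rows, dir_frames, dyn_frames = [], [], []
    for path in _session_paths(Path(session_dir)):
        try:
            sess = SessionData.from_csv(path)
            qc = qc_filter(sess, qc_cfg)
            stats = direction_stats(sess)
            stats.insert(0, "observer_id", sess.observer_id)
            dir_frames.append(stats)
            dyn = learning_dynamics(sess, config.learning_window,
                                    config.learning_step)
            dyn.insert(0, "observer_id", sess.observer_id)
            dyn_frames.append(dyn)
            pr = p_ratio(hallucination_estimates(sess), config.n_bins)
            session_rows.append({
                "observer_id": sess.observer_id, "file": path.name,
                "qc_pass": qc.passed,
                "detection_high": qc.detection_high,
                "rmse_high_deg": qc.rmse_high_deg,
                "detection_low": qc.detection_low,
                "n_hallucinations": pr.n_hallucinations,
                "p_ratio": pr.p_ratio, "error": ""})
        except (ValueError, RuntimeError) as exc:
            logger.warning("analysis failed for %s: %s", path.name, exc)
            session_rows.append({"observer_id": "", "file": path.name,
                                 "qc_pass": False, "error": str(exc)})
    summary = pd.DataFrame(session_rows)
    summary.to_csv(outdir / "session_summary.csv", index=False)
    if dir_frames:
        pd.concat(dir_frames).to_csv(outdir / "direction_stats.csv", index=False)
    if dyn_frames:
        pd.concat(dyn_frames).to_csv(outdir / "learning_dynamics.csv", index=False)
    _write_manifest(outdir, "analyze", config,
                    {"n_sessions": len(session_rows)})
    return summary


def run_fit_compare(config: RunConfig, session_dir, outdir) -> dict:
    """Fit all configured variants per QC-passing session; compare models.

    Writes a per-session fit table, the fixed-effects (summed BIC) table
    and, when at least two sessions and two variants survive, the
    random-effects protected exceedance probabilities.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc_cfg = QCConfig(**config.qc)
    settings = FitSettings(**config.fit)
    fits, rows = {}, []
    for path in _session_paths(Path(session_dir)):
        sess = SessionData.from_csv(path)
        if not qc_filter(sess, qc_cfg).passed:
            logger.warning("skipping %s: failed QC", path.name)
            continue
        try:
            sigma_m = estimate_motor_noise(sess)
        except ValueError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        per_variant = {}
        for variant in config.fit_variants:
            try:
                fit = fit_model(sess, variant, sigma_m, settings)
            except RuntimeError as exc:
                logger.warning("fit failed (%s, %s): %s",
                               path.name, variant, exc)
                continue
            per_variant[variant] = fit
            rows.append({"observer_id": sess.observer_id,
                         **params_to_record(fit.params, variant),
                         "nll": fit.nll, "bic": fit.bic,
                         "n_trials": fit.n_trials,
                         "converged": fit.converged})
        if len(per_variant) == len(config.fit_variants):
            fits[sess.observer_id] = per_variant
    fit_table = pd.DataFrame(rows)
    fit_table.to_csv(outdir / "model_fits.csv", index=False)
    out = {"fits": fit_table}
    if fits:
        fe = fixed_effects_compare(fits)
        fe.to_csv(outdir / "fixed_effects.csv", index=False)
        out["fixed_effects"] = fe
        variants = fe["variant"].tolist()
        if len(fits) >= 2 and len(variants) >= 2:
            bic = np.array([[fits[s][v].bic for v in variants]
                            for s in sorted(fits)])
            px = protected_exceedance_probability(bic, seed=config.seed)
            rf = pd.DataFrame({"variant": variants, "pxp": px.pxp,
                               "exceedance": px.exceedance,
                               "frequency": px.model_frequencies,
                               "bor": px.bor})
            rf.to_csv(outdir / "random_effects.csv", index=False)
            out["random_effects"] = rf
    _write_manifest(outdir, "fit_compare", config,
                    {"n_fitted_sessions": len(fits)})
    return out
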