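"""End-to-end orchestration: simulate -> fit -> metrics -> stats.

A run is fully described by a :class:`RunConfig` (serialisable to YAML) and
a single seed, expanded into independent per-stage streams so any stage can
be re-run on its own.  Rerunning with an identical config reproduces every
artifact byte for byte.

Artifacts written to the output directory:

* ``trial_log.csv``   — the simulated cohort (one row per trial)
* ``fits.csv``        — fitted diffusion parameters, one row per
  subject x session x tone x parameter
* ``metrics.csv``     — behavioural summaries per subject x session x tone
* ``deltas.csv``      — per-subject change-from-baseline scores (CBI, zr,
  midpoint v and a)
* ``stats.csv`` / ``report.txt`` — the inferential battery
* ``manifest.json``   — config, config hash, seed and package version
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from driftbias import __version__
from driftbias.bias_metrics import (behavioural_percentages,
                                    change_from_baseline_cbi, qc_filter)
from driftbias.ddm_fit import (FitSpec, fit_results_to_frame, fit_session,
                               parameter_change_from_baseline)
from driftbias.stats_pipeline import (one_sample_t_vs_zero, results_to_frame,
                                      rm_anova)
from driftbias.task_sim import (Session, TONES, generate_cohort,
                                read_trial_log, write_trial_log)

__all__ = ["RunConfig", "run_experiment", "validate_inputs", "StageError"]

log = logging.getLogger("driftbias")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Reproducible description of one simulated experiment."""

    seed: int = 0
    preset: str = "vehicle"
    delta: float = 0.0
    n_subjects: int = 13
    qc_threshold: float = 0.60
    fit_restarts: int = 3
    fit_min_trials: int = 20
    fit_objective: str = "ml"
    fit_xatol: float = 1e-3
    fit_fatol: float = 1e-4
    out_dir: str = "driftbias-run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def fit_spec(self) -> FitSpec:
        return FitSpec(n_restarts=self.fit_restarts,
                       min_trials=self.fit_min_trials,
                       objective=self.fit_objective,
                       xatol=self.fit_xatol, fatol=self.fit_fatol)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: RunConfig):
    root = np.random.SeedSequence(config.seed)
    sim_seed, _fit_seed = root.spawn(2)
    return generate_cohort(config.n_subjects, config.preset, sim_seed,
                           delta=config.delta)


@_stage("fit")
def _fit_all(sessions_by_subject, config: RunConfig):
    root = np.random.SeedSequence(config.seed)
    _sim_seed, fit_seed = root.spawn(2)
    spec = config.fit_spec()
    fits = {}
    for (sid, sessions), sub_seed in zip(sorted(sessions_by_subject.items()),
                                         fit_seed.spawn(len(sessions_by_subject))):
        fits[sid] = {}
        for session, s_seed in zip(sessions, sub_seed.spawn(len(sessions))):
            fits[sid][session.session_id] = fit_session(
                session, spec, rng=np.random.default_rng(s_seed))
    return fits


def metrics_frame(sessions) -> pd.DataFrame:
    """Tidy per-subject x session x tone behavioural metrics."""
    rows = []
    for s in sessions:
        summary = behavioural_percentages(s)
        for tone in TONES:
            if tone not in summary.pct_omission:
                continue
            rows.append({
                "subject_id": s.subject_id,
                "session_id": s.session_id,
                "condition_label": s.condition_label,
                "tone": tone,
                "cbi": summary.cbi,
                "pct_positive": summary.pct_positive.get(tone, np.nan),
                "pct_omission": summary.pct_omission[tone],
                "pct_premature": summary.pct_premature[tone],
                "median_latency": summary.median_latency[tone],
                "mean_latency": summary.mean_latency[tone],
                "n_responded": summary.n_responded.get(tone, 0),
            })
    return pd.DataFrame(rows)


def cohort_deltas(pairs, fits) -> pd.DataFrame:
    """Per-subject change-from-baseline scores for CBI and the analysed
    diffusion parameters (session-level zr; midpoint-tone v and a)."""
    rows = []
    for spec, veh, drug in pairs:
        sid = spec.subject_id
        f_veh = fits[sid][veh.session_id]
        f_drug = fits[sid][drug.session_id]
        row = {"subject_id": sid}
        try:
            row["d_cbi"] = change_from_baseline_cbi(
                behavioural_percentages(drug).cbi, behavioural_percentages(veh).cbi)
        except ValueError:
            row["d_cbi"] = np.nan
        row["d_zr"] = parameter_change_from_baseline(f_drug, f_veh, "zr")
        row["d_v_mid"] = parameter_change_from_baseline(f_drug, f_veh, "v")
        row["d_a_mid"] = parameter_change_from_baseline(f_drug, f_veh, "a")
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("stats")
def _stats(metrics: pd.DataFrame, deltas: pd.DataFrame):
    results = []
    for col, label in [("d_cbi", "change in CBI vs 0"),
                       ("d_zr", "change in zr vs 0"),
                       ("d_v_mid", "change in midpoint v vs 0"),
                       ("d_a_mid", "change in midpoint a vs 0")]:
        vals = deltas[col].dropna().to_numpy()
        if vals.size >= 2:
            results.append(one_sample_t_vs_zero(vals, effect=label))
    # session x tone repeated-measures ANOVA on percent positive responding
    table = metrics.dropna(subset=["pct_positive"])
    complete = (table.groupby("subject_id")["pct_positive"].count()
                == table["condition_label"].nunique() * len(TONES))
    keep = complete[complete].index
    table = table[table["subject_id"].isin(keep)]
    if keep.size >= 3 and table["condition_label"].nunique() >= 2:
        results.extend(rm_anova(table, "pct_positive",
                                ["condition_label", "tone"], "subject_id"))
    return results


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline; returns a manifest of the written artifacts."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pairs = _simulate(config)
    sessions = [s for _, veh, drug in pairs for s in (veh, drug)]
    write_trial_log(sessions, out / "trial_log.csv")
    log.info("simulated %d subjects -> %s", len(pairs), out / "trial_log.csv")

    excluded = {}
    for spec, veh, drug in pairs:
        ok, reasons = qc_filter([veh, drug], config.qc_threshold)
        if not ok:
            excluded[spec.subject_id] = reasons
    kept = [p for p in pairs if p[0].subject_id not in excluded]
    if not kept:
        raise StageError("stage 'qc' failed: every subject excluded")

    sessions_by_subject = {p[0].subject_id: [p[1], p[2]] for p in kept}
    fits = _fit_all(sessions_by_subject, config)
    flat = [fits[sid][s.session_id] for sid, ss in sorted(sessions_by_subject.items())
            for s in ss]
    fit_results_to_frame(flat).to_csv(out / "fits.csv", index=False)

    metrics = metrics_frame([s for p in kept for s in (p[1], p[2])])
    metrics.to_csv(out / "metrics.csv", index=False)

    deltas = cohort_deltas(kept, fits)
    deltas.to_csv(out / "deltas.csv", index=False)

    results = _stats(metrics, deltas)
    stats_df = results_to_frame(results)
    stats_df.to_csv(out / "stats.csv", index=False)
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(f"driftbias {__version__} run {config.config_hash()}\n")
        fh.write(f"preset={config.preset} delta={config.delta} "
                 f"n={config.n_subjects} seed={config.seed}\n")
        if excluded:
            for sid, reasons in sorted(excluded.items()):
                fh.write(f"excluded {sid}: {'; '.join(reasons)}\n")
        fh.write("\n")
        for r in results:
            df_txt = ",".join(f"{d:g}" for d in r.df)
            fh.write(f"{r.effect}: stat={r.statistic:.4f} df=({df_txt}) "
                     f"p={r.p:.4f} correction={r.correction}\n")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects_analysed": len(kept),
        "excluded": excluded,
        "artifacts": ["trial_log.csv", "fits.csv", "metrics.csv",
                      "deltas.csv", "stats.csv", "report.txt"],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_inputs(path, qc_threshold: float = 0.60) -> dict:
    """Validate a trial-log CSV and run the QC accuracy filter.

    Returns a report dict with the per-subject include/exclude decisions;
    structural violations raise :class:`~driftbias.task_sim.TrialLogError`
    with line numbers.
    """
    sessions = read_trial_log(path)
    by_subject: dict[str, list[Session]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    excluded = {}
    for sid, ss in sorted(by_subject.items()):
        ok, reasons = qc_filter(ss, qc_threshold)
        if not ok:
            excluded[sid] = reasons
    return {
        "path": str(path),
        "n_sessions": len(sessions),
        "n_subjects": len(by_subject),
        "excluded": excluded,
        "violations": [],
    }
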