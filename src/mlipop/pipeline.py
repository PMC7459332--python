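"""End-to-end pipeline: simulate -> score -> dF/F -> decode -> GLM
(-> circuit), writing CSV tables and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, decode, dff as dff_mod, glm, synth
from .config import PipelineConfig
from .io import save_session
from .session import SMINUS, SPLUS

log = logging.getLogger(__name__)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, check: bool = False) -> dict:
    """Execute the configured stages; returns a report dict.

    With ``check`` the report gains a ``checks`` section of basic sanity
    assertions (scored round-trip, decoder above chance when proficient)
    and ``ok`` reflects their conjunction.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "ok": True}

    cfg.session.seed = cfg.seed
    session = synth.generate_session(cfg.session, cfg.ensemble, cfg.learning)
    save_session(session, out / "session.h5")
    report["stages"]["simulate"] = {"n_trials": len(session.trials),
                                    "n_rois": session.n_rois}

    pc = behavior.percent_correct(session.outcomes(), cfg.pc_window)
    epochs = behavior.classify_epoch(pc, cfg.naive_threshold,
                                     cfg.proficient_threshold)
    table = session.trials_dataframe()
    table["percent_correct"] = pc
    table["epoch"] = epochs
    table.to_csv(out / "behavior.csv", index=False)
    report["stages"]["score"] = {
        "final_percent_correct": float(pc[np.isfinite(pc)][-1])
        if np.any(np.isfinite(pc)) else None}

    dff = dff_mod.compute_dff(session.F,
                              [tr.t_start for tr in session.trials],
                              session.imaging_rate)
    session.dff = dff
    tensor = dff_mod.align_trials(dff, session.trials, "odor_on",
                                  (-10.0, 6.0), session.imaging_rate)
    report["stages"]["dff"] = {
        "responsive_fraction": dff_mod.responsive_fraction(tensor)}

    if cfg.run_decode:
        prof = np.isin(tensor.trial_indices,
                       [tr.index for i, tr in enumerate(session.trials)
                        if epochs[i] == behavior.PROFICIENT])
        labels = tensor.labels(session)
        sub = tensor.values[prof]
        if prof.sum() >= 8 and len(set(labels[prof])) == 2:
            X = dff_mod.period_means(
                dff_mod.TrialTensor(sub, tensor.t_rel, "odor_on",
                                    tensor.trial_indices[prof],
                                    tensor.imaging_rate),
                cfg.windows.odorant)
            acc = decode.loo_lda_accuracy(X, labels[prof])
            dim = decode.dimensionality(X)
            pd.DataFrame({"metric": ["odorant_loo_lda_accuracy",
                                     "dimensionality"],
                          "value": [acc, dim]}).to_csv(
                out / "decoding.csv", index=False)
            report["stages"]["decode"] = {"odorant_accuracy": float(acc),
                                          "dimensionality": float(dim)}
        else:
            report["stages"]["decode"] = {"skipped": "too few proficient trials"}

    if cfg.run_glm:
        design = glm.build_design(session, dff, pc_window=cfg.pc_window,
                                  proficient_threshold=cfg.proficient_threshold,
                                  naive_threshold=cfg.naive_threshold)
        fit = glm.fit_encoding_glm(design)
        ve = glm.variance_explained(fit, cfg.windows)
        contrib = glm.group_contributions(design, cfg.windows)
        contrib.to_csv(out / "glm_contributions.csv")
        report["stages"]["glm"] = {"variance_explained_pct": ve}

    if cfg.run_circuit:
        from . import circuit
        table_c, (F, p, _) = circuit.condition_comparison(n_reps=10,
                                                          seed=cfg.seed)
        table_c.to_csv(out / "circuit_lick_strength.csv", index=False)
        report["stages"]["circuit"] = {"glm_F": float(F), "glm_p": float(p)}

    if check:
        checks = {
            "outcomes_scored": all(tr.outcome is not None
                                   for tr in session.trials),
            "dff_finite": bool(np.all(np.isfinite(dff))),
        }
        dec = report["stages"].get("decode", {})
        if "odorant_accuracy" in dec:
            checks["decoding_above_chance"] = dec["odorant_accuracy"] > 0.6
        report["checks"] = checks
        report["ok"] = all(checks.values())

    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "version": __version__, "config": asdict(cfg)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report["manifest"] = str(out / "manifest.json")
    return report
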