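"""End-to-end orchestration on synthetic data.

Runs the full analysis order — simulate, time-resolved decoding per
depiction, cross-decoding, temporal generalization, ROI decoding,
MEG-fMRI fusion, group statistics — for a multi-subject synthetic cohort,
writing CSV outputs with a JSON provenance sidecar. Deterministic given
(config, seed): all randomness flows from the master seed through
independent per-stage substreams.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, fusion, stats, synth
from .containers import default_times
from .io import (PipelineConfig, derive_seeds, write_metadata,
                 write_tgm_csv)
from .rdm import compute_rdm


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are retained."""


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the synthetic end-to-end analysis; returns output file paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = default_times(cfg.tmin_ms, cfg.tmax_ms, cfg.srate)
    seeds = derive_seeds(cfg.seed, 2 + 3 * cfg.n_subjects)
    gt = _stage("ground-truth", synth.make_ground_truth,
                cfg.n_categories, cfg.n_features, cfg.shared_fraction,
                seeds[0], noise_sd=cfg.noise_sd)
    deps = ("photo", "drawing")
    outputs = {}

    acc = {d: [] for d in deps}
    cross_acc = []
    fus = {d: [] for d in deps}
    tgm_first = None
    roi_rows = []
    for s in range(cfg.n_subjects):
        ep_seed, st_seed, beta_seed = seeds[2 + 3 * s: 5 + 3 * s]
        epochs = _stage("simulate", synth.simulate_epochs, gt,
                        cfg.n_trials_per_cell, cfg.n_channels, times,
                        ep_seed, depictions=deps)
        sets = {}
        for d in deps:
            sets[d] = _stage("supertrials", decoding.make_supertrials,
                             epochs.select(d), cfg.group_size,
                             cfg.n_repetitions, st_seed)
            tc = _stage("decode-time", decoding.pairwise_decode_timecourse,
                        sets[d], cfg.svm_c)
            acc[d].append(tc.values)
        cross = _stage("crossdecode", decoding.cross_decode_timecourse,
                       sets[deps[0]], sets[deps[1]], cfg.svm_c)
        cross_acc.append(cross.values)
        if s == 0:
            tgm_first = _stage("tgm", decoding.temporal_generalization,
                               sets[deps[0]], cfg.svm_c)
        betas = {d: _stage("simulate-betas", synth.simulate_betas, gt,
                           cfg.n_runs, n_voxels=cfg.n_features,
                           noise_sd=cfg.noise_sd, seed=beta_seed + i,
                           depiction=d)
                 for i, d in enumerate(deps)}
        roi_rows.append({d: _stage("decode-roi", decoding.pairwise_decode_roi,
                                   betas[d], cfg.svm_c) for d in deps})
        meg_rdms = {d: _stage("meg-rdms", fusion.meg_rdm_series,
                              epochs.select(d)) for d in deps}
        for d in deps:
            froi = compute_rdm(betas[d].betas.mean(axis=0))
            ftc = _stage("fusion", fusion.fusion_timecourse, meg_rdms[d],
                         froi, times, roi_label="sim-roi")
            fus[d].append(ftc.values)

    for d in deps:
        df = pd.DataFrame(np.asarray(acc[d]), columns=times)
        df.to_csv(out / f"decode_time_{d}.csv", index_label="subject")
        outputs[f"decode_time_{d}"] = out / f"decode_time_{d}.csv"
        pd.DataFrame(np.asarray(fus[d]), columns=times).to_csv(
            out / f"fusion_{d}.csv", index_label="subject")
        outputs[f"fusion_{d}"] = out / f"fusion_{d}.csv"
    pd.DataFrame(np.asarray(cross_acc), columns=times).to_csv(
        out / "crossdecode.csv", index_label="subject")
    outputs["crossdecode"] = out / "crossdecode.csv"
    write_tgm_csv(out / "tgm_photo_sub-01.csv", tgm_first)
    outputs["tgm"] = out / "tgm_photo_sub-01.csv"
    pd.DataFrame(roi_rows).to_csv(out / "decode_roi.csv",
                                  index_label="subject")
    outputs["decode_roi"] = out / "decode_roi.csv"

    # group statistics on the within-depiction decoding time courses
    stat_seed = seeds[1]
    rows = []
    for d in deps:
        eff = np.asarray(acc[d]) - decoding.CHANCE_PERCENT
        perm = _stage("stats", stats.sign_permutation_test, eff,
                      cfg.n_perm, "one", stat_seed)
        clus = _stage("stats", stats.cluster_permutation, eff,
                      adjacency="time", forming_p=cfg.forming_p,
                      alpha=cfg.alpha, n_perm=cfg.n_perm, seed=stat_seed)
        peak = _stage("stats", stats.bootstrap_peak, np.asarray(acc[d]),
                      times, cfg.n_boot, seed=stat_seed)
        rows.append({"depiction": d,
                     "min_p": float(perm.p_values.min()),
                     "n_significant_clusters": int(clus.significant.sum()),
                     "peak_ms": peak.peak_latency,
                     "peak_ci_low_ms": peak.ci_low,
                     "peak_ci_high_ms": peak.ci_high})
    pd.DataFrame(rows).to_csv(out / "group_stats.csv", index=False)
    outputs["group_stats"] = out / "group_stats.csv"

    write_metadata(out / "meta.json", "run-all",
                   {k: v for k, v in vars(cfg).items()}, cfg.seed)
    outputs["meta"] = out / "meta.json"
    return outputs
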