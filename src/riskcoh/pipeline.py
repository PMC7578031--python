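"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate (optional) -> behavior -> spikes ->
decoding -> lfp -> connectivity on one session bundle, writing each stage's
tables under the output directory together with the serialized configuration
and a seed registry, so every reported number is traceable to a stage output
file. Completed stages (matching config hash) are skipped on re-runs unless
forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import connectivity as conn
from . import decoding as dec
from . import lfp as lfpmod
from . import spikes as spk
from .io import read_bundle, write_bundle
from .task_synth import SessionConfig, simulate_session

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "behavior", "spikes", "decoding", "lfp", "connectivity")


@dataclass
class RunConfig:
    out_dir: str = "riskcoh_out"
    bundle_path: str | None = None      # read an existing bundle instead of simulating
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    force: bool = False

    simulate: SessionConfig = field(default_factory=SessionConfig)
    lick_window: tuple[float, float] = (400.0, 800.0)
    alpha: float = 0.05
    decoding_repetitions: int = 50
    normalization_mode: str = "safe"
    tf_freqs: tuple[float, float, float] = (4.0, 48.0, 2.0)   # lo, hi, step
    tf_decim: int = 20
    sfc_max_units: int | None = 8
    sfc_max_electrodes: int | None = 4

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.bundle_path is None and "simulate" not in self.stages:
            raise ValueError("need either a bundle_path or the simulate stage")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / stage / "_done.json"
    if not marker.exists():
        return False
    return json.loads(marker.read_text()).get("config_hash") == cfg_hash


def _mark_done(out: Path, stage: str, cfg_hash: str, summary: dict) -> None:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    (d / "_done.json").write_text(json.dumps(
        {"config_hash": cfg_hash, "summary": summary}, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the run report (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (out / "config.json").write_text(json.dumps(config.to_dict(), default=str))
    report: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}

    # --- bundle
    if "simulate" in config.stages:
        bdir = out / "bundle"
        if config.force or not _stage_done(out, "simulate", cfg_hash):
            bundle = simulate_session(config.simulate, seed=config.seed)
            write_bundle(bundle, bdir)
            _mark_done(out, "simulate", cfg_hash, {"n_trials": len(bundle.trials)})
        bundle = read_bundle(bdir)
    elif config.bundle_path is not None:
        bundle = read_bundle(config.bundle_path)
    report["stages"]["simulate"] = {"n_trials": len(bundle.trials),
                                    "n_units": len(bundle.units),
                                    "areas": sorted(bundle.lfps)}

    trials = beh.filter_trials(bundle.trials)
    audit = trials.attrs["filter_audit"]
    assert audit["n_in"] == (audit["n_kept"] + audit["n_removed_incorrect"]
                             + audit["n_removed_rt"])
    report["exclusions"] = {"trials": audit}
    kept_idx = trials["trial_id"].to_numpy(int)

    def subset_units():
        return [spk.UnitRecord(u.unit_id, u.area,
                               [u.spike_times[i] for i in kept_idx], u.quality)
                for u in bundle.units]

    units = subset_units()
    trials = trials.reset_index(drop=True)

    # --- behavior
    if "behavior" in config.stages:
        d = out / "behavior"
        d.mkdir(exist_ok=True)
        glm = beh.fit_behavior_glm(trials, "lick", "binomial-logit")
        cmp_ = beh.compare_uncertainty_models(trials)
        summary = {"coefficients": glm.coefficients, "p_values": glm.p_values,
                   "model_comparison": {"delta_aic": cmp_["delta_aic"],
                                        "preferred": cmp_["preferred"]}}
        (d / "glm.json").write_text(json.dumps(summary, default=float))
        _mark_done(out, "behavior", cfg_hash, summary)
        report["stages"]["behavior"] = summary

    # --- spikes
    selectivity: dict[int, spk.SelectivityResult] = {}
    if "spikes" in config.stages:
        d = out / "spikes"
        d.mkdir(exist_ok=True)
        included, unit_audit = spk.select_units(units, trials)
        results = [spk.fit_unit_glm(u, trials, alpha=config.alpha) for u in included]
        selectivity = {r.unit_id: r for r in results}
        sel_df = pd.DataFrame([{
            "unit_id": r.unit_id, "area": r.area, "factor": r.factor,
            **{f"beta_{k}": v for k, v in r.coefficients.items()},
            **{f"p_{k}": v for k, v in r.p_values.items()},
        } for r in results])
        sel_df.to_csv(d / "selectivity.csv", index=False)
        pairs, pair_stats = spk.noise_correlations(included, trials, selectivity)
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            d / "pairs.csv", index=False)
        table1 = {"n_units": len(results)}
        for lab in ("ev", "variance", "both", "interaction-only", "none"):
            table1[lab] = int(sum(r.factor == lab for r in results))
        summary = {"unit_audit": unit_audit, "table1": table1,
                   "table2": {k: pair_stats[k] for k in ("group_means", "group_n")}}
        (d / "summary.json").write_text(json.dumps(summary, default=float))
        _mark_done(out, "spikes", cfg_hash, summary)
        report["stages"]["spikes"] = summary
        report["exclusions"]["units"] = unit_audit

    # --- decoding
    if "decoding" in config.stages:
        d = out / "decoding"
        d.mkdir(exist_ok=True)
        cfg = dec.DecodingConfig(repetitions=config.decoding_repetitions,
                                 seed=config.seed)
        rows = {}
        for factor, levels in (("ev", (3.0, 9.0)), ("variance", (0.0, 4.0))):
            res = dec.excess_accuracy(units, trials, factor, levels, cfg)
            rows[f"congruent_{factor}"] = {"mean": res.mean, "ci": res.ci}
        inc = dec.cross_decode(units, trials, "ev", (3.0, 9.0),
                               "variance", (0.0, 4.0), cfg)
        rows["incongruent_ev_to_variance"] = {"mean": inc.mean, "ci": inc.ci}
        (d / "decoding.json").write_text(json.dumps(rows, default=float))
        _mark_done(out, "decoding", cfg_hash, rows)
        report["stages"]["decoding"] = rows

    # --- lfp
    clean_masks: dict[str, np.ndarray] = {}
    if "lfp" in config.stages:
        if not bundle.lfps:
            raise RuntimeError("lfp stage requires LFP data in the bundle")
        d = out / "lfp"
        d.mkdir(exist_ok=True)
        lo, hi, step = config.tf_freqs
        freqs = np.arange(lo, hi, step)
        summary = {}
        for area, traces in bundle.lfps.items():
            traces = traces[:, kept_idx, :]
            n_el, n_tr, _ = traces.shape
            flat = traces.reshape(n_el * n_tr, -1)
            pre = lfpmod.preprocess_lfp(flat, bundle.sampling_rate)
            keep, audit = lfpmod.clean_session(pre, bundle.sampling_rate,
                                               seed=config.seed)
            clean_masks[area] = keep.reshape(n_el, n_tr)
            maps_by_el, metas = [], []
            for e in range(n_el):
                rows_keep = np.nonzero(clean_masks[area][e])[0]
                if rows_keep.size < 20:
                    continue
                tf = lfpmod.wavelet_power(pre.reshape(n_el, n_tr, -1)[e, rows_keep],
                                          bundle.sampling_rate, freqs,
                                          t0=bundle.t0, decim=config.tf_decim)
                norm = lfpmod.normalize_power(tf, mode=config.normalization_mode)
                maps_by_el.append(norm.values)
                metas.append(trials.iloc[rows_keep])
            pooled = np.concatenate(maps_by_el, axis=0)
            meta = pd.concat(metas, ignore_index=True)
            res = lfpmod.fit_pixel_glm(pooled, meta, freqs, norm.times)
            np.savez(d / f"coef_maps_{area}.npz",
                     **{f: res[f]["coef"].values for f in res},
                     freqs=freqs, times=norm.times)
            summary[area] = {"cleaning": audit,
                             "n_obs": int(pooled.shape[0])}
        (d / "summary.json").write_text(json.dumps(summary, default=float))
        _mark_done(out, "lfp", cfg_hash, summary)
        report["stages"]["lfp"] = summary
        report["exclusions"]["lfp_trials"] = {
            a: {"n_in": int(m.size), "n_kept": int(m.sum())}
            for a, m in clean_masks.items()}

    # --- connectivity
    if "connectivity" in config.stages:
        if not bundle.lfps:
            raise RuntimeError(
                "connectivity stage requires LFP data (lfp stage missing or bundle has no LFP)")
        d = out / "connectivity"
        d.mkdir(exist_ok=True)
        areas = sorted(bundle.lfps)
        sub = type(bundle)(trials=trials, units=units,
                           lfps={a: v[:, kept_idx, :] for a, v in bundle.lfps.items()},
                           sampling_rate=bundle.sampling_rate, t0=bundle.t0,
                           ground_truth=bundle.ground_truth)
        freqs = np.arange(4.0, 48.0, 2.0)
        sfc = {}
        for sa, fa in ((areas[0], areas[1]), (areas[1], areas[0])):
            df = conn.session_sfc(sub, sa, fa, freqs=freqs,
                                  max_units=config.sfc_max_units,
                                  max_electrodes=config.sfc_max_electrodes)
            df.to_csv(d / f"sfc_{sa}_to_{fa}.csv", index=False)
            sfc[f"{sa}->{fa}"] = df
        keys = list(sfc)
        contrast = conn.directional_contrast(sfc[keys[0]], sfc[keys[1]], seed=config.seed)
        stats_tables = {k: conn.condition_stats(v).to_dict("records")
                        for k, v in sfc.items() if len(v)}
        summary = {"directional_contrast": contrast,
                   "n_significant": {k: int(sum(r["significant"] for r in v))
                                     for k, v in stats_tables.items()}}
        (d / "summary.json").write_text(json.dumps(summary, default=float))
        _mark_done(out, "connectivity", cfg_hash, summary)
        report["stages"]["connectivity"] = summary

    (out / "report.json").write_text(json.dumps(report, default=str))
    return report
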