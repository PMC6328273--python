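"""End-to-end pipeline: simulate/load -> detect -> metrics -> classify -> stats.

Driven by a single YAML/dict config; every stage logs, all parameters and
seeds are echoed into a JSON manifest, and a stage failure aborts with an
error naming the stage (partial outputs are kept and marked failed in the
manifest).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (read_experiment_h5, write_annotation_csv, write_events_csv,
                 write_manifest)
from .metrics import ThresholdSpec, bin_means, cycle_metrics, detect_spikes, \
    segment_bursts
from .protocol import build_protocol
from .simulate import Experiment, generate_experiment, sample_population
from .states import annotate_window, rhythmicity, state_fractions

__all__ = ["StageError", "run_pipeline", "DEFAULT_CONFIG", "metric_table"]

log = logging.getLogger("cpgph.pipeline")

DEFAULT_CONFIG: dict = {
    "experiment": {
        "source": "simulate",       # or a path to an HDF5 bundle
        "ganglion": "STG",
        "direction": "acid_first",
        "extreme": 5.5,
        "n_preparations": 6,
        "population_cv": 0.15,
        "seed": 0,
    },
    "analysis": {
        "window_s": 480.0,          # last 8 min of each step
        "bin_s": 10.0,
        "max_isi_factor": 0.25,     # fraction of the expected period
        "expected_frequency": None,  # Hz; default 1.0 STG / 0.6 CG
        "detect_check": True,       # render+threshold a trace as a check
        "detect_window_s": 30.0,
        "detect_sample_rate": 5000.0,
    },
    "stats": {
        "alpha": 0.05,
        "unit": None,               # default PD (STG) / LC (CG)
        "metrics": ["frequency", "spikes_per_burst", "duty_cycle"],
    },
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _merged(config: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (config or {}).items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def _condition_label(i: int, step) -> str:
    return f"s{i:02d}_{step.role}_pH{step.ph:.1f}"


def metric_table(experiments: list[Experiment], unit: str,
                 window_s: float = 480.0, bin_s: float = 10.0,
                 max_isi: float = 0.25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-condition metric table from a list of preparations.

    Returns ``(table, binned)``: the per-preparation condition means of
    frequency, spikes per burst and duty cycle of ``unit`` (the mean of
    the 10-s bin means, the per-preparation unit for ANOVA), plus the full
    binned series in tidy form.
    """
    rows, brows = [], []
    for p, exp in enumerate(experiments):
        prep = f"prep{p:02d}"
        train = exp.spike_trains[unit]
        for i, (w0, w1) in enumerate(exp.protocol.analysis_windows(window_s)):
            label = _condition_label(i, exp.protocol.steps[i])
            bursts = segment_bursts(train.between(w0, w1), max_isi)
            cm = cycle_metrics(bursts) if len(bursts) >= 2 else None
            for metric in ("frequency", "spikes_per_burst", "duty_cycle"):
                if cm is None or len(cm) == 0:
                    value, series = np.nan, (np.empty(0), np.empty(0))
                else:
                    series = (cm.cycle_onset, getattr(cm, metric))
                    value = np.nan
                bs = bin_means(series[0], series[1], (w0, w1), bin_s)
                if np.any(bs.n_per_bin > 0):
                    value = float(np.nanmean(bs.bin_means))
                rows.append((prep, exp.protocol.direction, label,
                             exp.protocol.steps[i].ph, metric, value))
                for k in range(bs.n_bins):
                    brows.append((prep, label, metric, float(bs.bin_edges[k]),
                                  float(bs.bin_means[k]), int(bs.n_per_bin[k])))
    table = pd.DataFrame(rows, columns=["preparation", "direction", "condition",
                                        "ph", "metric", "value"])
    binned = pd.DataFrame(brows, columns=["preparation", "condition", "metric",
                                          "bin_left", "mean", "n"])
    return table, binned


def run_pipeline(config: dict | None = None, out_dir=".", seed: int | None = None
                 ) -> dict:
    """Execute the full analysis pipeline and write a results bundle.

    Returns the manifest (also written to ``manifest.json``). Reruns with
    an identical config and seed produce byte-identical metric CSVs.
    """
    from .stats import rm_anova_posthoc  # deferred: pingouin import is slow

    cfg = _merged(config)
    if seed is not None:
        cfg["experiment"]["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg, "stages": {},
                      "outputs": []}

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = "failed"
        manifest["error"] = str(exc)
        write_manifest(manifest, out / "manifest.json")
        raise StageError(stage, exc) from exc

    ecfg, acfg, scfg = cfg["experiment"], cfg["analysis"], cfg["stats"]

    # --- simulate / load -------------------------------------------------
    stage = "simulate"
    try:
        if ecfg["source"] == "simulate":
            ganglion = ecfg["ganglion"]
            protocol = build_protocol(ecfg["direction"], extreme=ecfg["extreme"])
            bases = sample_population(ganglion, ecfg["n_preparations"],
                                      ecfg["population_cv"], ecfg["seed"])
            experiments = [
                generate_experiment(ganglion, protocol, base, seed=ecfg["seed"] + p)
                for p, base in enumerate(bases)
            ]
        else:
            experiments = [read_experiment_h5(ecfg["source"])]
            ganglion = experiments[0].ganglion
        log.info("%s: %d preparation(s), %d steps", stage, len(experiments),
                 len(experiments[0].protocol.steps))
        manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    unit = scfg["unit"] or ("PD" if ganglion == "STG" else "LC")
    f_expected = acfg["expected_frequency"] or (1.0 if ganglion == "STG" else 0.6)
    max_isi = acfg["max_isi_factor"] / f_expected

    # --- detect (threshold-crossing check on a rendered trace) -----------
    stage = "detect"
    try:
        if acfg["detect_check"] and ecfg["source"] == "simulate":
            exp = experiments[0]
            w0, w1 = exp.protocol.analysis_windows(acfg["window_s"])[0]
            t1 = w0 + acfg["detect_window_s"]
            trace = exp.render_trace(unit, w0, t1, acfg["detect_sample_rate"])
            p = exp.ground_truth[0].params[unit]
            thr = p.v_min + p.slow_amplitude + 0.4 * p.spike_amplitude
            detected = detect_spikes(trace, ThresholdSpec(absolute_mv=thr))
            truth = exp.spike_trains[unit].between(w0, t1)
            manifest["detect_check"] = {
                "unit": unit, "window": [w0, t1],
                "n_detected": len(detected), "n_ground_truth": len(truth),
            }
            log.info("detect: %d/%d spikes recovered", len(detected), len(truth))
        for p, exp in enumerate(experiments):
            write_events_csv(exp.spike_trains, out / f"events_prep{p:02d}.csv")
            manifest["outputs"].append(f"events_prep{p:02d}.csv")
        manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- metrics + binning -----------------------------------------------
    stage = "metrics"
    try:
        table, binned = metric_table(experiments, unit, acfg["window_s"],
                                     acfg["bin_s"], max_isi)
        table.to_csv(out / "metrics.csv", index=False)
        binned.to_csv(out / "binned.csv", index=False)
        manifest["outputs"] += ["metrics.csv", "binned.csv"]
        manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- classify ---------------------------------------------------------
    stage = "classify"
    try:
        frac_rows = []
        for p, exp in enumerate(experiments):
            for i, (w0, w1) in enumerate(
                    exp.protocol.analysis_windows(acfg["window_s"])):
                ann = annotate_window(exp.spike_trains, (w0, w1), ganglion,
                                      max_intraburst_isi=max_isi)
                write_annotation_csv(ann, out / f"annotation_prep{p:02d}_s{i:02d}.csv")
                label = _condition_label(i, exp.protocol.steps[i])
                fr = state_fractions(ann, ganglion)
                for s, f in fr.items():
                    frac_rows.append((f"prep{p:02d}", label, s, f))
                frac_rows.append((f"prep{p:02d}", label, "rhythmicity",
                                  rhythmicity(ann, ganglion)))
        pd.DataFrame(frac_rows, columns=["preparation", "condition", "state",
                                         "fraction"]) \
            .to_csv(out / "state_fractions.csv", index=False)
        manifest["outputs"].append("state_fractions.csv")
        manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stats ------------------------------------------------------------
    stage = "stats"
    try:
        stats_summary = {}
        if len(experiments) >= 3:
            control = _condition_label(0, experiments[0].protocol.steps[0])
            for metric in scfg["metrics"]:
                sub = table[table["metric"] == metric]
                if sub["value"].isna().any():
                    # silent steps yield undefined cycle metrics; the RM design
                    # must stay complete, so restrict to fully observed conditions
                    ok = sub.groupby("condition")["value"].apply(
                        lambda v: v.notna().all())
                    sub = sub[sub["condition"].isin(ok[ok].index)]
                if sub["condition"].nunique() < 2 or control not in set(sub["condition"]):
                    continue
                res = rm_anova_posthoc(sub, control=control, alpha=scfg["alpha"])
                res.anova.to_csv(out / f"anova_{metric}.csv", index=False)
                manifest["outputs"].append(f"anova_{metric}.csv")
                if res.posthoc is not None:
                    res.posthoc.to_csv(out / f"posthoc_{metric}.csv", index=False)
                    manifest["outputs"].append(f"posthoc_{metric}.csv")
                stats_summary[metric] = {
                    "p_unc": res.effect_p, "significant": res.significant,
                    "family_size": res.family_size,
                }
        manifest["stats"] = stats_summary
        manifest["stages"][stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    stage = "write"
    manifest["stages"][stage] = "completed"
    write_manifest(manifest, out / "manifest.json")
    return manifest
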