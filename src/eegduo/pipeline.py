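"""Config-driven orchestration of the two end-to-end analyses.

``run_erp_pipeline`` simulates (or loads) one paired HQ/LC task session and
runs the full event-related chain: re-referencing, epoching, baseline
correction, threshold artifact rejection, component peak detection in
system-specific windows, inter-peak intervals, wavelet single-trial
correction (tcERP), and the permutation contrast of N2 amplitudes.

``run_resting_pipeline`` simulates (or loads) paired eyes-open/eyes-closed
resting segments and runs the spontaneous-activity chain: Welch spectra
per ROI, automatic alpha-peak detection, relative beta power, and DFA of
the alpha amplitude envelope over the occipital pair.

Each run writes tidy CSV tables, a JSON summary stamped with a hash of the
configuration, and a small figure bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import correction, erp, io, preprocessing, simulate, spectral, stats
from .dfa import (
    alpha_bandpass,
    amplitude_envelope,
    assess_power_law,
    default_window_grid,
    dfa as compute_dfa,
)
from .containers import FRONTAL_ROI, OCCIPITAL_PAIR, ROIS

logger = logging.getLogger(__name__)

#: Single-trial P1 search windows (ms) per task and system.
P1_ALIGN_WINDOWS = {
    "gonogo": {"HQ": (130.0, 200.0), "LC": (240.0, 310.0)},
    "semantic": {"HQ": (100.0, 230.0), "LC": (240.0, 310.0)},
}

REJECT_THRESHOLDS_UV = {"gonogo": 100.0, "semantic": 80.0}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_erp_config(task: str = "gonogo", seed: int = 0) -> dict:
    """Complete ERP-pipeline configuration with study defaults."""
    if task == "gonogo":
        sim = {
            "n_blocks": 9, "trials_per_block": 90, "p_go": 0.7,
            "trial_duration_s": 1.0, "component_latencies_ms": [109.0, 164.0, 256.0],
            "n2_nogo_gain": 1.6,
        }
    elif task == "semantic":
        sim = {
            "n_trials": 108, "n_blocks": 6, "trial_duration_s": 2.0,
            "component_latencies_ms": [132.0, 193.0],
        }
    else:
        raise ValueError(f"unknown ERP task {task!r}")
    return {
        "task": task,
        "seed": int(seed),
        "simulation": {
            **sim,
            "marker_delay_ms": {"HQ": 0.0, "LC": 95.0 if task == "gonogo" else 82.0},
            "noise_sd_uV": 15.0,
            "pink_sd_uV": 5.0,
            "alpha_amplitude_uV": 10.0,
            "alpha_hurst": 0.75,
            "jitter_sd_ms": 0.0,
        },
        "analysis": {
            "epoch_window_ms": [-200.0, 800.0],
            "baseline_ms": [-200.0, 0.0],
            "reject_threshold_uV": REJECT_THRESHOLDS_UV[task],
            "roi": list(FRONTAL_ROI),
            "peak_lowpass_hz": 20.0,
            "nzt_z_threshold": 3.0,
            "n_scales": 4,
            "n_perm": 1000,
        },
    }


def default_resting_config(seed: int = 0) -> dict:
    """Resting-state pipeline configuration (eyes-open and eyes-closed)."""
    return {
        "task": "resting",
        "seed": int(seed),
        "simulation": {
            "duration_s": 300.0,
            "alpha_hurst": 0.75,
            "alpha_amplitude_uV": {"eyes_open": 6.0, "eyes_closed": 12.0},
            "noise_sd_uV": 15.0,
            "pink_sd_uV": 5.0,
        },
        "analysis": {
            "spectrum_band_hz": [0.5, 30.0],
            "segment_length_s": 4.0,
            "alpha_band_hz": [8.0, 12.0],
            "beta_band_hz": [15.0, 30.0],
            "dfa_fit_range_s": [1.0, 280.0],
            "r2_threshold": 0.97,
        },
    }


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(dict(cfg), sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# Simulation helpers
# ---------------------------------------------------------------------------


def _systems_from_config(sim: Mapping[str, Any]) -> list[simulate.SystemModel]:
    out = []
    for name in ("HQ", "LC"):
        out.append(simulate.SystemModel(
            name=name,
            marker_delay_ms=float(sim["marker_delay_ms"][name]),
            noise_sd_uV=float(sim.get("noise_sd_uV", 15.0)),
            pink_sd_uV=float(sim.get("pink_sd_uV", 5.0)),
            jitter_sd_ms=float(sim.get("jitter_sd_ms", 0.0)),
        ))
    return out


def simulate_erp_session(cfg: Mapping[str, Any]) -> dict[str, "io.Recording"]:
    """Build the paired task session described by an ERP config."""
    task, seed, sim = cfg["task"], int(cfg["seed"]), cfg["simulation"]
    if task == "gonogo":
        schedule = simulate.generate_task_schedule(
            int(sim["n_blocks"]), int(sim["trials_per_block"]),
            float(sim["p_go"]), float(sim["trial_duration_s"]), seed)
        template = simulate.gonogo_template(
            tuple(sim["component_latencies_ms"]),
            n2_nogo_gain=float(sim.get("n2_nogo_gain", 1.6)))
    else:
        schedule = simulate.constant_schedule(
            int(sim["n_trials"]), float(sim["trial_duration_s"]),
            n_blocks=int(sim.get("n_blocks", 1)))
        template = simulate.semantic_template(tuple(sim["component_latencies_ms"]))
    oscillation = simulate.OscillationSpec(
        hurst=float(sim.get("alpha_hurst", 0.75)),
        mean_amplitude_uV=float(sim.get("alpha_amplitude_uV", 10.0)),
        duration_s=schedule.end_s + 10.0)
    return simulate.generate_session(schedule, template, oscillation,
                                     _systems_from_config(sim), seed)


# ---------------------------------------------------------------------------
# ERP pipeline
# ---------------------------------------------------------------------------


def preprocess_session(rec, *, window_ms=(-200.0, 800.0),
                       baseline_ms=(-200.0, 0.0), threshold_uV=100.0,
                       erp_reference=("P7", "P8")):
    """Average-reference, epoch, baseline, reject, then ERP re-reference."""
    r = preprocessing.rereference(rec, "average")
    ep = preprocessing.extract_epochs(r, tuple(window_ms))
    ep = preprocessing.baseline_correct(ep, tuple(baseline_ms))
    ep, report = preprocessing.reject_artifacts(ep, threshold_uV)
    logger.info("%s: %d/%d trials retained after ±%g uV rejection",
                rec.meta.get("system", "?"), report.n_retained,
                report.n_total, threshold_uV)
    ep = preprocessing.rereference_epochs(ep, tuple(erp_reference))
    return ep, report


def run_erp_pipeline(cfg: Mapping[str, Any], out_dir: str | Path | None = None,
                     *, recordings: Mapping[str, Any] | None = None) -> dict:
    """Full event-related comparison of the paired systems.

    Returns the summary dict; when ``out_dir`` is given, also writes
    ``peaks.csv``, ``intervals.csv``, ``waveforms.csv``, ``summary.json``
    and ``erp_overview.png`` there.
    """
    task = cfg["task"]
    ana = cfg["analysis"]
    roi = tuple(ana["roi"])
    seed = int(cfg["seed"])
    recs = dict(recordings) if recordings is not None else simulate_erp_session(cfg)

    windows = {
        sys_name: {comp: tuple(win) for comp, win in sys_windows.items()}
        for sys_name, sys_windows in
        ana.get("peak_windows", erp.PEAK_WINDOWS[task]).items()}
    p1_windows = {
        sys_name: tuple(win) for sys_name, win in
        ana.get("p1_windows", P1_ALIGN_WINDOWS[task]).items()}
    lowpass = ana.get("peak_lowpass_hz", 20.0)
    epochs, peaks, reports, aligned = {}, {}, {}, {}
    target = None
    for name in ("HQ", "LC"):
        ep, report = preprocess_session(
            recs[name], window_ms=ana["epoch_window_ms"],
            baseline_ms=ana["baseline_ms"],
            threshold_uV=ana["reject_threshold_uV"])
        epochs[name], reports[name] = ep, report
        # one evoked-coefficient mask per system; peaks are measured on the
        # denoised averages (denoising is linear, so this equals averaging
        # the denoised single trials)
        mask = correction.select_coefficients_nzt(
            ep, roi, n_scales=int(ana.get("n_scales", 4)),
            z_threshold=float(ana.get("nzt_z_threshold", 3.0)))
        den = correction.denoise_trials(ep, mask)
        peaks[name] = erp.measure_components(den, roi, windows[name],
                                             lowpass_hz=lowpass)
        # align single trials by P1; the LC session reuses the HQ target so
        # the time-corrected averages are directly comparable
        al = correction.align_trials_by_p1(
            den, roi, p1_windows[name], target_latency_ms=target)
        if target is None:
            target = al.target_latency_ms
        aligned[name] = al

    tc_peaks = {}
    tc_windows = {"N1": (40.0, 160.0), "P1": (100.0, 220.0)}
    for name, al in aligned.items():
        w = erp.average_erp(al.epochs.copy_with(valid=al.epochs.valid & al.aligned),
                            None, roi)
        if lowpass:
            w = erp.smooth_waveform(w, lowpass)
        tc_peaks[name] = {
            comp: erp.detect_peak(w, comp, erp.COMPONENT_POLARITY[comp], win)
            for comp, win in tc_windows.items()}

    summary: dict[str, Any] = {
        "task": task, "seed": seed, "config_hash": config_hash(cfg),
        "retained_trials": {k: v.retained_by_condition for k, v in reports.items()},
        "peaks": {
            sys_name: {c: {"latency_ms": p.latency_ms, "amplitude_uV": p.amplitude_uV,
                           "found": p.found}
                       for c, p in sys_peaks.items()}
            for sys_name, sys_peaks in peaks.items()},
        "interpeak_intervals_ms": {k: erp.interpeak_intervals(v)
                                   for k, v in peaks.items()},
        "alignment_target_ms": target,
    }
    shared = [c for c in ("N1", "P1", "N2")
              if c in peaks["HQ"] and c in peaks["LC"]
              and peaks["HQ"][c].found and peaks["LC"][c].found]
    shifts = {c: peaks["LC"][c].latency_ms - peaks["HQ"][c].latency_ms
              for c in shared}
    summary["latency_shift_ms"] = shifts
    summary["mean_latency_shift_ms"] = (float(np.mean(list(shifts.values())))
                                        if shifts else None)
    tc_shifts = {c: tc_peaks["LC"][c].latency_ms - tc_peaks["HQ"][c].latency_ms
                 for c in tc_windows if tc_peaks["HQ"][c].found
                 and tc_peaks["LC"][c].found}
    summary["corrected_latency_shift_ms"] = tc_shifts

    if task == "gonogo":
        summary["n2_permutation"] = {}
        for name, ep in epochs.items():
            res = stats.permutation_condition_test(
                ep, erp.PERMUTATION_N2_WINDOWS[name], roi,
                conditions=("NoGo", "Go"), n_perm=int(ana.get("n_perm", 1000)),
                seed=seed)
            summary["n2_permutation"][name] = {
                "observed_uV": res.observed, "p_value": res.p_value,
                "n_permutations": res.n_permutations, "seed": res.seed}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_erp_tables(out, cfg, epochs, peaks, roi, summary, aligned)
    return summary


def _write_erp_tables(out: Path, cfg, epochs, peaks, roi, summary,
                      aligned) -> None:
    rows = []
    for sys_name, sys_peaks in peaks.items():
        for comp, p in sys_peaks.items():
            rows.append({"system": sys_name, "task": cfg["task"],
                         "component": comp, "latency_ms": p.latency_ms,
                         "amplitude_uV": p.amplitude_uV, "found": p.found})
    pd.DataFrame(rows).to_csv(out / "peaks.csv", index=False)

    rows = []
    for sys_name, ivals in summary["interpeak_intervals_ms"].items():
        for name, v in ivals.items():
            rows.append({"system": sys_name, "interval": name, "ms": v})
    pd.DataFrame(rows).to_csv(out / "intervals.csv", index=False)

    wf_rows = []
    conditions = sorted(set(epochs["HQ"].conditions.astype(str)))
    waves = {}
    for sys_name, ep in epochs.items():
        for cond in conditions:
            w = erp.average_erp(ep, cond, roi)
            waves[(sys_name, cond)] = w
            for t, v in zip(w.times_ms, w.values):
                wf_rows.append({"system": sys_name, "condition": cond,
                                "time_ms": t, "uV": v})
    pd.DataFrame(wf_rows).to_csv(out / "waveforms.csv", index=False)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
    _erp_figure(out / "erp_overview.png", waves, aligned, roi, conditions)


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    return str(x)


def _erp_figure(path: Path, waves, aligned, roi, conditions) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for (sys_name, cond), w in waves.items():
        axes[0].plot(w.times_ms, w.values, label=f"{sys_name} {cond}",
                     lw=1.0, alpha=0.9)
    axes[0].set_title("raw ERPs (" + "/".join(roi) + ")")
    for sys_name, al in aligned.items():
        ep = al.epochs.copy_with(valid=al.epochs.valid & al.aligned)
        for cond in conditions:
            w = erp.average_erp(ep, cond, roi)
            axes[1].plot(w.times_ms, w.values, label=f"{sys_name} {cond}",
                         lw=1.0, alpha=0.9)
    axes[1].set_title("time-corrected ERPs")
    for ax in axes:
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
    axes[0].set_ylabel("amplitude (uV)")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Resting pipeline
# ---------------------------------------------------------------------------


def run_resting_pipeline(cfg: Mapping[str, Any],
                         out_dir: str | Path | None = None,
                         *, recordings: Mapping[str, Any] | None = None) -> dict:
    """Resting-state spectra, alpha peaks, beta power and DFA per condition."""
    ana = cfg["analysis"]
    sim = cfg["simulation"]
    seed = int(cfg["seed"])
    fit_lo, fit_hi = ana.get("dfa_fit_range_s", [1.0, 280.0])
    duration = float(sim.get("duration_s", 300.0))
    # the largest DFA window is capped at a quarter of the recording; demand
    # at least a decade of window sizes above fit_lo for a meaningful fit
    if duration / 4.0 < 10.0 * fit_lo:
        raise ValueError(
            f"a {duration:.0f} s recording is too short for the requested "
            f"{fit_lo:g}-{fit_hi:g} s DFA fit range: the largest usable "
            f"window is {duration / 4.0:.1f} s; need >= {40 * fit_lo:.0f} s "
            "of signal")

    if recordings is None:
        recordings = {}
        amp = sim["alpha_amplitude_uV"]
        systems = [simulate.SystemModel("HQ"), simulate.SystemModel("LC")]
        for i, cond in enumerate(("eyes_open", "eyes_closed")):
            osc = simulate.OscillationSpec(
                hurst=float(sim.get("alpha_hurst", 0.75)),
                mean_amplitude_uV=float(amp[cond] if isinstance(amp, Mapping)
                                        else amp),
                duration_s=duration)
            pair = simulate.generate_resting_session(osc, systems, seed + i)
            for name, rec in pair.items():
                recordings[(name, cond)] = rec

    spec_rows, measures, dfa_results = [], [], {}
    for (sys_name, cond), rec in recordings.items():
        r = preprocessing.rereference(rec, "average")
        spec = spectral.compute_spectrum(
            r, tuple(ana.get("spectrum_band_hz", (0.5, 30.0))),
            float(ana.get("segment_length_s", 4.0)))
        for roi_name, roi_channels in ROIS.items():
            s = spectral.roi_average(spec, roi_channels, roi_name)
            pk = spectral.alpha_peak(s, tuple(ana.get("alpha_band_hz", (8, 12))))
            beta = spectral.relative_band_power(
                s, tuple(ana.get("beta_band_hz", (15, 30))),
                tuple(ana.get("spectrum_band_hz", (0.5, 30.0))))
            measures.append({
                "system": sys_name, "condition": cond, "roi": roi_name,
                "alpha_peak_hz": pk.frequency_hz, "alpha_peak_power": pk.power,
                "alpha_peak_found": pk.found, "relative_beta_power": beta})
            for f, p in zip(s.freqs, s.power):
                spec_rows.append({"system": sys_name, "condition": cond,
                                  "roi": roi_name, "freq_hz": f, "power": p})

        occ = alpha_bandpass(r.pick(OCCIPITAL_PAIR).mean(axis=0),
                             tuple(ana.get("alpha_band_hz", (8, 12))), fs=r.fs)
        env = amplitude_envelope(occ)
        grid = default_window_grid(len(env), r.fs, min_window_s=fit_lo,
                                   max_window_s=fit_hi)
        res = compute_dfa(env, r.fs, grid)
        assessment = assess_power_law(res, r2_threshold=float(
            ana.get("r2_threshold", 0.97)))
        dfa_results[(sys_name, cond)] = (res, assessment)

    summary = {
        "task": "resting", "seed": seed, "config_hash": config_hash(cfg),
        "band_measures": measures,
        "dfa": {f"{s}:{c}": {
            "alpha_exponent": res.alpha_exponent,
            "r_squared": res.r_squared,
            "significant_power_law": assessment.significant}
            for (s, c), (res, assessment) in dfa_results.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(spec_rows).to_csv(out / "spectra.csv", index=False)
        pd.DataFrame(measures).to_csv(out / "band_measures.csv", index=False)
        dfa_rows = [{"system": s, "condition": c, "tau_s": tau, "F": f}
                    for (s, c), (res, _) in dfa_results.items()
                    for tau, f in zip(res.window_sizes_s, res.fluctuation)]
        pd.DataFrame(dfa_rows).to_csv(out / "dfa.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
        _resting_figure(out / "resting_overview.png", spec_rows, dfa_results)
    return summary


def _resting_figure(path: Path, spec_rows, dfa_results) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(spec_rows)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for (sys_name, cond), g in df[df.roi == "posterior"].groupby(
            ["system", "condition"]):
        axes[0].semilogy(g.freq_hz, g.power, lw=1.0,
                         label=f"{sys_name} {cond}")
    axes[0].set_xlabel("frequency (Hz)")
    axes[0].set_ylabel("power (uV$^2$/Hz)")
    axes[0].set_title("posterior ROI spectra")
    axes[0].legend(fontsize=6)
    for (sys_name, cond), (res, _) in dfa_results.items():
        axes[1].loglog(res.window_sizes_s, res.fluctuation, "o-", ms=2, lw=0.8,
                       label=f"{sys_name} {cond} (alpha={res.alpha_exponent:.2f})")
    axes[1].set_xlabel("window size tau (s)")
    axes[1].set_ylabel("F(tau)")
    axes[1].set_title("DFA of alpha envelope (O1/O2)")
    axes[1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
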