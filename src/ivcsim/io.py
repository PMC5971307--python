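"""Result export: traces, layer stresses, metrics and summary tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import KPA_TO_MMHG, SimulationResult


def trace_frame(result: SimulationResult) -> pd.DataFrame:
    """Pressure trace with dp/dt (central differences) in clinical units."""
    t = result.trace.time
    p = result.trace.pressure
    dpdt = np.full_like(p, np.nan)
    if t.size >= 3:
        dpdt[1:-1] = (p[2:] - p[:-2]) / (t[2:] - t[:-2]) * 1000.0 * KPA_TO_MMHG
    return pd.DataFrame({
        "time_ms": t,
        "pressure_kPa": p,
        "pressure_mmHg": p * KPA_TO_MMHG,
        "volume_ml": result.trace.volume,
        "dpdt_mmHg_per_s": dpdt,
    })


def layer_stress_frame(result: SimulationResult) -> pd.DataFrame:
    cols = {f"layer{k+1}_kPa": result.layer_stress[:, k]
            for k in range(result.layer_stress.shape[1])}
    cols.update({f"layer{k+1}_active_kPa": result.layer_active_stress[:, k]
                 for k in range(result.layer_active_stress.shape[1])})
    return pd.DataFrame({"time_ms": result.trace.time, **cols})


def profile_frame(result: SimulationResult) -> pd.DataFrame:
    depth_pct, stress = result.end_profile()
    _, active = result.end_profile(active=True)
    return pd.DataFrame({"depth_pct": depth_pct,
                         "fibre_stress_kPa": stress,
                         "active_myocyte_stress_kPa": active})


def write_scenario_outputs(outdir, result: SimulationResult, metrics=None):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trace_frame(result).to_csv(out / "trace.csv", index=False)
    if result.layer_stress.size:
        layer_stress_frame(result).to_csv(out / "layer_stress.csv", index=False)
        profile_frame(result).to_csv(out / "profile_end_ivc.csv", index=False)
    if metrics is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(asdict(metrics), fh, indent=2)


def write_suite_outputs(outdir, metrics: dict, results: dict):
    from .experiments import summary_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in results.items():
        write_scenario_outputs(out / name, res, metrics.get(name))
    summary_table(metrics).to_csv(out / "summary.csv", index=False)


def plot_suite(outdir, results: dict):
    """Comparison plots: pressure traces and end-IVC transmural profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"control": "-", "const_emd": "--", "const_msv": ":",
              "const_both": "-.", "intramural": (0, (3, 1, 1, 1))}
    for name, res in results.items():
        ax.plot(res.trace.time, res.trace.pressure * KPA_TO_MMHG,
                ls=styles.get(name, "-"), label=name)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cavity pressure (mmHg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pressure_traces.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, res in results.items():
        if res.layer_active_stress.size:
            d, s = res.end_profile(active=True)
            ax.plot(d, s, marker="o", ls=styles.get(name, "-"), label=name)
    ax.set_xlabel("wall depth (% from endocardium)")
    ax.set_ylabel("end-IVC active myocyte stress (kPa)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "transmural_profiles.png", dpi=150)
    plt.close(fig)
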