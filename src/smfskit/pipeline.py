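"""End-to-end panel orchestration: simulate -> correct -> detect -> fit.

Reproduces the comparative design of a multiplexed SMFS screen in silico:
a panel of constructs, each probed without ligand (apo), with ligand
(bound, stiffer unfolding kinetics) and optionally under a non-binding
control, at one or more pulling speeds.  Each panel cell is simulated,
corrected, filtered by the fingerprint classifier, and summarized by
histogram/KDE force statistics; apo-vs-bound shifts and (with two or more
speeds) dynamic force spectra are computed per construct.  The whole run is
deterministic given the master seed, and the analysis never reads the
simulation ground truth.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np

from .bellevans import BellEvansParams
from .correct import correct_baseline, correct_invols, smooth_median
from .events import analyze_curve
from .fitting import (
    RuptureDataset,
    compare_conditions,
    dfs_from_datasets,
    fit_bell_evans_histogram,
    kde_modes,
    mode_standard_error,
)
from .simulate import SimulationConfig, fingerprint_construct, simulate_curve

#: histogram fits with reduced chi^2 above this are summarized by KDE modes
CHI2_KDE_THRESHOLD = 3.0


def _cell_seed(master_seed: int, *labels) -> int:
    """Stable per-cell seed independent of iteration order."""
    tag = "/".join(str(x) for x in labels)
    return (master_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def analyze_cell(construct: str, condition: str, kinetics: BellEvansParams,
                 speed: float, n_curves: int, seed: int,
                 sim_overrides: dict | None = None,
                 analysis_options: dict | None = None) -> tuple[RuptureDataset, dict]:
    """Simulate and analyze one construct x condition x speed cell.

    Returns the pooled cohesin rupture dataset (accepted traces only) and a
    stats dict (acceptance counts and rejection reasons).
    """
    overrides = dict(sim_overrides or {})
    opts = dict(analysis_options or {})
    base = SimulationConfig(segments=tuple(fingerprint_construct(kinetics)),
                            pulling_speed=speed, construct=construct,
                            condition=condition, **overrides)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_curves) % (2**31)
    forces, rates = [], []
    n_accepted = 0
    reasons: dict[str, int] = {}
    for s in child_seeds:
        curve, _ = simulate_curve(replace(base, seed=int(s)))
        pre = correct_baseline(
            correct_invols(curve, 1.0, float(curve.metadata.get("invols", 1.0))))
        smoothed = smooth_median(pre)
        ana = analyze_curve(smoothed, raw=pre, **opts)
        cls = ana.classification
        reasons[cls.reason] = reasons.get(cls.reason, 0) + 1
        if cls.accepted and cls.cohesin_event.reliable:
            ev = cls.cohesin_event
            if ev.loading_rate > 0:
                n_accepted += 1
                forces.append(ev.rupture_force)
                rates.append(ev.loading_rate)
    ds = RuptureDataset(np.asarray(forces), np.asarray(rates),
                        construct=construct, condition=condition, pulling_speed=speed)
    stats = {"n_curves": n_curves, "n_accepted": n_accepted, "reasons": reasons}
    return ds, stats


def _summarize(ds: RuptureDataset, bin_size: float, seed: int) -> dict:
    """Histogram fit + KDE modes + mode SE for one cell's rupture forces."""
    out: dict = {"n": ds.n}
    if ds.n < 20:
        out["method"] = "insufficient"
        return out
    fit = fit_bell_evans_histogram(ds, bin_size=bin_size)
    kde = kde_modes(ds)
    method = "bell_evans"
    if not fit.converged or fit.reduced_chi2 > CHI2_KDE_THRESHOLD:
        method = "kde"
    modes = [fit.most_probable_force] if method == "bell_evans" else kde.modes
    out.update({
        "method": method,
        "modes_pN": [round(m, 3) for m in modes],
        "bell_evans": {
            "delta_x_nm": round(fit.params.delta_x, 5),
            "k0_per_s": float(f"{fit.params.k0:.5g}"),
            "sd_delta_x_nm": round(fit.param_sds[0], 5),
            "sd_k0_per_s": float(f"{fit.param_sds[1]:.5g}"),
            "most_probable_force_pN": round(fit.most_probable_force, 3),
            "reduced_chi2": round(fit.reduced_chi2, 3),
            "converged": fit.converged,
            "bin_size_pN": bin_size,
            "loading_rate_pN_s": float(f"{fit.loading_rate_used:.6g}"),
        },
        "kde_modes_pN": [round(m, 3) for m in kde.modes],
        "kde_bandwidth_pN": round(kde.bandwidth, 3),
        "mode_se_pN": round(mode_standard_error(ds, seed=seed), 3),
    })
    return out


def run_panel(config: dict, seed: int | None = None,
              outdir: str | Path | None = None) -> dict:
    """Run the full comparative panel described by ``config``.

    Config keys: ``constructs`` (mapping name -> mapping condition ->
    {delta_x, k0}), ``speeds`` (list of nm/s; the first is the main
    comparison speed), ``n_curves`` per cell, ``seed``, optional
    ``simulation`` and ``analysis`` override mappings and ``bin_size``.
    Every cell failure is recorded in the report rather than dropped.
    """
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    speeds = [float(s) for s in config.get("speeds", [1600.0])]
    n_curves = int(config.get("n_curves", 300))
    bin_size = float(config.get("bin_size", 25.0))
    sim_over = config.get("simulation", {})
    ana_opts = config.get("analysis", {})

    canonical = json.dumps(config, sort_keys=True).encode()
    report: dict = {
        "config_hash": hashlib.sha256(canonical).hexdigest(),
        "seed": master_seed,
        "cells": {},
        "comparisons": {},
        "dfs": {},
    }
    datasets: dict[tuple[str, str, float], RuptureDataset] = {}

    for construct, conditions in config["constructs"].items():
        for condition, kin in conditions.items():
            kinetics = BellEvansParams(float(kin["delta_x"]), float(kin["k0"]))
            for speed in speeds:
                cell_id = f"{construct}/{condition}/{speed:g}"
                try:
                    ds, stats = analyze_cell(
                        construct, condition, kinetics, speed, n_curves,
                        _cell_seed(master_seed, construct, condition, speed),
                        sim_overrides=sim_over, analysis_options=ana_opts)
                    datasets[(construct, condition, speed)] = ds
                    summary = _summarize(ds, bin_size,
                                         _cell_seed(master_seed, cell_id, "boot"))
                    summary.update(stats)
                    report["cells"][cell_id] = summary
                except Exception as exc:  # noqa: BLE001 - cell failures must surface
                    report["cells"][cell_id] = {"error": f"{type(exc).__name__}: {exc}"}

    main_speed = speeds[0]
    for construct, conditions in config["constructs"].items():
        for other in ("bound", "control"):
            if "apo" not in conditions or other not in conditions:
                continue
            apo_cell = report["cells"].get(f"{construct}/apo/{main_speed:g}", {})
            other_cell = report["cells"].get(f"{construct}/{other}/{main_speed:g}", {})
            if "modes_pN" not in apo_cell or "modes_pN" not in other_cell:
                report["comparisons"][f"{construct}/{other}"] = {"error": "missing cell"}
                continue
            shifts = compare_conditions(apo_cell["modes_pN"],
                                        other_cell["modes_pN"][0])
            se = math.hypot(apo_cell.get("mode_se_pN", math.nan),
                            other_cell.get("mode_se_pN", math.nan))
            report["comparisons"][f"{construct}/{other}"] = {
                "shifts": [{"F_apo_pN": round(s.force_apo, 3),
                            "F_other_pN": round(s.force_bound, 3),
                            "delta_F_pN": round(s.delta, 3),
                            "percent": round(s.percent, 2)} for s in shifts],
                "combined_mode_se_pN": round(se, 3),
            }

    if len(speeds) >= 2:
        for construct, conditions in config["constructs"].items():
            for condition in conditions:
                key = f"{construct}/{condition}"
                cell_sets = [datasets[(construct, condition, sp)] for sp in speeds
                             if (construct, condition, sp) in datasets
                             and datasets[(construct, condition, sp)].n >= 20]
                if len(cell_sets) < 2:
                    report["dfs"][key] = {"error": "fewer than 2 usable speeds"}
                    continue
                try:
                    fit = dfs_from_datasets(cell_sets)
                    report["dfs"][key] = {
                        "delta_x_nm": round(fit.params.delta_x, 5),
                        "k0_per_s": float(f"{fit.params.k0:.5g}"),
                        "sd_delta_x_nm": round(fit.param_sds[0], 5),
                        "sd_k0_per_s": float(f"{fit.param_sds[1]:.5g}"),
                        "loading_rates_pN_s": [float(f"{r:.6g}") for r in fit.loading_rates],
                        "forces_pN": [round(f, 3) for f in fit.forces],
                        "fwhms_pN": [round(w, 3) for w in fit.fwhms],
                        "speeds_nm_s": fit.speeds,
                    }
                except Exception as exc:  # noqa: BLE001
                    report["dfs"][key] = {"error": f"{type(exc).__name__}: {exc}"}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.json")
        write_summary_table(report, outdir / "summary.tsv")
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_summary_table(report: dict, path: str | Path) -> None:
    """Flat TSV: one row per cell with the headline numbers."""
    with open(path, "w") as fh:
        fh.write("construct\tcondition\tspeed_nm_s\tn\tmethod\tmodes_pN\t"
                 "delta_x_nm\tsd_delta_x_nm\tk0_per_s\tsd_k0_per_s\tbin_size_pN\n")
        for cell_id in sorted(report["cells"]):
            cell = report["cells"][cell_id]
            construct, condition, speed = cell_id.split("/")
            if "error" in cell or cell.get("method") == "insufficient":
                fh.write(f"{construct}\t{condition}\t{speed}\t{cell.get('n', 0)}\t"
                         f"failed\t-\t-\t-\t-\t-\t-\n")
                continue
            be = cell["bell_evans"]
            modes = ";".join(f"{m:g}" for m in cell["modes_pN"])
            fh.write(f"{construct}\t{condition}\t{speed}\t{cell['n']}\t"
                     f"{cell['method']}\t{modes}\t{be['delta_x_nm']}\t"
                     f"{be['sd_delta_x_nm']}\t{be['k0_per_s']}\t{be['sd_k0_per_s']}\t"
                     f"{be['bin_size_pN']}\n")


def make_figures(report: dict, outdir: str | Path,
                 datasets: dict | None = None) -> list[Path]:
    """Histogram panels (apo vs bound overlays) and DFS plots from a report.

    Histogram panels need the raw per-cell force arrays; when ``datasets``
    (mapping (construct, condition, speed) -> RuptureDataset) is not
    supplied only the DFS plots — which are reconstructable from the report
    alone — are drawn.  Cells without data are annotated, not dropped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if datasets:
        constructs = sorted({k[0] for k in datasets})
        for construct in constructs:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            plotted = False
            for condition, color in (("apo", "#c56400"), ("bound", "#c40000"),
                                     ("control", "#555555")):
                keys = [k for k in datasets if k[0] == construct and k[1] == condition]
                if not keys:
                    continue
                ds = datasets[keys[0]]
                if ds.n == 0:
                    continue
                plotted = True
                ax.hist(ds.forces, bins=np.arange(0, ds.forces.max() + 50, 25),
                        density=True, alpha=0.45, color=color, label=condition)
                cell = report["cells"].get(f"{construct}/{condition}/{keys[0][2]:g}", {})
                grid = np.linspace(0, ds.forces.max() + 50, 400)
                if cell.get("method") == "kde":
                    from scipy.stats import gaussian_kde
                    ax.plot(grid, gaussian_kde(ds.forces, bw_method="silverman")(grid),
                            ":", color=color)
                elif cell.get("method") == "bell_evans":
                    from .bellevans import BellEvansParams as BEP, bell_evans_pdf
                    be = cell["bell_evans"]
                    p = BEP(be["delta_x_nm"], be["k0_per_s"])
                    ax.plot(grid, bell_evans_pdf(grid, p, be["loading_rate_pN_s"]),
                            "--" if condition == "apo" else "-", color=color)
            if not plotted:
                ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction",
                            ha="center")
            ax.set_xlabel("rupture force (pN)")
            ax.set_ylabel("density (1/pN)")
            ax.set_title(construct)
            ax.legend(frameon=False)
            path = outdir / f"hist_{construct}.png"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            written.append(path)

    if report.get("dfs"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        any_dfs = False
        for key, dfs in sorted(report["dfs"].items()):
            if "error" in dfs:
                continue
            any_dfs = True
            r = np.asarray(dfs["loading_rates_pN_s"])
            F = np.asarray(dfs["forces_pN"])
            w = np.asarray(dfs["fwhms_pN"])
            ax.errorbar(r, F, yerr=w / 2, fmt="o", capsize=3, label=key)
            from .bellevans import BellEvansParams as BEP, most_probable_force
            p = BEP(dfs["delta_x_nm"], dfs["k0_per_s"])
            grid = np.geomspace(r.min() / 2, r.max() * 2, 100)
            ax.plot(grid, [most_probable_force(p, g) for g in grid], "--", lw=1)
        if any_dfs:
            ax.set_xscale("log")
            ax.set_xlabel("loading rate (pN/s)")
            ax.set_ylabel("most probable rupture force (pN)")
            ax.legend(frameon=False, fontsize=7)
        else:
            ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction", ha="center")
        path = outdir / "dfs.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
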