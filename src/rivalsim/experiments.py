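"""Composable experiment runners: single runs, drive scans, theory sweeps.

These functions glue the simulator to the measurement battery and return
tidy tables; the command-line interface in :mod:`rivalsim.cli` is a thin
wrapper around them.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as ms
from . import theory
from .config import RunConfig
from .network import simulate
from .raster import SpikeRaster, _jsonable


def analyze_raster(
    raster: SpikeRaster,
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    burn_in_ms: float = 2000.0,
    window_ms: float = 50.0,
    report_threshold_ms: float = 300.0,
    spike_window_ms: float = 100.0,
    n_pairs: int = 1000,
    pair_seed: int | None = None,
    subthreshold_policy: str = "absorb",
    spike_stats: bool = True,
) -> dict:
    """Full measurement battery on one raster.

    Returns a dict with the dominance statistics, state-conditioned spiking
    statistics (means and per-neuron tables), and per-epoch table.  Spiking
    statistics are pooled over both pools: "dominant" collects each pool's
    E neurons during that pool's reported dominance.
    """
    trace = ms.percept_trace(raster, pool_a, pool_b, window_ms, t_start=burn_in_ms)
    dom = ms.dominance_durations(trace, report_threshold_ms, subthreshold_policy)
    out: dict = {
        "trace": trace,
        "dominance": dom,
        "n_epochs": int(dom.durations.size),
        "mean_duration_ms": dom.mean,
        "cv_d": dom.cv_d,
        "skewness": dom.skewness,
        "gamma_shape": dom.gamma_shape,
        "gamma_scale": dom.gamma_scale,
        "predominance_a": dom.predominance_a,
        "alternation_rate_hz": dom.alternation_rate_hz,
    }
    if not spike_stats:
        return out
    mask = ms.state_mask(trace, report_threshold_ms, subthreshold_policy)
    int_a_dom = ms._state_intervals(trace, mask == 1)
    int_b_dom = ms._state_intervals(trace, mask == -1)
    pools = {"a": (pool_a, int_a_dom, int_b_dom), "b": (pool_b, int_b_dom, int_a_dom)}
    cv_dom, cv_sup, fano_dom, fano_sup, rsc_dom, rsc_sup = [], [], [], [], [], []
    rate_dom, rate_sup = [], []
    for tag, (pool, dom_int, sup_int) in pools.items():
        cv_dom.append(ms.cv_isi(raster, pool, dom_int))
        cv_sup.append(ms.cv_isi(raster, pool, sup_int))
        fano_dom.append(ms.fano_factor(raster, pool, dom_int, spike_window_ms))
        fano_sup.append(ms.fano_factor(raster, pool, sup_int, spike_window_ms))
        seed_off = 0 if tag == "a" else 1
        rsc_dom.append(ms.spike_count_correlations(
            raster, pool, dom_int, spike_window_ms, n_pairs,
            None if pair_seed is None else pair_seed + seed_off))
        rsc_sup.append(ms.spike_count_correlations(
            raster, pool, sup_int, spike_window_ms, n_pairs,
            None if pair_seed is None else pair_seed + 2 + seed_off))
        for intervals, sink in ((dom_int, rate_dom), (sup_int, rate_sup)):
            counts = ms._windowed_counts(raster, pool, intervals, spike_window_ms)
            if counts.shape[1]:
                sink.append(counts.mean(axis=1) * (1000.0 / spike_window_ms))
    def _cat(parts):
        parts = [np.asarray(p) for p in parts if len(p)]
        return np.concatenate(parts) if parts else np.empty(0)
    cv_dom_all = _cat([s.values for s in cv_dom])
    cv_sup_all = _cat([s.values for s in cv_sup])
    fano_dom_all = _cat([s.values for s in fano_dom])
    rsc_dom_all, rsc_sup_all = _cat(rsc_dom), _cat(rsc_sup)
    out.update({
        "cv_isi_dominant": float(cv_dom_all.mean()) if cv_dom_all.size else np.nan,
        "cv_isi_suppressed": float(cv_sup_all.mean()) if cv_sup_all.size else np.nan,
        "fano_dominant": float(fano_dom_all.mean()) if fano_dom_all.size else np.nan,
        "r_sc_dominant": float(rsc_dom_all.mean()) if rsc_dom_all.size else np.nan,
        "r_sc_suppressed": float(rsc_sup_all.mean()) if rsc_sup_all.size else np.nan,
        "rate_dominant_hz": float(_cat(rate_dom).mean()) if rate_dom else np.nan,
        "rate_suppressed_hz": float(_cat(rate_sup).mean()) if rate_sup else np.nan,
        "tables": {
            "cv_isi_dominant": pd.concat(cv_dom, keys=["a", "b"]),
            "cv_isi_suppressed": pd.concat(cv_sup, keys=["a", "b"]),
            "fano_dominant": pd.concat(fano_dom, keys=["a", "b"]),
            "fano_suppressed": pd.concat(fano_sup, keys=["a", "b"]),
            "r_sc_dominant": rsc_dom_all,
            "r_sc_suppressed": rsc_sup_all,
        },
    })
    return out


def epochs_table(result: dict) -> pd.DataFrame:
    dom = result["dominance"]
    return pd.DataFrame(
        [{"label": "A" if e.label == 1 else "B", "start_ms": e.start,
          "end_ms": e.end, "duration_ms": e.duration, "censored": e.censored}
         for e in dom.epochs]
    )


def run_experiment(cfg: RunConfig, out_dir: str | Path | None = None,
                   spike_stats: bool = True, log=None) -> dict:
    """One config-driven simulation plus the measurement battery.

    Writes (when ``out_dir`` given): the raster (TSV + metadata sidecar),
    per-epoch table, per-neuron statistic tables and a JSON summary.
    """
    t0 = time.time()
    conn = cfg.build_connectivity()
    params = cfg.neuron_params()
    drive = cfg.build_drive(conn)
    raster = simulate(
        conn, params, drive, cfg.run["duration_ms"],
        seed=cfg.run["init_seed"], weight_interp=cfg.run["weight_interp"],
        scheme=cfg.run["scheme"],
    )
    raster.metadata["config"] = cfg.to_dict()
    pool_a, pool_b = cfg.percept_pools(conn)
    m = cfg.measures
    result = analyze_raster(
        raster, pool_a, pool_b,
        burn_in_ms=cfg.run["burn_in_ms"], window_ms=m["window_ms"],
        report_threshold_ms=m["report_threshold_ms"],
        spike_window_ms=m["spike_window_ms"], n_pairs=m["n_pairs"],
        pair_seed=m["pair_seed"], subthreshold_policy=m["subthreshold_policy"],
        spike_stats=spike_stats,
    )
    result["raster"] = raster
    result["conn"] = conn
    result["wall_time_s"] = time.time() - t0
    if log:
        log(f"simulated {cfg.run['duration_ms']:.0f} ms in "
            f"{result['wall_time_s']:.1f} s; {raster.n_events} spikes; "
            f"{result['n_epochs']} completed dominance epochs")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if cfg.output.get("save_raster", True):
            raster.save(out_dir / "raster.tsv")
        epochs_table(result).to_csv(out_dir / "epochs.csv", index=False)
        if spike_stats:
            for name in ("cv_isi_dominant", "cv_isi_suppressed",
                         "fano_dominant", "fano_suppressed"):
                tab = result["tables"][name]
                tab.rename("value").to_csv(out_dir / f"{name}.csv",
                                           index_label=["pool", "neuron"])
        summary = {k: v for k, v in result.items()
                   if isinstance(v, (int, float, str))}
        (out_dir / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2))
    return result


def scan_experiment(
    cfg: RunConfig,
    grid: np.ndarray,
    axis: str = "symmetric",
    out_dir: str | Path | None = None,
    spike_stats: bool = False,
    log=None,
) -> pd.DataFrame:
    """Repeat the configured run across a drive grid.

    ``axis='symmetric'`` drives both pools at each grid value;
    ``axis='pool_a_only'`` varies pool A with pool B at the configured base
    value.  Returns one statistics row per grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("scan grid needs at least 2 points")
    if axis not in ("symmetric", "pool_a_only"):
        raise ValueError(f"unknown scan axis {axis!r}")
    conn = cfg.build_connectivity()
    params = cfg.neuron_params()
    pool_a, pool_b = cfg.percept_pools(conn)
    m = cfg.measures
    rows = []
    for g in grid:
        if axis == "symmetric":
            drive = cfg.build_drive(conn, value=g, value_b=g)
        else:
            drive = cfg.build_drive(conn, value=g, value_b=cfg.drive["value"])
        raster = simulate(
            conn, params, drive, cfg.run["duration_ms"],
            seed=cfg.run["init_seed"], weight_interp=cfg.run["weight_interp"],
            scheme=cfg.run["scheme"],
        )
        res = analyze_raster(
            raster, pool_a, pool_b,
            burn_in_ms=cfg.run["burn_in_ms"], window_ms=m["window_ms"],
            report_threshold_ms=m["report_threshold_ms"],
            spike_window_ms=m["spike_window_ms"], n_pairs=m["n_pairs"],
            pair_seed=m["pair_seed"],
            subthreshold_policy=m["subthreshold_policy"],
            spike_stats=spike_stats,
        )
        row = {"drive": float(g), "axis": axis}
        for key in ("n_epochs", "mean_duration_ms", "cv_d", "skewness",
                    "predominance_a", "alternation_rate_hz",
                    "cv_isi_dominant", "cv_isi_suppressed",
                    "fano_dominant", "r_sc_dominant", "r_sc_suppressed",
                    "rate_dominant_hz", "rate_suppressed_hz"):
            if key in res:
                row[key] = res[key]
        sd = res["dominance"].sd
        row["sd_duration_ms"] = sd
        rows.append(row)
        if log:
            log(f"drive={g:g}: {row['n_epochs']} epochs, "
                f"mean={row['mean_duration_ms']:.0f} ms, CV_D={row['cv_d']:.2f}")
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / f"scan_{axis}.csv", index=False)
    return frame


def scan_report(frame: pd.DataFrame, base_drive: float | None = None) -> dict:
    """Levelt checks, the sigma-mu regression and variability trends for a
    completed scan frame."""
    out: dict = {}
    if (frame["axis"] == "symmetric").all():
        sym = frame.rename(columns={"mean_duration_ms": "mean_duration"})
        out["levelt"] = ms.levelt_checks(symmetric_scan=sym)
        ok = frame["n_epochs"] >= 3
        if ok.sum() >= 3:
            slope, p = ms.sigma_mu_regression(
                frame.loc[ok, "mean_duration_ms"], frame.loc[ok, "sd_duration_ms"])
            out["sigma_mu_slope"] = slope
            out["sigma_mu_pvalue"] = p
        for col, name in (("cv_d", "cv_d_trend"),
                          ("cv_isi_dominant", "cv_isi_dominant_trend")):
            if col in frame and frame[col].notna().sum() >= 3:
                from scipy.stats import spearmanr
                rho, p = spearmanr(frame["drive"], frame[col],
                                   nan_policy="omit")
                out[name] = {"spearman_rho": float(rho), "p_value": float(p)}
    else:
        pa = frame.rename(columns={"drive": "drive_a",
                                   "alternation_rate_hz": "alternation_rate"})
        # predominance fractions sum to one by construction
        pa["predominance_b"] = 1.0 - pa["predominance_a"]
        out["levelt"] = ms.levelt_checks(
            pool_a_scan=pa, equidominance_base=base_drive)
    return out


def theory_sweep_for_config(
    cfg: RunConfig, w_long_grid_amplitude: np.ndarray
) -> tuple[pd.DataFrame, float | None]:
    """Mean-field sweep over the long-range amplitude grid (A units, i.e.
    the same scale as A_ie_long before the sqrt(k) division)."""
    conn = cfg.build_connectivity()
    params = cfg.neuron_params()
    drive = cfg.build_drive(conn)
    system = theory.meanfield_from_architecture(conn, drive, params)
    grid_eff = np.array([
        theory.effective_weight(a, cfg.architecture["k"], params)
        for a in np.asarray(w_long_grid_amplitude, dtype=float)
    ])
    frame, singular = theory.sweep_mutual_inhibition(system, grid_eff)
    frame.insert(0, "A_ie_long", np.asarray(w_long_grid_amplitude, dtype=float))
    if singular is not None:
        singular = singular / (np.sqrt(cfg.architecture["k"]) * params.tau_s)
    return frame, singular
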