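"""Perceptual and spiking statistics derived from spike rasters.

The perceptual pipeline converts pooled excitatory spike counts into a percept
state variable P = (u_A - u_B)/(u_A + u_B) on non-overlapping windows
(default 50 ms), classifies each window as percept A (P > 1/3), percept B
(P < -1/3) or neither, filters the label sequence with a report threshold
(minimum reportable event duration), and measures dominance durations as the
intervals between reported state changes.

The spiking pipeline computes, per neuron and separately for dominant and
suppressed states of the neuron's pool: the interspike-interval coefficient of
variation (CV_ISI), the spike-count Fano factor on 100 ms windows, and
pairwise spike-count correlations (r_sc) on 100 ms windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .raster import SpikeRaster

NEITHER = 0
POOL_A = 1
POOL_B = -1


# ---------------------------------------------------------------------------
# percept state
# ---------------------------------------------------------------------------

@dataclass
class PerceptTrace:
    """Windowed percept state variable over [t_start, t_start + n*window)."""

    window: float  # ms
    t_start: float  # ms
    u_a: np.ndarray  # pooled E spike counts, pool A
    u_b: np.ndarray
    p: np.ndarray  # percept state variable in [-1, 1]
    label: np.ndarray  # +1 A, -1 B, 0 neither

    @property
    def n_windows(self) -> int:
        return self.label.size

    @property
    def t_end(self) -> float:
        return self.t_start + self.n_windows * self.window

    def window_times(self) -> np.ndarray:
        """Left edge of each window (ms)."""
        return self.t_start + self.window * np.arange(self.n_windows)


def percept_trace(
    raster: SpikeRaster,
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    window: float = 50.0,
    t_start: float = 0.0,
) -> PerceptTrace:
    """Percept state variable from pooled excitatory activity.

    Windows tile [t_start, duration) without overlap (a trailing partial
    window is dropped).  A window with no spikes in either pool, or with
    |P| exactly 1/3, is classified "neither".
    """
    pool_a = np.asarray(pool_a)
    pool_b = np.asarray(pool_b)
    if pool_a.size == 0 or pool_b.size == 0:
        raise ValueError("both percept pools must be non-empty")
    n_windows = int(np.floor((raster.duration - t_start) / window))
    if n_windows < 1:
        raise ValueError("raster shorter than one percept window")
    edges = t_start + window * np.arange(n_windows + 1)
    in_a = np.isin(raster.ids, pool_a)
    in_b = np.isin(raster.ids, pool_b)
    u_a = np.histogram(raster.times[in_a], bins=edges)[0]
    u_b = np.histogram(raster.times[in_b], bins=edges)[0]
    tot = u_a + u_b
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, (u_a - u_b) / np.where(tot > 0, tot, 1), 0.0)
    label = np.zeros(n_windows, dtype=np.int8)
    label[p > 1 / 3] = POOL_A
    label[p < -1 / 3] = POOL_B
    return PerceptTrace(window=window, t_start=t_start, u_a=u_a, u_b=u_b,
                        p=p, label=label)


# ---------------------------------------------------------------------------
# dominance durations
# ---------------------------------------------------------------------------

@dataclass
class ReportedEpoch:
    label: int  # +1 pool A, -1 pool B
    start: float  # ms
    end: float  # ms
    censored: bool  # first/last epoch: true duration unknown

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class DominanceStats:
    """Reported dominance epochs and their summary statistics.

    ``epochs`` lists every reported epoch including the censored first/last
    ones; all moment/fit fields are computed on completed (non-censored)
    durations only.  ``defined`` is False when fewer than two completed
    epochs exist; the numeric fields are then NaN, never silent numbers.
    """

    report_threshold: float
    epochs: list = field(default_factory=list)
    defined: bool = False
    mean: float = np.nan
    sd: float = np.nan
    cv_d: float = np.nan
    skewness: float = np.nan
    gamma_shape: float = np.nan
    gamma_scale: float = np.nan
    predominance_a: float = np.nan
    predominance_b: float = np.nan
    alternation_rate_hz: float = np.nan

    @property
    def durations(self) -> np.ndarray:
        """Completed (non-censored) dominance durations (ms)."""
        return np.array([e.duration for e in self.epochs if not e.censored])

    @property
    def all_durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.epochs])


def _label_runs(label: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start window, end window) for maximal constant runs."""
    runs = []
    start = 0
    for i in range(1, label.size + 1):
        if i == label.size or label[i] != label[start]:
            runs.append((int(label[start]), start, i))
            start = i
    return runs


def reported_epochs(
    trace: PerceptTrace, report_threshold: float, policy: str = "absorb"
) -> list[ReportedEpoch]:
    """Filter the window labels into reported percept epochs.

    The reported percept changes at the start of any run of a *different*
    label — percept A, percept B, or neither — that lasts at least
    ``report_threshold`` (the minimum reportable event duration).  Runs
    shorter than the threshold are sub-threshold events: under the default
    ``absorb`` policy the duration clock keeps running through them, so they
    are absorbed into the ongoing reported epoch; under ``drop`` an epoch
    ends at the end of its last qualifying run instead.  Only A/B epochs are
    returned (a qualifying "neither" run terminates the ongoing epoch without
    opening a new one).  With threshold 0 every labeled run is reported
    unchanged.  The first and last epochs are marked censored: their true
    onset/offset is not observed.
    """
    if report_threshold < 0:
        raise ValueError("report threshold must be non-negative")
    if policy not in ("absorb", "drop"):
        raise ValueError(f"unknown sub-threshold policy {policy!r}")
    w = trace.window
    runs = _label_runs(trace.label)
    epochs: list[ReportedEpoch] = []
    current = NEITHER
    epoch_start = None
    last_qual_end = None  # end of the last qualifying run of current percept
    for lab, i0, i1 in runs:
        dur = (i1 - i0) * w
        if dur >= report_threshold and lab != current:
            t0 = trace.t_start + i0 * w
            if current != NEITHER:
                end = t0 if policy == "absorb" else last_qual_end
                epochs.append(ReportedEpoch(current, epoch_start, end, False))
            current = lab
            epoch_start = t0 if lab != NEITHER else None
            last_qual_end = trace.t_start + i1 * w
        elif lab == current and lab != NEITHER:
            last_qual_end = trace.t_start + i1 * w
    if current != NEITHER:
        end = trace.t_end if policy == "absorb" else last_qual_end
        epochs.append(ReportedEpoch(current, epoch_start, end, True))
    if epochs:
        epochs[0] = ReportedEpoch(
            epochs[0].label, epochs[0].start, epochs[0].end, True
        )
    return epochs


def duration_moments(durations: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, SD, CV_D, skewness, skewness/CV_D) of dominance durations.

    SD uses ddof=1; skewness is the adjusted Fisher-Pearson (bias-corrected)
    estimator.  Degenerate variance gives CV_D = 0 and undefined skewness.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations")
    mu = durations.mean()
    sd = durations.std(ddof=1)
    if sd == 0:
        return mu, 0.0, 0.0, np.nan, np.nan
    cv = sd / mu
    skew = float(sps.skew(durations, bias=False))
    return mu, sd, cv, skew, skew / cv


def dominance_durations(
    trace: PerceptTrace,
    report_threshold: float = 300.0,
    policy: str = "absorb",
) -> DominanceStats:
    """Reported dominance durations and their statistics.

    The gamma shape/scale are maximum-likelihood estimates (location fixed
    at zero) on the completed durations.
    """
    epochs = reported_epochs(trace, report_threshold, policy)
    out = DominanceStats(report_threshold=report_threshold, epochs=epochs)
    completed = out.durations
    # predominance and alternation need reported epochs at all
    if epochs:
        span_a = sum(e.duration for e in epochs if e.label == POOL_A)
        span_b = sum(e.duration for e in epochs if e.label == POOL_B)
        if span_a + span_b > 0:
            out.predominance_a = span_a / (span_a + span_b)
            out.predominance_b = span_b / (span_a + span_b)
        reported_span = epochs[-1].end - epochs[0].start
        if reported_span > 0:
            out.alternation_rate_hz = (len(epochs) - 1) / (reported_span / 1000.0)
    if completed.size < 2:
        return out
    out.defined = True
    out.mean, out.sd, out.cv_d, out.skewness, _ = duration_moments(completed)
    if completed.size >= 3 and out.sd > 0:
        shape, _, scale = sps.gamma.fit(completed, floc=0)
        out.gamma_shape, out.gamma_scale = float(shape), float(scale)
    return out


def sigma_mu_regression(
    mus: np.ndarray, sigmas: np.ndarray, through_origin: bool = True
) -> tuple[float, float]:
    """Regression of dominance-duration SD on mean across drive strengths.

    Through the origin (default) the slope is directly interpretable as an
    overall CV_D.  Returns (slope, two-sided p-value); the p-value is
    descriptive only.
    """
    mus = np.asarray(mus, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    ok = np.isfinite(mus) & np.isfinite(sigmas)
    mus, sigmas = mus[ok], sigmas[ok]
    if mus.size < 3:
        raise ValueError("need at least 3 (mu, sigma) pairs")
    if through_origin:
        slope = float(np.sum(mus * sigmas) / np.sum(mus**2))
        resid = sigmas - slope * mus
        dof = mus.size - 1
        se = np.sqrt(np.sum(resid**2) / dof / np.sum(mus**2))
        tval = slope / se if se > 0 else np.inf
        p = 2 * sps.t.sf(abs(tval), dof)
    else:
        res = sps.linregress(mus, sigmas)
        slope, p = float(res.slope), float(res.pvalue)
    return slope, float(p)


# ---------------------------------------------------------------------------
# state masks and state-conditioned spiking statistics
# ---------------------------------------------------------------------------

def state_mask(trace: PerceptTrace, report_threshold: float = 300.0,
               policy: str = "absorb") -> np.ndarray:
    """Per-window reported-state assignment.

    Returns an int8 array over windows: +1 where the reported percept is A
    and the raw window label agrees, -1 likewise for B, 0 otherwise.
    Pool A is *dominant* in +1 windows and *suppressed* in -1 windows (and
    vice versa for pool B); neither-windows and sub-threshold events inside
    an epoch are excluded from both states.
    """
    epochs = reported_epochs(trace, report_threshold, policy)
    out = np.zeros(trace.n_windows, dtype=np.int8)
    w = trace.window
    for e in epochs:
        i0 = int(round((e.start - trace.t_start) / w))
        i1 = int(round((e.end - trace.t_start) / w))
        seg = slice(i0, i1)
        agree = trace.label[seg] == e.label
        out[seg][agree] = e.label
    return out


def _state_intervals(trace: PerceptTrace, mask: np.ndarray) -> np.ndarray:
    """Contiguous time intervals [t0, t1) where ``mask`` (bool per window)
    holds, as an (n, 2) array in ms."""
    intervals = []
    w = trace.window
    start = None
    for i in range(mask.size + 1):
        on = i < mask.size and mask[i]
        if on and start is None:
            start = i
        elif not on and start is not None:
            intervals.append((trace.t_start + start * w, trace.t_start + i * w))
            start = None
    return np.array(intervals).reshape(-1, 2)


def cv_isi(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    intervals: np.ndarray,
    min_isis: int = 3,
) -> pd.Series:
    """Per-neuron CV of interspike intervals within state epochs.

    ISIs are collected within each contiguous state interval (never spanning
    a state change) and pooled across the neuron's intervals.  Neurons with
    fewer than ``min_isis`` qualifying ISIs are excluded.
    """
    trains = raster.by_neuron()
    out = {}
    for nid in np.asarray(neuron_ids):
        train = trains.get(int(nid))
        if train is None:
            continue
        isis = []
        for t0, t1 in intervals:
            seg = train[np.searchsorted(train, t0): np.searchsorted(train, t1)]
            if seg.size >= 2:
                isis.append(np.diff(seg))
        if not isis:
            continue
        isis = np.concatenate(isis)
        if isis.size < min_isis:
            continue
        out[int(nid)] = isis.std(ddof=1) / isis.mean()
    return pd.Series(out, dtype=float, name="cv_isi")


def _windowed_counts(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    intervals: np.ndarray,
    window: float,
) -> np.ndarray:
    """Spike counts in ``window``-ms bins tiling each state interval.

    Returns an (n_neurons, n_windows_total) array; partial windows at
    interval ends are dropped.
    """
    neuron_ids = np.asarray(neuron_ids)
    trains = raster.by_neuron()
    cols = []
    for t0, t1 in intervals:
        n_win = int(np.floor((t1 - t0) / window))
        if n_win < 1:
            continue
        edges = t0 + window * np.arange(n_win + 1)
        block = np.zeros((neuron_ids.size, n_win), dtype=np.int64)
        for row, nid in enumerate(neuron_ids):
            train = trains.get(int(nid))
            if train is not None:
                idx = np.searchsorted(train, edges)
                block[row] = np.diff(idx)
        cols.append(block)
    if not cols:
        return np.zeros((neuron_ids.size, 0), dtype=np.int64)
    return np.concatenate(cols, axis=1)


def fano_factor(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    intervals: np.ndarray,
    window: float = 100.0,
    min_windows: int = 20,
) -> pd.Series:
    """Per-neuron Fano factor (variance/mean of windowed spike counts)
    within state intervals.  Neurons with zero mean count, or with fewer
    than ``min_windows`` qualifying windows, are excluded."""
    counts = _windowed_counts(raster, neuron_ids, intervals, window)
    if counts.shape[1] < min_windows:
        return pd.Series(dtype=float, name="fano")
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    ok = mean > 0
    ids = np.asarray(neuron_ids)[ok]
    return pd.Series(var[ok] / mean[ok], index=ids, name="fano")


def spike_count_correlations(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    intervals: np.ndarray,
    window: float = 100.0,
    n_pairs: int = 1000,
    seed: int | None = None,
    min_windows: int = 20,
) -> np.ndarray:
    """Pairwise Pearson correlations of windowed spike counts.

    ``n_pairs`` distinct unordered pairs are sampled (seeded) from
    ``neuron_ids`` (within-pool excitatory neurons by convention); pairs in
    which either member has zero count variance are excluded.
    """
    neuron_ids = np.asarray(neuron_ids)
    if neuron_ids.size < 2:
        raise ValueError("need at least 2 neurons to form pairs")
    counts = _windowed_counts(raster, neuron_ids, intervals, window)
    if counts.shape[1] < min_windows:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = neuron_ids.size
    max_pairs = n * (n - 1) // 2
    n_pairs = min(n_pairs, max_pairs)
    seen = set()
    while len(seen) < n_pairs:
        draw = rng.integers(0, n, size=2 * (n_pairs - len(seen)) + 8)
        for j in range(0, draw.size - 1, 2):
            a, b = int(draw[j]), int(draw[j + 1])
            if a == b:
                continue
            seen.add((min(a, b), max(a, b)))
            if len(seen) == n_pairs:
                break
    sd = counts.std(axis=1)
    rs = []
    centered = counts - counts.mean(axis=1, keepdims=True)
    for a, b in sorted(seen):
        if sd[a] == 0 or sd[b] == 0:
            continue
        r = (centered[a] @ centered[b]) / (counts.shape[1] * sd[a] * sd[b])
        rs.append(r)
    return np.asarray(rs)


# ---------------------------------------------------------------------------
# Levelt proposition checks
# ---------------------------------------------------------------------------

def levelt_checks(
    symmetric_scan: pd.DataFrame | None = None,
    pool_a_scan: pd.DataFrame | None = None,
    equidominance_base: float | None = None,
) -> dict:
    """Evaluate Levelt-style propositions on drive-scan statistics.

    ``symmetric_scan``: columns ``drive``, ``mean_duration``,
    ``alternation_rate`` (one row per symmetric drive strength); used for
    proposition 4 (mean duration decreases with drive).
    ``pool_a_scan``: columns ``drive_a``, ``predominance_a``,
    ``predominance_b``, ``alternation_rate``; pool B held at
    ``equidominance_base``; used for the classic and modified proposition 2
    and the maximal-alternation-rate check.
    Returns a dict of booleans with effect sizes and descriptive p-values.
    """
    report: dict = {}
    if symmetric_scan is not None:
        if len(symmetric_scan) < 4:
            raise ValueError("symmetric scan needs at least 4 drive points")
        rho, p = sps.spearmanr(
            symmetric_scan["drive"], symmetric_scan["mean_duration"]
        )
        report["levelt4"] = {
            "passed": bool(rho < 0),
            "spearman_rho": float(rho),
            "p_value": float(p),
        }
    if pool_a_scan is not None:
        if len(pool_a_scan) < 4:
            raise ValueError("pool-A scan needs at least 4 drive points")
        if equidominance_base is None:
            raise ValueError("equidominance_base required with pool_a_scan")
        scan = pool_a_scan.sort_values("drive_a").reset_index(drop=True)
        below = scan[scan["drive_a"] < equidominance_base]
        above = scan[scan["drive_a"] > equidominance_base]
        i_eq = int((scan["drive_a"] - equidominance_base).abs().idxmin())
        pred_b_eq = float(scan.loc[i_eq, "predominance_b"])
        pred_a_eq = float(scan.loc[i_eq, "predominance_a"])
        classic = bool(
            len(below) and (below["predominance_b"].mean() > pred_b_eq)
        )
        modified = bool(
            len(above) and (above["predominance_a"].mean() > pred_a_eq)
        )
        report["levelt2_classic"] = {
            "passed": classic,
            "pred_b_below_minus_eq": float(below["predominance_b"].mean() - pred_b_eq)
            if len(below) else np.nan,
        }
        report["levelt2_modified"] = {
            "passed": modified,
            "pred_a_above_minus_eq": float(above["predominance_a"].mean() - pred_a_eq)
            if len(above) else np.nan,
        }
        if "alternation_rate" in scan:
            i_max = int(scan["alternation_rate"].idxmax())
            report["max_alternation_at_equidominance"] = {
                "passed": bool(abs(i_max - i_eq) <= 1),
                "argmax_drive": float(scan.loc[i_max, "drive_a"]),
                "equidominance_drive": float(scan.loc[i_eq, "drive_a"]),
            }
    if not report:
        raise ValueError("no scan provided")
    return report
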