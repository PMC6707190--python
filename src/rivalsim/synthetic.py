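"""Synthetic spike rasters with known ground truth.

These generators produce the same :class:`~rivalsim.raster.SpikeRaster`
objects as the simulator, so the whole measurement pipeline can be validated
against analytically known statistics without running a network: Poisson
trains (CV_ISI = 1, Fano = 1, r_sc = 0), periodic trains (CV_ISI = 0),
gamma-renewal trains, and a two-pool raster that alternates dominance with
epoch durations drawn from a stated distribution (ground truth for the
dominance pipeline).
"""

from __future__ import annotations

import numpy as np

from .raster import SpikeRaster


def _renewal_train(
    rng: np.random.Generator, duration: float, sample_isi
) -> np.ndarray:
    """Spike times on [0, duration) from an ISI sampler (ms)."""
    times = []
    t = sample_isi(rng)
    while t < duration:
        times.append(t)
        t += sample_isi(rng)
    return np.asarray(times)


def poisson_raster(
    n_neurons: int, rate_hz: float, duration: float, seed: int | None = None
) -> SpikeRaster:
    """Independent homogeneous Poisson trains at ``rate_hz`` (duration ms)."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    ids, times = [], []
    if rate_hz > 0:
        mean_isi = 1000.0 / rate_hz
        for nid in range(n_neurons):
            tt = _renewal_train(rng, duration, lambda r: r.exponential(mean_isi))
            ids.append(np.full(tt.size, nid, dtype=np.int64))
            times.append(tt)
    if ids:
        ids = np.concatenate(ids)
        times = np.concatenate(times)
        order = np.argsort(times, kind="stable")
        ids, times = ids[order], times[order]
    else:
        ids, times = np.empty(0, dtype=np.int64), np.empty(0)
    return SpikeRaster(ids=ids, times=times, n_neurons=n_neurons,
                       duration=duration,
                       metadata={"generator": "poisson", "rate_hz": rate_hz,
                                 "seed": seed})


def periodic_raster(
    n_neurons: int, rate_hz: float, duration: float, jitter_phase: bool = True,
    seed: int | None = None,
) -> SpikeRaster:
    """Perfectly regular trains (CV_ISI = 0), with random phase offsets by
    default so the population is not artificially synchronized."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    period = 1000.0 / rate_hz
    ids, times = [], []
    for nid in range(n_neurons):
        phase = rng.uniform(0, period) if jitter_phase else period
        tt = np.arange(phase, duration, period)
        ids.append(np.full(tt.size, nid, dtype=np.int64))
        times.append(tt)
    ids = np.concatenate(ids)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(ids=ids[order], times=times[order], n_neurons=n_neurons,
                       duration=duration,
                       metadata={"generator": "periodic", "rate_hz": rate_hz,
                                 "seed": seed})


def gamma_renewal_raster(
    n_neurons: int, rate_hz: float, shape: float, duration: float,
    seed: int | None = None,
) -> SpikeRaster:
    """Gamma-renewal trains: ISI ~ Gamma(shape, scale) with mean 1000/rate_hz,
    so CV_ISI = 1/sqrt(shape)."""
    if rate_hz <= 0 or shape <= 0:
        raise ValueError("rate and shape must be positive")
    rng = np.random.default_rng(seed)
    scale = 1000.0 / rate_hz / shape
    ids, times = [], []
    for nid in range(n_neurons):
        tt = _renewal_train(rng, duration, lambda r: r.gamma(shape, scale))
        ids.append(np.full(tt.size, nid, dtype=np.int64))
        times.append(tt)
    ids = np.concatenate(ids)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(ids=ids[order], times=times[order], n_neurons=n_neurons,
                       duration=duration,
                       metadata={"generator": "gamma_renewal", "shape": shape,
                                 "rate_hz": rate_hz, "seed": seed})


def alternating_two_pool_raster(
    n_per_pool: int = 20,
    dominant_rate_hz: float = 20.0,
    suppressed_rate_hz: float = 2.0,
    epoch_shape: float = 4.0,
    epoch_mean_ms: float = 2000.0,
    duration: float = 60_000.0,
    seed: int | None = None,
    deterministic_epochs: float | None = None,
) -> tuple[SpikeRaster, list[tuple[int, float, float]]]:
    """Two-pool raster alternating dominance, with known epoch boundaries.

    Epoch durations are gamma(shape=epoch_shape) with mean ``epoch_mean_ms``
    (or constant ``deterministic_epochs`` ms if given).  The dominant pool
    fires Poisson at ``dominant_rate_hz`` per neuron, the suppressed pool at
    ``suppressed_rate_hz``.  Pool A occupies neuron ids [0, n_per_pool), pool
    B the next block.  Returns the raster and the true epoch list as
    ``(label, start, end)`` with label +1 for pool A, -1 for pool B.

    The ground-truth epoch list includes the final, truncated epoch.
    """
    rng = np.random.default_rng(seed)
    # draw epoch boundaries
    epochs = []
    t = 0.0
    lab = 1
    while t < duration:
        if deterministic_epochs is not None:
            d = deterministic_epochs
        else:
            d = rng.gamma(epoch_shape, epoch_mean_ms / epoch_shape)
        end = min(t + d, duration)
        epochs.append((lab, t, end))
        t += d
        lab = -lab
    ids, times = [], []
    pools = {1: np.arange(n_per_pool), -1: np.arange(n_per_pool, 2 * n_per_pool)}
    for lab, t0, t1 in epochs:
        for pool_lab, members in pools.items():
            rate = dominant_rate_hz if pool_lab == lab else suppressed_rate_hz
            if rate <= 0:
                continue
            span = t1 - t0
            for nid in members:
                n_exp = rate * span / 1000.0
                n_spk = rng.poisson(n_exp)
                tt = np.sort(rng.uniform(t0, t1, size=n_spk))
                ids.append(np.full(n_spk, nid, dtype=np.int64))
                times.append(tt)
    ids = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(times) if times else np.empty(0)
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(
        ids=ids[order], times=times[order], n_neurons=2 * n_per_pool,
        duration=duration,
        metadata={
            "generator": "alternating_two_pool",
            "dominant_rate_hz": dominant_rate_hz,
            "suppressed_rate_hz": suppressed_rate_hz,
            "epoch_shape": epoch_shape,
            "epoch_mean_ms": epoch_mean_ms,
            "deterministic_epochs": deterministic_epochs,
            "seed": seed,
        },
    )
    return raster, epochs
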