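"""Leaky integrate-and-fire network with spike-frequency adaptation.

Each neuron i obeys, below threshold,

    dv_i/dt = f_i(t) + s_i(t) - v_i / tau_m - gamma * a_i(t)
    ds_i/dt = -s_i / tau_s + sum_j w_ij * delta(t - t_spike^j)
    da_i/dt = -a_i / tau_a + delta(t - t_spike^i)

with the threshold-subtraction reset v_i -> v_i - theta when v_i reaches
theta.  Integration uses a modified Euler (Heun) step of size ``h`` for the
voltage, exact exponential decay for the linear s and a traces, and linear
interpolation of the spike time within the step that crosses threshold.
Synaptic and adaptation increments from a spike are applied at the end of the
step in which it occurred; by default the synaptic kick is weighted by
``exp(-(t_step_end - t_spike)/tau_s)`` so the interpolated spike time is
honored (``weight_interp=False`` switches to the plain end-of-step kick for
sensitivity checks).

Everything is deterministic given the connectivity, the drive realization and
the seed used for the initial voltages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .architectures import Connectivity
from .drive import DriveSpec
from .params import NeuronParams
from .raster import SpikeRaster


@dataclass
class NetworkState:
    """Dynamical variables of the network at time ``t``."""

    v: np.ndarray  # voltage (mV)
    s: np.ndarray  # synaptic input (mV/ms)
    a: np.ndarray  # adaptation trace
    t: float = 0.0  # ms

    def copy(self) -> "NetworkState":
        return NetworkState(self.v.copy(), self.s.copy(), self.a.copy(), self.t)


def initial_state(
    n_neurons: int, params: NeuronParams, seed: int | None = None
) -> NetworkState:
    """Random initial condition: v uniform on [0, theta), s = a = 0.

    Randomized voltages avoid spurious synchrony at onset; the first stretch
    of simulated time is discarded as burn-in by the statistics layer anyway.
    """
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, params.theta, size=n_neurons)
    return NetworkState(v=v, s=np.zeros(n_neurons), a=np.zeros(n_neurons))


@njit(cache=True)
def _run_kernel(
    v, s, a,
    indptr, indices, weights,
    group, drive_values, drive_is_constant,
    theta, tau_m, tau_s, tau_a, gamma_vec, h,
    start_step, n_steps, weight_interp, use_heun,
):  # pragma: no cover - exercised through simulate()
    """Advance the network ``n_steps`` steps in place.

    Returns (spike_ids, spike_times, n_spikes, bad_neuron); ``bad_neuron``
    is the first neuron whose state went non-finite, or -1.
    """
    n = v.size
    decay_s = np.exp(-h / tau_s)
    decay_a = np.exp(-h / tau_a)
    cap = max(1024, n * 4)
    spike_ids = np.empty(cap, dtype=np.int64)
    spike_times = np.empty(cap, dtype=np.float64)
    n_spikes = 0
    fired = np.empty(n, dtype=np.int64)
    frac = np.empty(n, dtype=np.float64)

    for step in range(n_steps):
        t = (start_step + step) * h
        row0 = 0 if drive_is_constant else start_step + step
        row1 = 0 if drive_is_constant else start_step + step + 1
        n_fired = 0
        for i in range(n):
            g = group[i]
            f0 = drive_values[row0, g] if g >= 0 else 0.0
            f1 = drive_values[row1, g] if g >= 0 else 0.0
            vi = v[i]
            si = s[i]
            ai = a[i]
            s_dec = si * decay_s
            a_dec = ai * decay_a
            gi = gamma_vec[i]
            k1 = f0 + si - vi / tau_m - gi * ai
            if use_heun:
                v_euler = vi + h * k1
                k2 = f1 + s_dec - v_euler / tau_m - gi * a_dec
                v_new = vi + 0.5 * h * (k1 + k2)
            else:
                v_new = vi + h * k1
            if not np.isfinite(v_new):
                return spike_ids[:n_spikes], spike_times[:n_spikes], n_spikes, i
            s[i] = s_dec
            a[i] = a_dec
            if v_new >= theta:
                # linear interpolation of the crossing within the step
                fr = (theta - vi) / (v_new - vi)
                if fr < 0.0:
                    fr = 0.0
                elif fr > 1.0:
                    fr = 1.0
                fired[n_fired] = i
                frac[n_fired] = fr
                n_fired += 1
                # one reset per step; if a synchronous barrage drove v past
                # 2*theta the neuron stays above threshold and fires again on
                # the next step (per-neuron ISIs therefore never fall below h)
                v_new -= theta
            v[i] = v_new
        # end-of-step application of spikes: adaptation and synaptic kicks
        for m in range(n_fired):
            i = fired[m]
            fr = frac[m]
            if n_spikes >= cap:
                cap *= 2
                new_ids = np.empty(cap, dtype=np.int64)
                new_times = np.empty(cap, dtype=np.float64)
                new_ids[:n_spikes] = spike_ids[:n_spikes]
                new_times[:n_spikes] = spike_times[:n_spikes]
                spike_ids = new_ids
                spike_times = new_times
            spike_ids[n_spikes] = i
            spike_times[n_spikes] = t + fr * h
            n_spikes += 1
            a[i] += 1.0
            if weight_interp:
                kick = np.exp(-(1.0 - fr) * h / tau_s)
            else:
                kick = 1.0
            for ptr in range(indptr[i], indptr[i + 1]):
                s[indices[ptr]] += weights[ptr] * kick
    return spike_ids[:n_spikes], spike_times[:n_spikes], n_spikes, -1


def _gamma_vec(params: NeuronParams, conn: Connectivity) -> np.ndarray:
    """Per-neuron adaptation strength; zero on I neurons when adaptation is
    restricted to the excitatory class."""
    if params.adapt_e_only:
        from .architectures import E_CLASS

        return np.where(
            conn.layout.syn_class == E_CLASS, params.gamma, 0.0
        ).astype(np.float64)
    return np.full(conn.n_neurons, params.gamma, dtype=np.float64)


def _drive_arrays(drive: DriveSpec, n_neurons: int):
    if drive.group.size != n_neurons:
        raise ValueError("drive group vector length does not match network size")
    return (
        drive.group.astype(np.int64),
        np.ascontiguousarray(drive.values),
        drive.is_constant,
    )


def step(
    state: NetworkState,
    params: NeuronParams,
    conn: Connectivity,
    drive: DriveSpec,
    weight_interp: bool = True,
    scheme: str = "heun",
) -> tuple[NetworkState, list[tuple[int, float]]]:
    """Advance the network one integration step.

    Returns the new state and the spikes fired in this step as
    ``(neuron index, interpolated spike time)`` pairs.  Thin wrapper over the
    same compiled kernel :func:`simulate` uses, so stepwise and batch
    integration are identical.
    """
    if not (np.all(np.isfinite(state.v)) and np.all(np.isfinite(state.s))
            and np.all(np.isfinite(state.a))):
        bad = int(np.flatnonzero(
            ~(np.isfinite(state.v) & np.isfinite(state.s) & np.isfinite(state.a))
        )[0])
        raise FloatingPointError(f"non-finite state at neuron {bad}")
    new = state.copy()
    indptr, indices, weights = conn.to_csr()
    group, values, is_const = _drive_arrays(drive, conn.n_neurons)
    start_step = int(round(state.t / params.h))
    ids, times, n_spk, bad = _run_kernel(
        new.v, new.s, new.a, indptr, indices, weights,
        group, values, is_const,
        params.theta, params.tau_m, params.tau_s, params.tau_a,
        _gamma_vec(params, conn), params.h,
        start_step, 1, weight_interp, scheme == "heun",
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite state at neuron {bad}")
    new.t = state.t + params.h
    order = np.lexsort((ids[:n_spk], times[:n_spk]))
    return new, [(int(ids[j]), float(times[j])) for j in order]


def simulate(
    conn: Connectivity,
    params: NeuronParams,
    drive: DriveSpec,
    duration: float,
    seed: int | None = None,
    state: NetworkState | None = None,
    weight_interp: bool = True,
    scheme: str = "heun",
    validate: bool = False,
) -> SpikeRaster:
    """Integrate the network for ``duration`` ms and return the spike raster.

    ``seed`` only controls the random initial voltages (the dynamics are
    deterministic; stochastic drive carries its own seed).  Passing ``state``
    overrides the initial condition.
    """
    if duration < 10 * params.tau_m:
        raise ValueError(
            f"duration {duration} ms is shorter than 10*tau_m = {10 * params.tau_m} ms"
        )
    n_steps = int(round(duration / params.h))
    avail = drive.n_steps_available()
    if avail is not None and avail < n_steps:
        raise ValueError(
            f"drive covers {avail} steps but the run needs {n_steps}"
        )
    if state is None:
        state = initial_state(conn.n_neurons, params, seed)
    else:
        state = state.copy()
    indptr, indices, weights = conn.to_csr()
    group, values, is_const = _drive_arrays(drive, conn.n_neurons)
    ids, times, n_spk, bad = _run_kernel(
        state.v, state.s, state.a, indptr, indices, weights,
        group, values, is_const,
        params.theta, params.tau_m, params.tau_s, params.tau_a,
        _gamma_vec(params, conn), params.h,
        0, n_steps, weight_interp, scheme == "heun",
    )
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite or runaway state at neuron {bad} "
            f"(t ~ {times[n_spk - 1] if n_spk else 0.0:.1f} ms)"
        )
    # interpolated spike times within one step arrive in neuron order; sort
    # globally by (time, id) so the raster invariant holds
    order = np.lexsort((ids[:n_spk], times[:n_spk]))
    raster = SpikeRaster(
        ids=ids[order],
        times=times[order],
        n_neurons=conn.n_neurons,
        duration=duration,
        metadata={
            "architecture": conn.kind,
            "architecture_params": conn.params,
            "architecture_seed": conn.seed,
            "drive_kind": drive.kind,
            "drive_params": drive.params,
            "drive_seed": drive.seed,
            "init_seed": seed,
            "neuron": params.to_dict(),
            "weight_interp": weight_interp,
            "scheme": scheme,
        },
    )
    if validate:
        raster.validate()
    return raster
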