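"""Feedforward drive protocols.

Drive is organized by *groups*: disjoint sets of neurons that share a single
time course.  Constant drives store one value per group; Ornstein-Uhlenbeck
(OU) drives store one value per group per integration step, generated with the
exact discretization of the OU process so the stationary mean and SD are
reproduced at any step size.

Units: drive is a current in mV/ms (it enters the voltage equation directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter


@dataclass
class DriveSpec:
    """Per-neuron feedforward drive as a function of time.

    ``group`` assigns each neuron to a drive group (``-1`` = no drive, f=0).
    ``values`` has shape ``(1, n_groups)`` for constant drive or
    ``(n_steps + 1, n_groups)`` for time-varying drive sampled on the
    integration grid (one extra sample so both Heun stages are defined at the
    final step).
    """

    group: np.ndarray
    values: np.ndarray
    kind: str = "constant"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("drive values must be finite")

    @property
    def is_constant(self) -> bool:
        return self.values.shape[0] == 1

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    def n_steps_available(self) -> int | None:
        """Number of integration steps this drive covers (None = unlimited)."""
        if self.is_constant:
            return None
        return self.values.shape[0] - 1

    def at(self, step: int) -> np.ndarray:
        """Group drive values at integration step ``step``."""
        row = 0 if self.is_constant else step
        return self.values[row]


def constant_drive(
    n_neurons: int,
    targets: np.ndarray | list,
    value: float | None = None,
    *,
    groups: list[tuple[np.ndarray, float]] | None = None,
) -> DriveSpec:
    """Nonfluctuating drive: ``value`` on ``targets``, zero elsewhere.

    For several target sets with different values pass
    ``groups=[(indices, value), ...]`` instead (sets must be disjoint).
    """
    group = np.full(n_neurons, -1, dtype=np.int64)
    if groups is None:
        if value is None:
            raise ValueError("value required when groups not given")
        groups = [(np.asarray(targets), float(value))]
    vals = []
    for gid, (idx, v) in enumerate(groups):
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError("empty target set for constant drive")
        if np.any(group[idx] != -1):
            raise ValueError("drive target sets must be disjoint")
        if not np.isfinite(v):
            raise ValueError("drive value must be finite")
        group[idx] = gid
        vals.append(float(v))
    return DriveSpec(
        group=group,
        values=np.array([vals]),
        kind="constant",
        params={"values": vals},
    )


def ou_path(
    mu: float, sigma: float, tau: float, n_steps: int, h: float,
    rng: np.random.Generator, x0: float | None = None,
) -> np.ndarray:
    """Exact discrete-time OU sample path of length ``n_steps + 1``::

        x[t+h] = mu + (x[t] - mu) * a + sigma * sqrt(1 - a^2) * xi,   a = exp(-h/tau)

    Stationary mean ``mu`` and stationary SD ``sigma``; started from the
    stationary distribution unless ``x0`` is given.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    a = np.exp(-h / tau)
    noise_sd = sigma * np.sqrt(1.0 - a * a)
    x = np.empty(n_steps + 1)
    x[0] = mu + sigma * rng.standard_normal() if x0 is None else x0
    xi = rng.standard_normal(n_steps)
    # first-order linear recursion dev[t+1] = a*dev[t] + noise_sd*xi[t],
    # evaluated as an IIR filter
    dev = lfilter([noise_sd], [1.0, -a], xi, zi=[a * (x[0] - mu)])[0]
    x[1:] = mu + dev
    return x


def ou_drive(
    n_neurons: int,
    groups: list[tuple[np.ndarray, float]],
    sigma: float,
    tau: float,
    duration: float,
    h: float,
    seed: int | None = None,
    clip_at_zero: bool = False,
) -> DriveSpec:
    """OU drive: one independent process per target group.

    ``groups`` is ``[(indices, mean), ...]``; all listed neurons in one group
    share the group's single process.  ``sigma`` is the stationary SD.
    Negative excursions are kept by default (``clip_at_zero=True`` rectifies,
    for sensitivity analyses only).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / h))
    group = np.full(n_neurons, -1, dtype=np.int64)
    paths = []
    for gid, (idx, mu) in enumerate(groups):
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError("empty target set for OU drive")
        if np.any(group[idx] != -1):
            raise ValueError("drive target sets must be disjoint")
        group[idx] = gid
        paths.append(ou_path(mu, sigma, tau, n_steps, h, rng))
    values = np.column_stack(paths)
    if clip_at_zero:
        values = np.maximum(values, 0.0)
    return DriveSpec(
        group=group,
        values=values,
        kind="ou",
        params={
            "means": [float(m) for _, m in groups],
            "sigma": sigma,
            "tau": tau,
            "h": h,
            "clip_at_zero": clip_at_zero,
        },
        seed=seed,
    )


def levelt_scan(
    n_neurons: int,
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    base: float,
    grid: np.ndarray | list,
    axis: str = "symmetric",
) -> list[DriveSpec]:
    """Sequence of constant drives for Levelt-style experiments.

    ``axis='symmetric'`` drives both pools at each grid value;
    ``axis='pool_a_only'`` varies pool A while pool B stays at ``base``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("drive grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("drive grid values must be non-negative")
    specs = []
    for g in grid:
        if axis == "symmetric":
            spec = constant_drive(
                n_neurons, None, groups=[(pool_a, g), (pool_b, g)]
            )
        elif axis == "pool_a_only":
            spec = constant_drive(
                n_neurons, None, groups=[(pool_a, g), (pool_b, base)]
            )
        else:
            raise ValueError(f"unknown scan axis {axis!r}")
        spec.params["scan_value"] = float(g)
        specs.append(spec)
    return specs
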