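"""Balanced-state mean-field theory for the mutual-inhibition circuit.

In the large, strongly coupled limit the attractor of an E/I network is a
*balanced state*: the mean input to every population sits at spiking
threshold, and the population rates r solve the linear system

    W r + f = 0

where W is the matrix of effective population coupling weights (signed: E
columns non-negative, I columns non-positive) and f is the external drive
vector.  For the two-pool discrete architecture the population order is
(e1, i1, e2, i2) and the only cross-pool entries are the excitatory-to-
inhibitory long-range couplings, so W has the sparsity

    [ w_ee  -w_ei    0      0   ]
    [ w_ie  -w_ii   w_L     0   ]
    [  0      0    w_ee   -w_ei ]
    [ w_L     0    w_ie   -w_ii ]

A unique balanced solution exists iff f lies in the column space of W; a
symmetrically coupled network therefore admits no balanced state under
asymmetric drive.  As the mutual-inhibition weight w_L grows, det(W) crosses
zero: the singularity anticipates the transition from the symmetric
(normalization) regime to the asymmetric winner-take-all regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import Connectivity, DISCRETE, UNSTRUCTURED, E_CLASS, I_CLASS
from .drive import DriveSpec
from .params import NeuronParams

#: population order of the two-pool system
POPULATIONS = ("e1", "i1", "e2", "i2")

#: relative tolerance on |det W| / ||W||^n below which W is declared singular
SINGULAR_RTOL = 1e-12


@dataclass
class MeanFieldSystem:
    """Linear balanced-state system ``W r + f = 0``.

    ``W`` is 4x4 (two pools) or 2x2 (single pool); ``f`` the drive vector in
    mV/ms.  Rates are in spikes/ms so that ``W r`` is in mV/ms.
    """

    W: np.ndarray
    f: np.ndarray
    populations: tuple = POPULATIONS
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.f = np.asarray(self.f, dtype=float).ravel()
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.f.size != self.W.shape[0]:
            raise ValueError("f length must match W")

    def pool_block(self, pool: int) -> "MeanFieldSystem":
        """The 2x2 within-pool subsystem (couplings to the other pool
        removed), i.e. the classic single-pool balanced-state system."""
        if self.W.shape[0] != 4:
            raise ValueError("pool_block requires the 4-population system")
        sl = slice(0, 2) if pool == 0 else slice(2, 4)
        return MeanFieldSystem(
            W=self.W[sl, sl].copy(),
            f=self.f[sl].copy(),
            populations=self.populations[sl],
            params=dict(self.params),
        )


@dataclass
class BalancedSolution:
    """Solution of the balanced-state condition.

    ``rates`` are in spikes/ms (`rates_hz` converts); ``feasible`` requires
    an exact solution with all rates non-negative.  Infeasibility carries a
    ``reason``: "singular" (f outside the column space of a rank-deficient
    W), "negative_rate", or "" when feasible.
    """

    rates: np.ndarray
    feasible: bool
    singular: bool
    residual: float
    reason: str = ""

    @property
    def rates_hz(self) -> np.ndarray:
        return self.rates * 1000.0


def effective_weight(amplitude: float, k: int, params: NeuronParams) -> float:
    """Population coupling weight from microscopic parameters.

    Each neuron receives ``k`` synapses of amplitude ``A/sqrt(k)``; one
    presynaptic spike contributes a synaptic-current integral of
    ``w * tau_s``, so at population rate r (spikes/ms) the mean input is
    ``sqrt(k) * A * tau_s * r``.
    """
    return np.sqrt(k) * amplitude * params.tau_s


def meanfield_from_architecture(
    conn: Connectivity,
    drive: DriveSpec,
    params: NeuronParams | None = None,
) -> MeanFieldSystem:
    """Build the balanced-state system for a discrete or unstructured
    architecture.  Drive entries are the per-population mean drives."""
    if params is None:
        params = NeuronParams()
    if conn.kind not in (DISCRETE, UNSTRUCTURED):
        raise ValueError(
            f"mean-field mapping not defined for architecture {conn.kind!r}"
        )
    k = conn.params["k"]
    a = conn.params
    w_ee = effective_weight(a["A_ee"], k, params)
    w_ei = effective_weight(a["A_ei"], k, params)
    w_ie = effective_weight(a["A_ie"], k, params)
    w_ii = effective_weight(a["A_ii"], k, params)

    def pop_drive(selector) -> float:
        idx = selector
        g = drive.group[idx]
        vals = drive.values.mean(axis=0)
        out = np.where(g >= 0, vals[np.maximum(g, 0)], 0.0)
        return float(out.mean())

    lay = conn.layout
    if conn.kind == UNSTRUCTURED:
        f = np.array([pop_drive(lay.e_idx), pop_drive(lay.i_idx)])
        W = np.array([[w_ee, -w_ei], [w_ie, -w_ii]])
        return MeanFieldSystem(W=W, f=f, populations=("e", "i"),
                               params={"k": k, **{x: a[x] for x in
                                       ("A_ee", "A_ei", "A_ie", "A_ii")}})
    w_long = effective_weight(a["A_ie_long"], k, params)
    f = np.array([
        pop_drive(lay.pool_e_idx(0)),
        pop_drive(np.flatnonzero((lay.pool == 0) & (lay.syn_class == I_CLASS))),
        pop_drive(lay.pool_e_idx(1)),
        pop_drive(np.flatnonzero((lay.pool == 1) & (lay.syn_class == I_CLASS))),
    ])
    W = two_pool_matrix(w_ee, w_ei, w_ie, w_ii, w_long)
    return MeanFieldSystem(W=W, f=f, params={"k": k, **{x: a[x] for x in
                           ("A_ee", "A_ei", "A_ie", "A_ii", "A_ie_long")}})


def two_pool_matrix(
    w_ee: float, w_ei: float, w_ie: float, w_ii: float, w_long: float
) -> np.ndarray:
    """4x4 coupling matrix of the two-pool mutual-inhibition system."""
    return np.array([
        [w_ee, -w_ei, 0.0, 0.0],
        [w_ie, -w_ii, w_long, 0.0],
        [0.0, 0.0, w_ee, -w_ei],
        [w_long, 0.0, w_ie, -w_ii],
    ])


def solve_balanced(system: MeanFieldSystem, atol: float = 1e-9) -> BalancedSolution:
    """Solve ``W r = -f``; all pathologies are reported states.

    A rank-deficient W is handled by a least-squares projection: if the
    projection residual exceeds tolerance, f is outside the column space and
    no balanced state exists.  Negative rate components mark the solution
    infeasible (the balanced state would require a negative rate, which the
    network resolves by pinning that population at zero instead).
    """
    W, f = system.W, system.f
    n = W.shape[0]
    norm = np.linalg.norm(W)
    singular = False
    if norm == 0:
        singular = True
    else:
        det = np.linalg.det(W)
        singular = abs(det) / norm**n < SINGULAR_RTOL
    if singular:
        rates, res, rank, _ = np.linalg.lstsq(W, -f, rcond=None)
        residual = float(np.linalg.norm(W @ rates + f))
        scale = max(np.linalg.norm(f), 1.0)
        if residual > atol * scale:
            return BalancedSolution(
                rates=np.full(n, np.nan), feasible=False, singular=True,
                residual=residual, reason="singular",
            )
    else:
        rates = np.linalg.solve(W, -f)
        residual = float(np.linalg.norm(W @ rates + f))
    if np.any(rates < 0):
        return BalancedSolution(rates=rates, feasible=False, singular=singular,
                                residual=residual, reason="negative_rate")
    return BalancedSolution(rates=rates, feasible=True, singular=singular,
                            residual=residual)


def solve_single_pool(system: MeanFieldSystem, pool: int = 0) -> BalancedSolution:
    """Classic single-pool balanced state: the within-pool 2x2 block solved
    in isolation (mutual-inhibition input ignored)."""
    sub = system.pool_block(pool) if system.W.shape[0] == 4 else system
    return solve_balanced(sub)


def sweep_mutual_inhibition(
    base: MeanFieldSystem, w_long_grid: np.ndarray
) -> tuple[pd.DataFrame, float | None]:
    """Solve the two-pool system along a grid of mutual-inhibition weights.

    Returns a tidy frame (one row per grid value, solution and flags) and
    the singular point located by bisection on det(W), or None when det does
    not change sign in the grid range.
    """
    grid = np.asarray(w_long_grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("w_long grid must be increasing with >= 2 points")
    if base.W.shape[0] != 4:
        raise ValueError("sweep requires the 4-population system")
    w_ee, w_ei = base.W[0, 0], -base.W[0, 1]
    w_ie, w_ii = base.W[1, 0], -base.W[1, 1]

    def system_at(w_long: float) -> MeanFieldSystem:
        return MeanFieldSystem(
            W=two_pool_matrix(w_ee, w_ei, w_ie, w_ii, w_long),
            f=base.f.copy(), params=dict(base.params),
        )

    rows = []
    for w in grid:
        sol = solve_balanced(system_at(w))
        rows.append({
            "w_long": w, "feasible": sol.feasible, "singular": sol.singular,
            "reason": sol.reason,
            **{f"r_{p}_hz": r for p, r in zip(base.populations, sol.rates_hz)},
        })
    frame = pd.DataFrame(rows)

    def det_at(w: float) -> float:
        return float(np.linalg.det(system_at(w).W))

    dets = np.array([det_at(w) for w in grid])
    sign_change = np.flatnonzero(np.sign(dets[:-1]) * np.sign(dets[1:]) < 0)
    singular_point = None
    if sign_change.size:
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if det_at(lo) * det_at(mid) <= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-12 * max(1.0, abs(hi)):
                break
        singular_point = 0.5 * (lo + hi)
    return frame, singular_point


def compare_theory_simulation(
    solutions: pd.DataFrame,
    simulated: pd.DataFrame,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Join theory solutions with simulated population rates on the w_long
    grid and report per-population relative errors and regime labels.

    ``simulated`` needs columns ``w_long`` and ``r_<pop>_hz`` matching the
    theory frame.  A single global scale factor between theory and
    simulation is fit once on the symmetric branch (least squares over all
    populations of symmetric-regime points) and then frozen; all comparisons
    are therefore of curve shape and regime boundaries, not absolute rates.
    Regimes are labelled from the simulated pool asymmetry.
    """
    pops = [c[2:-3] for c in solutions.columns if c.startswith("r_") and c.endswith("_hz")]
    merged = solutions.merge(simulated, on="w_long", suffixes=("_th", "_sim"))
    if len(merged) != len(solutions) or len(merged) != len(simulated):
        raise ValueError("theory and simulation grids do not match")
    e_cols = [p for p in pops if p.startswith("e")]
    asym = np.abs(
        merged[f"r_{e_cols[0]}_hz_sim"] - merged[f"r_{e_cols[-1]}_hz_sim"]
    ) / (merged[f"r_{e_cols[0]}_hz_sim"] + merged[f"r_{e_cols[-1]}_hz_sim"]).clip(lower=1e-12)
    merged["regime"] = np.where(asym > 1 / 3, "asymmetric", "symmetric")
    scale = 1.0
    if calibrate:
        sym = merged[(merged["regime"] == "symmetric") & merged["feasible"]]
        th = np.concatenate([sym[f"r_{p}_hz_th"].to_numpy() for p in pops])
        si = np.concatenate([sym[f"r_{p}_hz_sim"].to_numpy() for p in pops])
        ok = np.isfinite(th) & np.isfinite(si) & (th > 0)
        if ok.sum() >= 2:
            scale = float(np.sum(th[ok] * si[ok]) / np.sum(th[ok] ** 2))
    merged["calibration"] = scale
    for p in pops:
        th = merged[f"r_{p}_hz_th"] * scale
        si = merged[f"r_{p}_hz_sim"]
        merged[f"rel_err_{p}"] = (th - si).abs() / si.clip(lower=1e-12)
    return merged
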