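"""Connectivity construction for the three network architectures.

Three randomly connected circuits are supported:

* **unstructured** — one population of N neurons split evenly between
  excitatory (E) and inhibitory (I) classes; every neuron receives exactly
  ``k`` in-synapses from each afferent class, with class-pair amplitudes
  ``A_xy / sqrt(k)``.
* **discrete mutual inhibition** — two unstructured pools; additionally every
  I neuron receives exactly ``k`` long-range excitatory in-synapses from the
  opposite pool (amplitude ``A_ie_long / sqrt(k)``).  This is the minimal
  two-percept rivalry circuit.
* **continuum** — 80% E / 20% I neurons arranged evenly on a ring, connected
  independently with probability ``p`` and a von Mises weight profile peaked
  at zero angular distance.

Weights are signed by the presynaptic class: afferents of E neurons are
positive, afferents of I neurons negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

E_CLASS = 0
I_CLASS = 1

UNSTRUCTURED = "unstructured"
DISCRETE = "discrete_mutual_inhibition"
CONTINUUM = "continuum"

#: Case-example synaptic amplitudes (divided by sqrt(k) when wiring).
UNSTRUCTURED_AMPLITUDES = {"A_ee": 12.5, "A_ie": 20.0, "A_ei": 50.0, "A_ii": 50.0}
DISCRETE_AMPLITUDES = {
    "A_ee": 10.5,
    "A_ei": 20.0,
    "A_ie": 30.0,
    "A_ie_long": 30.0,
    "A_ii": 45.0,
}
#: Case-example continuum parameters. The second concentration printed for the
#: E->E class in the source parameter list is read as the I->I concentration
#: (kappa_ii), the one class otherwise missing; it is an explicit config key.
CONTINUUM_PARAMS = {
    "A_ee": 84.0,
    "A_ei": 314.0,
    "A_ie": 1319.0,
    "A_ii": 689.0,
    "kappa_ee": 0.26,
    "kappa_ei": 0.93,
    "kappa_ie": 0.97,
    "kappa_ii": 0.5,
    "p": 0.34,
}


@dataclass
class PopulationLayout:
    """Per-neuron labels: synaptic class, pool membership, ring angle."""

    n_total: int
    syn_class: np.ndarray  # 0 = E, 1 = I
    pool: np.ndarray  # 0, 1, or -1 (no pool structure)
    angle: np.ndarray | None = None  # ring position in radians (continuum)

    @property
    def e_idx(self) -> np.ndarray:
        return np.flatnonzero(self.syn_class == E_CLASS)

    @property
    def i_idx(self) -> np.ndarray:
        return np.flatnonzero(self.syn_class == I_CLASS)

    def pool_e_idx(self, pool: int) -> np.ndarray:
        return np.flatnonzero((self.syn_class == E_CLASS) & (self.pool == pool))


@dataclass
class Connectivity:
    """Sparse signed synaptic structure plus neuron labels.

    ``pre``, ``post``, ``weight`` are parallel arrays of synapses (one row per
    ordered pair; duplicate pairs never occur).  ``params`` records the
    generation parameters for provenance.
    """

    layout: PopulationLayout
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.layout.n_total

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def in_degree(self, from_class: int | None = None) -> np.ndarray:
        """In-degree per neuron, optionally counting one afferent class."""
        mask = np.ones(self.pre.size, dtype=bool)
        if from_class is not None:
            mask = self.layout.syn_class[self.pre] == from_class
        return np.bincount(self.post[mask], minlength=self.n_neurons)

    def to_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Outgoing adjacency in CSR form (indptr by presynaptic neuron)."""
        order = np.argsort(self.pre, kind="stable")
        indices = self.post[order].astype(np.int64)
        data = self.weight[order].astype(np.float64)
        counts = np.bincount(self.pre, minlength=self.n_neurons)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return indptr, indices, data

    def save(self, path) -> None:
        """Write the synapse triplet table (pre, post, weight) as TSV, plus a
        label table (class, pool, angle) and a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savetxt(path, np.column_stack([self.pre, self.post, self.weight]),
                   fmt=("%d", "%d", "%.12g"), delimiter="\t",
                   header="pre\tpost\tweight", comments="")
        lay = self.layout
        angle = lay.angle if lay.angle is not None else np.full(lay.n_total, np.nan)
        np.savetxt(path.with_suffix(path.suffix + ".labels"),
                   np.column_stack([lay.syn_class, lay.pool, angle]),
                   fmt=("%d", "%d", "%.12g"), delimiter="\t",
                   header="syn_class\tpool\tangle", comments="")
        meta = {"kind": self.kind, "seed": self.seed, "n": lay.n_total,
                "params": {k: (float(v) if isinstance(v, (int, float, np.floating))
                               else v) for k, v in self.params.items()}}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "Connectivity":
        import json
        from pathlib import Path

        path = Path(path)
        trip = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        labels = np.loadtxt(path.with_suffix(path.suffix + ".labels"),
                            delimiter="\t", skiprows=1, ndmin=2)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        angle = labels[:, 2]
        layout = PopulationLayout(
            n_total=int(meta["n"]),
            syn_class=labels[:, 0].astype(np.int8),
            pool=labels[:, 1].astype(np.int8),
            angle=None if np.all(np.isnan(angle)) else angle,
        )
        if trip.size == 0:
            pre = post = np.empty(0, dtype=np.int64)
            weight = np.empty(0)
        else:
            pre = trip[:, 0].astype(np.int64)
            post = trip[:, 1].astype(np.int64)
            weight = trip[:, 2]
        return cls(layout=layout, pre=pre, post=post, weight=weight,
                   kind=meta["kind"], params=meta.get("params", {}),
                   seed=meta.get("seed"))


def _sample_in_synapses(
    rng: np.random.Generator,
    pool_pre: np.ndarray,
    targets: np.ndarray,
    k: int,
    in_degree: str = "binomial",
) -> tuple[np.ndarray, np.ndarray]:
    """Random wiring with mean in-degree ``k`` per target from ``pool_pre``.

    ``in_degree="binomial"`` (default) connects each ordered pair
    independently with probability ``k / n_pre``, so in-degrees are
    Binomial(n_pre, k/n_pre); the resulting quenched heterogeneity across
    neurons desynchronizes the population, which is essential for the
    asynchronous irregular regime.  ``in_degree="fixed"`` draws exactly
    ``k`` distinct partners per target (a zero-variance in-degree, kept for
    sensitivity checks).  Self-connections never occur.
    """
    if k >= pool_pre.size:
        raise ValueError(
            f"in-degree k={k} must be smaller than the afferent class size "
            f"{pool_pre.size}"
        )
    if in_degree == "fixed":
        pres = np.empty((targets.size, k), dtype=np.int64)
        for row, tgt in enumerate(targets):
            candidates = pool_pre[pool_pre != tgt]
            pres[row] = rng.choice(candidates, size=k, replace=False)
        return pres.ravel(), np.repeat(targets, k)
    if in_degree != "binomial":
        raise ValueError(f"unknown in-degree distribution {in_degree!r}")
    p = k / pool_pre.size
    mask = rng.random((targets.size, pool_pre.size)) < p
    # remove self-connections where the target is in the afferent pool
    pos = np.searchsorted(pool_pre, targets)
    rows = np.flatnonzero(
        (pos < pool_pre.size) & (pool_pre[np.minimum(pos, pool_pre.size - 1)] == targets)
    )
    mask[rows, pos[rows]] = False
    r, c = np.nonzero(mask)
    return pool_pre[c], targets[r]


def _signed_amplitude(a: float, pre_class: int) -> float:
    return a if pre_class == E_CLASS else -a


def build_unstructured(
    n: int = 4000,
    k: int = 600,
    amplitudes: dict | None = None,
    seed: int | None = None,
    in_degree: str = "binomial",
) -> Connectivity:
    """Unstructured random network: N/2 E and N/2 I neurons, mean in-degree
    ``k`` from each afferent class, weights ``±A_xy/sqrt(k)``."""
    if amplitudes is None:
        amplitudes = UNSTRUCTURED_AMPLITUDES
    if n % 2:
        raise ValueError("n must be even (E and I evenly split)")
    rng = np.random.default_rng(seed)
    syn_class = np.zeros(n, dtype=np.int8)
    syn_class[n // 2 :] = I_CLASS
    layout = PopulationLayout(
        n_total=n, syn_class=syn_class, pool=np.full(n, -1, dtype=np.int8)
    )
    pre, post, weight = _wire_pool(
        rng, layout, np.arange(n), k, amplitudes, in_degree
    )
    return Connectivity(
        layout=layout,
        pre=pre,
        post=post,
        weight=weight,
        kind=UNSTRUCTURED,
        params={"n": n, "k": k, "in_degree": in_degree, **amplitudes},
        seed=seed,
    )


def _wire_pool(rng, layout, members, k, amplitudes, in_degree):
    """Within-pool wiring shared by the unstructured and discrete builders."""
    e_members = members[layout.syn_class[members] == E_CLASS]
    i_members = members[layout.syn_class[members] == I_CLASS]
    sqrt_k = np.sqrt(k)
    pres, posts, weights = [], [], []
    # (afferent pool, target set, amplitude key, sign class)
    wiring = [
        (e_members, e_members, "A_ee", E_CLASS),
        (i_members, e_members, "A_ei", I_CLASS),
        (e_members, i_members, "A_ie", E_CLASS),
        (i_members, i_members, "A_ii", I_CLASS),
    ]
    for pool_pre, targets, key, pre_class in wiring:
        p, q = _sample_in_synapses(rng, pool_pre, targets, k, in_degree)
        w = np.full(p.size, _signed_amplitude(amplitudes[key] / sqrt_k, pre_class))
        pres.append(p)
        posts.append(q)
        weights.append(w)
    return (
        np.concatenate(pres),
        np.concatenate(posts),
        np.concatenate(weights),
    )


def build_discrete_mutual_inhibition(
    n: int = 4000,
    k: int = 200,
    amplitudes: dict | None = None,
    seed: int | None = None,
    in_degree: str = "binomial",
) -> Connectivity:
    """Two unstructured pools of n/2 neurons each (in-degree ``k`` per class
    within the pool); every I neuron additionally receives exactly ``k``
    long-range excitatory in-synapses from the opposite pool with amplitude
    ``A_ie_long/sqrt(k)``."""
    if amplitudes is None:
        amplitudes = DISCRETE_AMPLITUDES
    if n % 4:
        raise ValueError("n must be divisible by 4 (two pools, E/I split)")
    rng = np.random.default_rng(seed)
    half = n // 2
    quarter = n // 4
    syn_class = np.zeros(n, dtype=np.int8)
    pool = np.zeros(n, dtype=np.int8)
    # layout: [pool0 E, pool1 E, pool0 I, pool1 I] so that excitatory neurons
    # occupy a contiguous index block per pool (convenient for rasters)
    syn_class[half:] = I_CLASS
    pool[quarter:half] = 1
    pool[half + quarter :] = 1
    layout = PopulationLayout(n_total=n, syn_class=syn_class, pool=pool)

    pres, posts, weights = [], [], []
    for pid in (0, 1):
        members = np.flatnonzero(pool == pid)
        p, q, w = _wire_pool(rng, layout, members, k, amplitudes, in_degree)
        pres.append(p)
        posts.append(q)
        weights.append(w)
    # long-range mutual inhibition pathway: opposite-pool E -> I
    a_long = amplitudes["A_ie_long"] / np.sqrt(k)
    if a_long != 0:
        for pid in (0, 1):
            e_other = layout.pool_e_idx(1 - pid)
            i_members = np.flatnonzero(
                (layout.pool == pid) & (layout.syn_class == I_CLASS)
            )
            p, q = _sample_in_synapses(rng, e_other, i_members, k, in_degree)
            pres.append(p)
            posts.append(q)
            weights.append(np.full(p.size, a_long))
    return Connectivity(
        layout=layout,
        pre=np.concatenate(pres),
        post=np.concatenate(posts),
        weight=np.concatenate(weights),
        kind=DISCRETE,
        params={"n": n, "k": k, "in_degree": in_degree, **amplitudes},
        seed=seed,
    )


def von_mises_weight(
    theta_i: np.ndarray | float,
    theta_j: np.ndarray | float,
    amplitude: float,
    kappa: float,
    p: float,
    n_post: int,
) -> np.ndarray | float:
    """Von Mises synaptic footprint::

        w_ij = A * exp(kappa * cos(theta_i - theta_j)) / (p * N * 2*pi * I0(kappa))

    Positive, 2*pi-periodic in the angular distance and maximal at
    ``theta_i == theta_j``.  ``n_post`` is the postsynaptic class size; with
    connection probability ``p`` the expected summed weight from one
    presynaptic neuron onto a class is ``A / (2*pi)`` independent of kappa
    (the von Mises density integrates to one).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if n_post <= 0:
        raise ValueError("n_post must be positive")
    return (
        amplitude
        * np.exp(kappa * np.cos(np.asarray(theta_i) - np.asarray(theta_j)))
        / (p * n_post * 2 * np.pi * i0(kappa))
    )


def build_continuum(
    n: int = 4000,
    params: dict | None = None,
    seed: int | None = None,
) -> Connectivity:
    """Ring network: 80% E / 20% I neurons placed evenly on [0, 2*pi), each
    ordered pair connected independently with probability ``p``, weight from
    :func:`von_mises_weight` with the class-pair amplitude and concentration
    (I afferents negated)."""
    if params is None:
        params = CONTINUUM_PARAMS
    required = {"A_ee", "A_ei", "A_ie", "A_ii", "kappa_ee", "kappa_ei",
                "kappa_ie", "kappa_ii", "p"}
    missing = required - params.keys()
    if missing:
        raise ValueError(f"continuum parameters missing: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n_e = int(round(0.8 * n))
    n_i = n - n_e
    syn_class = np.concatenate(
        [np.zeros(n_e, dtype=np.int8), np.ones(n_i, dtype=np.int8)]
    )
    # evenly spaced per class; only angle differences matter
    angle = np.concatenate(
        [2 * np.pi * np.arange(n_e) / n_e, 2 * np.pi * np.arange(n_i) / n_i]
    )
    layout = PopulationLayout(
        n_total=n, syn_class=syn_class, pool=np.full(n, -1, dtype=np.int8),
        angle=angle,
    )
    p = params["p"]
    class_sizes = {E_CLASS: n_e, I_CLASS: n_i}
    class_idx = {E_CLASS: np.arange(n_e), I_CLASS: np.arange(n_e, n)}
    pres, posts, weights = [], [], []
    spec = {
        (E_CLASS, E_CLASS): ("A_ee", "kappa_ee"),
        (E_CLASS, I_CLASS): ("A_ei", "kappa_ei"),
        (I_CLASS, E_CLASS): ("A_ie", "kappa_ie"),
        (I_CLASS, I_CLASS): ("A_ii", "kappa_ii"),
    }
    for (post_cls, pre_cls), (a_key, k_key) in spec.items():
        tgt = class_idx[post_cls]
        src = class_idx[pre_cls]
        mask = rng.random((tgt.size, src.size)) < p
        if post_cls == pre_cls:
            np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
        w = von_mises_weight(
            angle[tgt[rows]], angle[src[cols]],
            params[a_key], params[k_key], p, class_sizes[post_cls],
        )
        if pre_cls == I_CLASS:
            w = -w
        pres.append(src[cols])
        posts.append(tgt[rows])
        weights.append(w)
    return Connectivity(
        layout=layout,
        pre=np.concatenate(pres).astype(np.int64),
        post=np.concatenate(posts).astype(np.int64),
        weight=np.concatenate(weights),
        kind=CONTINUUM,
        params={"n": n, **params},
        seed=seed,
    )
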