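# rivalsim

Deterministic spiking-network simulation of perceptual rivalry.

During rivalry (binocular rivalry, Necker cube, and kin) perception
alternates every few seconds under a constant ambiguous stimulus, with
dominance durations that follow a gamma-like distribution (coefficient of
variation 0.4–0.8), while the underlying cortical neurons fire irregularly
and asynchronously (CV of interspike intervals near 1, spike-count
correlations near zero, Fano factors near 1). `rivalsim` implements a single
biophysical circuit model that produces both scales of variability at once
with **no injected noise**: leaky integrate-and-fire neurons with
spike-frequency adaptation, wired into mutual-inhibition architectures whose
chaotic balanced-state dynamics supply the stochasticity of the perceptual
alternations.

The package is aimed at computational neuroscientists who want to simulate
these circuits, reproduce the dominance-duration and spiking-variability
phenomenology, test Levelt's propositions in silico, or extend the
architecture space.

## Model

Each neuron obeys

    dv_i/dt = f_i(t) + s_i(t) − v_i/τ_m − γ a_i(t)        v_i < θ
    v_i → v_i − θ                                          at threshold
    ds_i/dt = −s_i/τ_s + Σ_j w_ij δ(t − t_spike^j)
    da_i/dt = −a_i/τ_a + δ(t − t_spike^i)

with θ = 20 mV, τ_m = 20 ms, τ_s = 2 ms; spike-frequency adaptation
(strength γ, time constant τ_a) acts on excitatory neurons and is the fatigue
mechanism that terminates dominance epochs. Integration uses a modified Euler
step (h = 0.1 ms) with linearly interpolated spike times.

Three architectures (4000 neurons each):

* **unstructured** — one balanced E/I network, random wiring with mean
  in-degree k = 600 per afferent class, weights ±A_xy/√k;
* **discrete mutual inhibition** — two such pools (k = 200) coupled *only*
  by long-range excitatory→inhibitory projections: the minimal two-percept
  rivalry circuit;
* **continuum** — an 80% E / 20% I ring with von Mises connectivity
  footprints, w_ij = A·exp(κ·cos(θ_i−θ_j)) / (p·N·2π·I₀(κ)).

Percepts are read out by pooling excitatory spike counts u_A, u_B in 50 ms
windows into the percept state variable P = (u_A−u_B)/(u_A+u_B), classifying
each window (A if P > 1/3, B if P < −1/3, else neither), and filtering with a
report threshold (default 300 ms). The statistics battery measures dominance
durations (gamma fits, CV_D, skewness), per-state CV_ISI, Fano factors and
pairwise spike-count correlations, and checks Levelt's propositions on drive
scans.

The mean-field layer solves the balanced-state condition **W r + f = 0** for
the two-pool (four-population) and classic single-pool systems, locates the
determinant singularity that anticipates the transition from the symmetric
(normalization) regime to winner-take-all, and compares predicted with
simulated rates.

## Worked example

Simulate the discrete mutual-inhibition case example (symmetric drive
5 mV/ms to all excitatory neurons) for two minutes of biological time and
print the constraint report:

```
rivalsim run --preset discrete_case_example --duration 122000 --seed 1 \
             --out out_discrete
```

or in Python:

```python
import rivalsim as rs
from rivalsim.experiments import analyze_raster

conn  = rs.build_discrete_mutual_inhibition(seed=11)      # 4000 neurons
drive = rs.constant_drive(conn.n_neurons, conn.layout.e_idx, 5.0)
raster = rs.simulate(conn, rs.DISCRETE_NEURON, drive, 122_000.0, seed=12)
pool_a, pool_b = conn.layout.pool_e_idx(0), conn.layout.pool_e_idx(1)
res = analyze_raster(raster, pool_a, pool_b, burn_in_ms=2000.0, pair_seed=13)
print(f"epochs: {res['n_epochs']}, mean duration: {res['mean_duration_ms']:.0f} ms")
print(f"CV_ISI dominant/suppressed: {res['cv_isi_dominant']:.2f} / "
      f"{res['cv_isi_suppressed']:.2f}")
print(f"r_sc dominant/suppressed: {res['r_sc_dominant']:.3f} / "
      f"{res['r_sc_suppressed']:.3f}")
print(f"Fano (dominant): {res['fano_dominant']:.2f}")
print(f"rates dominant/suppressed (Hz): {res['rate_dominant_hz']:.1f} / "
      f"{res['rate_suppressed_hz']:.2f}")
```

Output from this exact call:

```
epochs: 113, mean duration: 1047 ms
CV_ISI dominant/suppressed: 1.17 / 1.19
r_sc dominant/suppressed: 0.033 / 0.103
Fano (dominant): 1.36
rates dominant/suppressed (Hz): 17.5 / 0.17
```

The network alternates spontaneously on the ~1 s scale although the input is
constant; dominant-pool excitatory neurons fire at ~17 Hz, irregularly
(CV_ISI > 1) and asynchronously (r_sc near zero, Fano near one), and the
suppressed pool stays below 1 Hz yet also spikes irregularly — it is driven
by the fluctuating output of the dominant pool.

Other entry points:

```
rivalsim scan   --preset discrete_case_example --grid 3.5,4.5,5.5,6.5 \
                --duration 60000 --out out_scan        # Levelt checks
rivalsim theory --preset discrete_case_example --grid 0,2,4,...,30 \
                --out out_theory                       # mean-field sweep
rivalsim fixtures --kind poisson --n 20 --rate 20      # synthetic rasters
```

## Layout

| module | contents |
| --- | --- |
| `rivalsim.network` | LIF-with-adaptation integrator (numba kernel) |
| `rivalsim.architectures` | the three connectivity builders |
| `rivalsim.drive` | constant / OU / scan drive protocols |
| `rivalsim.measures` | percept state, dominance durations, CV_ISI, Fano, r_sc, Levelt checks |
| `rivalsim.theory` | balanced-state mean-field solver and sweeps |
| `rivalsim.synthetic` | ground-truth rasters for pipeline validation |
| `rivalsim.config`, `rivalsim.experiments`, `rivalsim.report`, `rivalsim.cli` | config schema, experiment runners, constraint report, CLI |

See `docs/methods.md` for the modelling decisions, parameter conventions and
known limitations.
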