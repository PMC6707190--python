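"""Neuron parameters shared by a population.

Units convention used throughout the package: voltages in mV, times in ms,
feedforward drive and synaptic input in mV/ms, rates reported in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the leaky integrate-and-fire neuron with adaptation.

    Parameters
    ----------
    theta : float
        Spike threshold (mV). On crossing, the voltage is reset to
        ``v - theta`` (threshold-subtraction reset).
    tau_m : float
        Membrane time constant (ms).
    tau_s : float
        Synaptic time constant (ms); presynaptic spikes kick the synaptic
        input variable, which decays exponentially with ``tau_s``.
    tau_a : float
        Adaptation time constant (ms). Each of a neuron's own spikes
        increments its adaptation trace by 1; the trace decays with ``tau_a``
        and hyperpolarizes with strength ``gamma``.
    gamma : float
        Adaptation strength (dimensionless multiplier on the trace).
    h : float
        Integration step (ms).
    adapt_e_only : bool
        Apply spike-frequency adaptation to excitatory neurons only
        (default).  Fast-spiking inhibitory interneurons show little
        adaptation, and with adaptation on the inhibitory class the
        disinhibition loop that sustains winner-take-all competition is
        blunted: the discrete case example then locks into a permanent
        winner instead of rivaling.
    """

    theta: float = 20.0
    tau_m: float = 20.0
    tau_s: float = 2.0
    tau_a: float = 350.0
    gamma: float = 0.44
    h: float = 0.1
    adapt_e_only: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_s", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if self.h <= 0:
            raise ValueError(f"integration step h must be positive, got {self.h}")
        if self.h > self.tau_s / 2:
            raise ValueError(
                f"h={self.h} too coarse for tau_s={self.tau_s}; need h <= tau_s/2"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


#: Case-example parameters for the discrete mutual-inhibition network.
DISCRETE_NEURON = NeuronParams(tau_a=350.0, gamma=0.44)

#: Case-example parameters for the continuum (ring) network.
CONTINUUM_NEURON = NeuronParams(tau_a=650.0, gamma=0.013)

#: Non-adapting neuron (unstructured network and mean-field comparisons).
NONADAPTING_NEURON = NeuronParams(gamma=0.0)
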