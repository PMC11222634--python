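"""Discrete-time leaky integrate-and-fire (LIF) primitives.

All dynamics use fixed-step first-order Euler discretization with a step of
1 ms; every time constant is expressed in simulation steps, so millisecond
values from the literature divide through directly.

Two coupled state variables per neuron:

* the unweighted postsynaptic current (PSC) ``a``, a first-order low-pass
  filter of the neuron's spike train,

      a[t] = (1 - 1/tau_syn) * a[t-1] + s[t]

* the membrane potential ``u``, a leaky integrator of the weighted input
  current that resets to zero on spiking,

      u_minus[t] = (1 - 1/tau_m) * u[t-1] + (R/tau_m) * I[t]
      s[t] = H(u_minus[t] - v_th),   u[t] = u_minus[t] * (1 - s[t])

Spike and reset co-occur at ``u_minus >= v_th``: the spike indicator and the
reset branch can never disagree (exact threshold equality is measure-zero in
float arithmetic).

For gradient computation the Heaviside step is replaced by a smooth surrogate
(:func:`spike_pseudo_grad`); the functions here are written dtype-agnostic so
that the same code paths run under complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "LIFState",
    "psc_step",
    "lif_step",
    "spike_pseudo_grad",
    "soft_spike",
]


@dataclass
class NeuronParams:
    """Intrinsic parameters of a LIF neuron (population).

    Parameters
    ----------
    tau_m
        Membrane time constant in timesteps; must be > 1 so the decay factor
        ``1 - 1/tau_m`` lies in (0, 1).
    tau_syn
        Synaptic (PSC) time constant in timesteps; must be > 1.
    R
        Leak resistance (dimensionless input gain), > 0.
    v_th
        Firing threshold, > 0.

    ``tau_m`` and ``R`` may be arrays (one entry per neuron) when intrinsic
    plasticity adapts them individually.
    """

    tau_m: float | np.ndarray = 16.0
    tau_syn: float = 8.0
    R: float | np.ndarray = 1.0
    v_th: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tau_m) <= 1):
            raise ValueError("tau_m must be > 1 timestep")
        if np.any(np.asarray(self.tau_syn) <= 1):
            raise ValueError("tau_syn must be > 1 timestep")
        if np.any(np.asarray(self.R) <= 0):
            raise ValueError("R must be positive")
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")


@dataclass
class LIFState:
    """Per-neuron state at one timestep: membrane ``u``, PSC ``a``, spikes ``s``."""

    u: np.ndarray
    a: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, ...] | int) -> "LIFState":
        """Rest state u = a = s = 0, the default initial condition."""
        return cls(u=np.zeros(shape), a=np.zeros(shape), s=np.zeros(shape))


def _check_binary(s: np.ndarray) -> None:
    if not np.all((s == 0) | (s == 1)):
        raise ValueError("spike vector must be binary (0/1)")


def psc_step(a_prev: np.ndarray, s: np.ndarray, tau_syn: float) -> np.ndarray:
    """One step of the first-order synapse: ``(1 - 1/tau_syn) * a_prev + s``.

    An isolated spike at time ``t_f`` therefore leaves the geometric tail
    ``a[t] = (1 - 1/tau_syn)**(t - t_f)``, and the impulse response sums to
    ``tau_syn`` over an infinite horizon.
    """
    if tau_syn <= 1:
        raise ValueError("tau_syn must be > 1 timestep")
    a_prev = np.asarray(a_prev, dtype=float)
    s = np.asarray(s)
    _check_binary(s)
    if not np.all(np.isfinite(a_prev)):
        raise ValueError("a_prev must be finite")
    return (1.0 - 1.0 / tau_syn) * a_prev + s


def lif_step(
    state: LIFState, weighted_current: np.ndarray, params: NeuronParams
) -> LIFState:
    """Advance membrane dynamics one step under the already-summed input drive.

    ``weighted_current`` is the total weighted PSC drive for this step
    (feedforward plus recurrent). Returns the new state; the PSC trace ``a``
    is advanced with :func:`psc_step` using the new spikes.
    """
    I = np.asarray(weighted_current, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("weighted current must be finite")
    if I.shape != np.shape(state.u):
        raise ValueError(
            f"shape mismatch: current {I.shape} vs state {np.shape(state.u)}"
        )
    tau = np.asarray(params.tau_m, dtype=float)
    u_minus = (1.0 - 1.0 / tau) * state.u + (params.R / tau) * I
    s = (u_minus >= params.v_th).astype(float)
    u = u_minus * (1.0 - s)
    a = psc_step(state.a, s, params.tau_syn)
    return LIFState(u=u, a=a, s=s)


def soft_spike(u_minus: np.ndarray, v_th: float, width: float = 0.2) -> np.ndarray:
    """Smooth relaxation of the spike function: logistic sigmoid around v_th.

    Used by the differentiable ("relaxed") network graph whose exact gradient
    the BPTT implementation computes; its derivative is the ``sigmoid``
    surrogate kernel. Written without branches so it accepts complex input
    (complex-step differentiation).
    """
    x = (u_minus - v_th) / width
    if np.iscomplexobj(x):
        # analytic branch-free form for complex-step differentiation
        return 1.0 / (1.0 + np.exp(-x))
    x = np.clip(np.asarray(x, dtype=float), -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-x))


def spike_pseudo_grad(
    u_minus: np.ndarray, v_th: float, kind: str = "sigmoid", width: float = 0.2
) -> np.ndarray:
    """Pseudo-derivative d s / d u of the spike nonlinearity.

    The kernel is a unimodal bump centered at ``v_th`` integrating to ~1 over
    the membrane axis, standing in for the non-differentiable Heaviside during
    backpropagation. ``kind``:

    - ``"sigmoid"`` (default): derivative of the logistic used by
      :func:`soft_spike`, peak 1/(4*width) at threshold;
    - ``"triangle"``: piecewise-linear hat of half-width ``2*width``;
    - ``"gaussian"``: normal density with std ``width``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    x = u_minus - v_th
    if kind == "sigmoid":
        if np.iscomplexobj(x):
            sg = 1.0 / (1.0 + np.exp(-x / width))
            return sg * (1.0 - sg) / width
        z = np.exp(-np.abs(np.asarray(x, dtype=float)) / width)  # symmetric, overflow-safe
        return z / ((1.0 + z) ** 2 * width)
    if kind == "triangle":
        h = 2.0 * width
        return np.maximum(0.0, (h - np.abs(x)) / h**2)
    if kind == "gaussian":
        return np.exp(-0.5 * (x / width) ** 2) / (width * np.sqrt(2.0 * np.pi))
    raise ValueError(f"unknown surrogate kind: {kind!r}")
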