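"""Homeostatic intrinsic plasticity (SpiKL-IP style) for recurrent neurons.

Each neuron tracks its firing rate through an intracellular-calcium trace

    phi[t] = (1 - 1/tau_cal) * phi[t-1] + s[t],     y[t] = phi[t] / tau_cal

and adapts its leak resistance ``R`` and membrane time constant ``tau`` by
gradient descent on an information-theoretic objective: the KL divergence
from the neuron's output-rate distribution to an exponential distribution
with target mean rate ``mu``. For the closed-form LIF rate function under a
constant suprathreshold current ``x``,

    y(x; R, tau) = 1 / (tau * ln(Rx / (Rx - v_th))),    Rx > v_th,

the instantaneous objective is ``L = -ln(dy/dx) + y/mu`` (output-entropy
maximization plus mean-rate penalty). Its exact partials are

    dL/dtau = (1 - y/mu) / tau
    dL/dR   = (z - 2 v_th tau y + v_th tau y^2 / mu) / (R (z - v_th))

with ``z = Rx``. In the online rule the operating point is implied from the
measured rate: ``z - v_th = v_th / (exp(1/(tau y)) - 1)``. The ``tau``
update vanishes exactly at ``y = mu``, which is what drives the long-run
firing rate to the target; the ``R`` update shapes sensitivity and in closed
loop drifts toward its clamp while ``tau`` holds the rate.

Silent neurons are handled by a rate floor and per-step update clipping;
``R`` and ``tau`` are clamped to validity ranges after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IPState", "calcium_step", "ip_objective", "ip_update_direction", "ip_step", "lif_rate"]

#: per-step |update| ceiling; keeps the degenerate silent-neuron gradient finite
MAX_STEP = 10.0
Y_FLOOR = 1e-4
Q_MAX = 30.0  # ceiling on 1/(tau*y) before exponentiation

R_BOUNDS = (0.2, 10.0)
TAU_BOUNDS = (2.0, 256.0)


@dataclass
class IPState:
    """Adaptive intrinsic parameters and rate estimate for one neuron pool."""

    n: int
    mu: float = 0.1
    tau_cal: float = 16.0
    gamma: float = 0.4
    R0: float = 1.0
    tau0: float = 16.0
    enabled: bool = True
    phi: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)
    R: np.ndarray = field(init=False)
    tau: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.mu >= 1:
            raise ValueError("target rate mu must lie in (0, 1) spikes/step")
        if self.tau_cal <= 1:
            raise ValueError("tau_cal must be > 1 timestep")
        self.phi = np.zeros(self.n)
        self.y = np.zeros(self.n)
        self.R = np.full(self.n, float(self.R0))
        self.tau = np.full(self.n, float(self.tau0))

    # hooks used by the layer simulator -------------------------------------
    def observe(self, s: np.ndarray) -> None:
        """Advance the calcium trace with this step's (batch-mean) spikes."""
        self.phi, self.y = calcium_step(self.phi, s, self.tau_cal)

    def adapt(self, v_th: float) -> None:
        if self.enabled and self.gamma != 0.0:
            self.R, self.tau = ip_step(self, v_th)


def calcium_step(
    phi: np.ndarray, s: np.ndarray, tau_cal: float
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the calcium trace; returns (phi, rate estimate y)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("spike values must lie in [0, 1]")
    phi = (1.0 - 1.0 / tau_cal) * phi + s
    return phi, phi / tau_cal


def lif_rate(x, R, tau, v_th: float = 1.0):
    """Closed-form continuous-time LIF firing rate under constant current."""
    z = R * x
    if np.any(z <= v_th):
        raise ValueError("rate model requires suprathreshold drive R*x > v_th")
    return 1.0 / (tau * np.log(z / (z - v_th)))


def ip_objective(R, tau, x, v_th: float = 1.0, mu: float = 0.05):
    """Instantaneous IP loss ``-ln(dy/dx) + y/mu`` at fixed input ``x``."""
    z = R * x
    g = np.log(z / (z - v_th))
    y = 1.0 / (tau * g)
    return (
        -np.log(R * v_th) + np.log(tau) + 2.0 * np.log(g)
        + np.log(z) + np.log(z - v_th) + y / mu
    )


def ip_update_direction(
    y: np.ndarray, R: np.ndarray, tau: np.ndarray, v_th: float, mu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient (dL/dR, dL/dtau) at the operating point implied by rate ``y``.

    The implied suprathreshold margin is ``z - v_th = v_th/(e^{1/(tau y)}-1)``;
    a rate floor and an exponent ceiling guard silent neurons.
    """
    y = np.clip(np.asarray(y, dtype=float), Y_FLOOR, 1.0 - 1e-9)
    q = np.clip(1.0 / (tau * y), 1e-9, Q_MAX)
    margin = v_th / np.expm1(q)  # z - v_th
    z = v_th + margin
    d_tau = (1.0 - y / mu) / tau
    d_R = (z - 2.0 * v_th * tau * y + v_th * tau * y**2 / mu) / (R * margin)
    d_R = np.clip(d_R, -MAX_STEP, MAX_STEP)
    d_tau = np.clip(d_tau, -MAX_STEP, MAX_STEP)
    return d_R, d_tau


def ip_step(state: IPState, v_th: float) -> tuple[np.ndarray, np.ndarray]:
    """One gradient-descent update of (R, tau), clamped to validity ranges."""
    d_R, d_tau = ip_update_direction(state.y, state.R, state.tau, v_th, state.mu)
    R = np.clip(state.R - state.gamma * d_R, *R_BOUNDS)
    tau = np.clip(state.tau - state.gamma * d_tau, *TAU_BOUNDS)
    return R, tau
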