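"""Conductance-based synapses with short-term plasticity.

Three receptor types are modelled: AMPA, GABA_A and NMDA.  Each presynaptic
spike contributes a difference-of-exponentials conductance transient

    g(t) = g_max * a(t_sp) * (exp(-(t - t_sp - tau_D)/tau_off)
                              - exp(-(t - t_sp - tau_D)/tau_on))

which drives a current ``g(t) * s(V) * (V - E_rev)`` where ``s(V)`` is the
NMDA magnesium-block gate (identically 1 for AMPA and GABA_A).  ``a(t_sp)``
is the relative efficiency of the spike under the Tsodyks–Markram model of
short-term facilitation and depression: a utilization variable ``u`` climbs
toward 1 with each spike and decays with ``tau_facil``, while a resource
variable ``R`` is consumed by each spike and recovers with ``tau_rec``.

The per-spike update, with ``dt_n`` the interval since the previous spike, is

    u_{n+1} = u_n exp(-dt_n/tau_facil) + U (1 - u_n exp(-dt_n/tau_facil))
    R_{n+1} = R_n (1 - u_{n+1}) exp(-dt_n/tau_rec) + 1 - exp(-dt_n/tau_rec)
    a_{n+1} = u_{n+1} R_{n+1}

with the first spike of a train initialized to ``u_1 = U``, ``R_1 = 1 - U``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Receptor",
    "SynapseParams",
    "STPParams",
    "STPState",
    "nmda_gate",
    "stp_on_spike",
    "stp_fixed_point",
    "synaptic_current",
    "kernel_peak_time",
    "DualExpAccumulator",
]

# NMDA gate constants (dimensionless, dimensionless, per mV).  Frozen: they
# define the magnesium-block phenomenology and are not tunable.
NMDA_GATE_SCALE = 1.08
NMDA_GATE_COEFF = 0.19
NMDA_GATE_SLOPE = 0.064


class Receptor(str, Enum):
    AMPA = "AMPA"
    GABAA = "GABAA"
    NMDA = "NMDA"


@dataclass(frozen=True)
class SynapseParams:
    """Kernel constants of one receptor type on one projection.

    tau_on/tau_off are the rise and decay time constants (ms) of the
    difference-of-exponentials conductance, tau_D the axonal + synaptic
    transmission delay (ms), E_rev the reversal potential (mV) and g_max the
    peak conductance scale (nS).
    """

    receptor: Receptor
    g_max: float
    E_rev: float
    tau_on: float
    tau_off: float
    tau_D: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_off > self.tau_on > 0):
            raise ValueError(
                f"need tau_off > tau_on > 0, got tau_on={self.tau_on}, tau_off={self.tau_off}"
            )
        if self.tau_D < 0:
            raise ValueError(f"tau_D must be non-negative, got {self.tau_D}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be non-negative, got {self.g_max}")


@dataclass(frozen=True)
class STPParams:
    """Tsodyks–Markram constants: baseline utilization U and the facilitation
    / depression-recovery time constants (ms)."""

    U: float = 0.25
    tau_facil: float = 500.0
    tau_rec: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.U < 1):
            raise ValueError(f"U must lie strictly in (0, 1), got {self.U}")
        if self.tau_facil <= 0 or self.tau_rec <= 0:
            raise ValueError("tau_facil and tau_rec must be positive")

    def replace(self, **kwargs) -> "STPParams":
        return replace(self, **kwargs)


@dataclass
class STPState:
    """Utilization u, resources R after the most recent spike, and its time."""

    u: float = 0.0
    R: float = 1.0
    t_last: Optional[float] = None


def nmda_gate(V, receptor: Receptor | str = Receptor.NMDA):
    """Voltage gate s(V): sigmoidal magnesium-block factor for NMDA, 1 otherwise.

    Accepts scalars or numpy arrays for ``V``.
    """
    if Receptor(receptor) is not Receptor.NMDA:
        return np.ones_like(V, dtype=float) if isinstance(V, np.ndarray) else 1.0
    return NMDA_GATE_SCALE / (1.0 + NMDA_GATE_COEFF * np.exp(-NMDA_GATE_SLOPE * np.asarray(V)))


def stp_on_spike(
    state: STPState, t_spike: float, params: STPParams
) -> tuple[STPState, float]:
    """Apply one presynaptic spike to the facilitation/depression state.

    Returns the post-spike state and the relative efficiency ``a = u * R``
    computed from the post-update values.  The first spike of a train sets
    ``u = U`` and ``R = 1 - U``.
    """
    if state.t_last is None:
        u = params.U
        R = 1.0 - params.U
    else:
        if t_spike < state.t_last:
            raise ValueError(
                f"presynaptic spikes out of order: t_spike={t_spike} < t_last={state.t_last}"
            )
        dt = t_spike - state.t_last
        ef = math.exp(-dt / params.tau_facil)
        er = math.exp(-dt / params.tau_rec)
        u = state.u * ef + params.U * (1.0 - state.u * ef)
        R = state.R * (1.0 - u) * er + 1.0 - er
    new = STPState(u=u, R=R, t_last=t_spike)
    return new, u * R


def stp_fixed_point(params: STPParams, isi: float) -> tuple[float, float]:
    """Steady-state (u*, R*) of the per-spike recursion for a periodic train
    with inter-spike interval ``isi`` (ms).  Closed-form solution of the
    two-line linear system obtained by setting u_{n+1} = u_n, R_{n+1} = R_n.
    """
    ef = math.exp(-isi / params.tau_facil)
    er = math.exp(-isi / params.tau_rec)
    u_star = params.U / (1.0 - (1.0 - params.U) * ef)
    R_star = (1.0 - er) / (1.0 - (1.0 - u_star) * er)
    return u_star, R_star


def synaptic_current(
    events: Iterable[tuple[float, float]],
    params: SynapseParams,
    V: float,
    t: float,
) -> float:
    """Direct evaluation of the synaptic current (pA) at time ``t``.

    ``events`` is a sequence of ``(t_sp, a)`` presynaptic spikes with their
    STP efficiencies.  Events whose delayed onset ``t_sp + tau_D`` lies in
    the future contribute nothing.  Sign convention: the returned value is
    *subtracted* from the membrane drive, so depolarized V relative to E_rev
    yields an outward (hyperpolarizing) current.
    """
    g = 0.0
    for t_sp, a in events:
        s = t - t_sp - params.tau_D
        if s < 0:
            continue
        g += a * (math.exp(-s / params.tau_off) - math.exp(-s / params.tau_on))
    return params.g_max * float(nmda_gate(V, params.receptor)) * g * (V - params.E_rev)


def kernel_peak_time(params: SynapseParams) -> float:
    """Time after the presynaptic spike at which the conductance kernel peaks:
    tau_D + tau_on*tau_off/(tau_off - tau_on) * ln(tau_off/tau_on)."""
    num = params.tau_on * params.tau_off / (params.tau_off - params.tau_on)
    return params.tau_D + num * math.log(params.tau_off / params.tau_on)


class DualExpAccumulator:
    """Grid-stepped bookkeeping of the difference-of-exponentials sum.

    Rather than summing over past events, two auxiliary variables ``x_off``
    and ``x_on`` are each incremented by the event weight at its (delayed)
    onset step and decay by ``exp(-dt/tau)`` per step; their difference is
    mathematically identical to the direct kernel sum at grid times.  The
    network engine uses the same scheme per neuron and receptor.
    """

    def __init__(self, tau_on: float, tau_off: float, dt: float):
        if not (tau_off > tau_on > 0):
            raise ValueError("need tau_off > tau_on > 0")
        self.dt = dt
        self._decay_on = math.exp(-dt / tau_on)
        self._decay_off = math.exp(-dt / tau_off)
        self.x_on = 0.0
        self.x_off = 0.0

    def step(self, incoming_weight: float = 0.0) -> float:
        """Advance one grid step, adding ``incoming_weight`` for events whose
        delayed onset falls on the *previous* grid time; returns the kernel
        sum at the new grid time."""
        self.x_on = self.x_on * self._decay_on + incoming_weight * self._decay_on
        self.x_off = self.x_off * self._decay_off + incoming_weight * self._decay_off
        return self.x_off - self.x_on

    @property
    def value(self) -> float:
        return self.x_off - self.x_on


def kernel_sum_on_grid(
    event_steps: Sequence[int],
    weights: Sequence[float],
    tau_on: float,
    tau_off: float,
    dt: float,
    n_steps: int,
) -> np.ndarray:
    """Kernel sum at grid times 0..n_steps via the auxiliary-decay scheme.

    ``event_steps[i]`` is the grid index of event i's delayed onset (the step
    at which its kernel value is zero).  Returned array has length
    ``n_steps + 1``.
    """
    incoming = np.zeros(n_steps + 1)
    for k, w in zip(event_steps, weights):
        if 0 <= k <= n_steps:
            incoming[k] += w
    acc = DualExpAccumulator(tau_on, tau_off, dt)
    out = np.zeros(n_steps + 1)
    for k in range(1, n_steps + 1):
        out[k] = acc.step(incoming[k - 1])
    # events landing exactly on a grid point contribute zero there
    return out
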