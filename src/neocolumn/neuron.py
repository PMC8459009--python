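"""Adaptive exponential integrate-and-fire (aEIF) point-neuron dynamics.

The membrane potential ``V`` (mV) and adaptation current ``w`` (pA) evolve as

    C dV/dt = -g_L (V - E_L) + g_L exp((V - V_th)/Delta_T) + I - w
    tau_w dw/dt = a (V - E_L) - w

and whenever a forward-Euler step carries ``V`` above the threshold ``V_th``
a spike is recorded, ``V`` is reset to ``V_r`` and ``w`` is incremented by
``b``.  Units are fixed package-wide: pA, pF, nS, mV, ms (pA/pF = mV/ms).

The exponential spike-initiation term is implemented with a bare ``g_L``
prefactor, i.e. the numerical value of the term is ``g_L`` (in pA) at
``V = V_th``.  The textbook aEIF multiplies the exponential by
``g_L * Delta_T``; that variant is available through ``canonical_exp_term``
for sensitivity checks but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["AEIFParams", "NeuronState", "aeif_step", "aeif_dvdt", "simulate_neuron"]

#: Upper clamp on the exponent (V - V_th)/Delta_T, preventing overflow in the
#: same step in which the threshold/reset rule fires.
EXP_ARG_MAX = 10.0


@dataclass(frozen=True)
class AEIFParams:
    """Membrane parameters of one cell class.

    Attributes
    ----------
    C : float
        Membrane capacitance (pF).
    g_L : float
        Leak conductance (nS).
    E_L : float
        Leak reversal potential (mV).
    V_r : float
        Reset potential (mV).
    V_th : float
        Spike threshold (mV).
    Delta_T : float
        Slope factor of the spike-initiation exponential (mV).
    tau_w : float
        Adaptation time constant (ms).
    a : float
        Subthreshold adaptation conductance (nS).
    b : float
        Spike-triggered adaptation increment (pA).
    """

    C: float
    g_L: float
    E_L: float
    V_r: float
    V_th: float
    Delta_T: float
    tau_w: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "tau_w", "Delta_T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AEIFParams.{name} must be positive, got {getattr(self, name)}")
        if self.V_r > self.V_th:
            raise ValueError(
                f"reset potential V_r={self.V_r} must not exceed threshold V_th={self.V_th}"
            )

    def replace(self, **kwargs) -> "AEIFParams":
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Instantaneous state of one neuron: V (mV), w (pA), last spike time (ms)."""

    V: float
    w: float
    last_spike_time: Optional[float] = None


def aeif_dvdt(
    V: float,
    w: float,
    p: AEIFParams,
    I_total: float,
    *,
    canonical_exp_term: bool = False,
) -> float:
    """Right-hand side of the voltage equation, in mV/ms."""
    arg = (V - p.V_th) / p.Delta_T
    if arg > EXP_ARG_MAX:
        arg = EXP_ARG_MAX
    prefactor = p.g_L * p.Delta_T if canonical_exp_term else p.g_L
    return (-p.g_L * (V - p.E_L) + prefactor * math.exp(arg) + I_total - w) / p.C


def aeif_step(
    state: NeuronState,
    params: AEIFParams,
    I_total: float,
    dt: float,
    t: float,
    *,
    canonical_exp_term: bool = False,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by a single forward-Euler step of length ``dt``.

    ``I_total`` is the summed background, stimulus and synaptic current (pA)
    evaluated at time ``t``.  Returns the new state and whether the step
    produced a spike; a spike is stamped at ``t + dt``, with ``V`` set to the
    reset potential and ``w`` incremented by ``b``.

    Raises
    ------
    FloatingPointError
        If the stepped ``V`` or ``w`` is non-finite (numeric blow-up).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    p = params
    dV = aeif_dvdt(state.V, state.w, p, I_total, canonical_exp_term=canonical_exp_term)
    V_new = state.V + dt * dV
    w_new = state.w + dt * (p.a * (state.V - p.E_L) - state.w) / p.tau_w
    if not (math.isfinite(V_new) and math.isfinite(w_new)):
        raise FloatingPointError(
            f"non-finite neuron state at t={t + dt:g} ms: V={V_new}, w={w_new}"
        )
    spiked = V_new > p.V_th
    if spiked:
        V_new = p.V_r
        w_new += p.b
        return NeuronState(V=V_new, w=w_new, last_spike_time=t + dt), True
    return NeuronState(V=V_new, w=w_new, last_spike_time=state.last_spike_time), False


def simulate_neuron(
    params: AEIFParams,
    I: float,
    duration: float,
    dt: float = 0.05,
    *,
    V0: Optional[float] = None,
    w0: float = 0.0,
    canonical_exp_term: bool = False,
) -> tuple[list[float], "list[float]"]:
    """Simulate an isolated neuron under a constant current.

    Initial conditions default to ``V(0) = E_L``, ``w(0) = 0``.  Returns
    ``(spike_times, voltage_trace)`` where the trace is sampled every step
    (length ``n_steps + 1``, including t = 0).
    """
    state = NeuronState(V=params.E_L if V0 is None else V0, w=w0)
    n_steps = int(round(duration / dt))
    spikes: list[float] = []
    trace = [state.V]
    for k in range(n_steps):
        state, spiked = aeif_step(
            state, params, I, dt, k * dt, canonical_exp_term=canonical_exp_term
        )
        if spiked:
            spikes.append((k + 1) * dt)
        trace.append(state.V)
    return spikes, trace
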