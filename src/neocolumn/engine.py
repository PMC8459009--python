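"""Time-stepped co-simulation of the column: neurons, synapses, delays.

The engine advances all neurons on a fixed grid (default dt = 0.05 ms).
Within a step the order is:

1. deliver spike events whose transmission delay elapses at the current
   grid time (each delivery increments the postsynaptic onset and offset
   accumulators of the matching receptor);
2. evaluate synaptic currents at the current membrane potential;
3. add background and stimulus currents and take one forward-Euler step;
4. apply the threshold/reset rule; spikes are stamped at the end of the step;
5. update the presynaptic short-term-plasticity state of each spiking
   neuron (at emission time) and enqueue one delivery per outgoing synapse;
6. decay the conductance accumulators by one step.

Synaptic conductances are tracked per neuron and receptor with two
auxiliary exponentials (onset/offset) rather than per-event sums; the two
schemes are mathematically identical on the grid.  Because STP constants
are shared across a neuron's outgoing connections, the utilization/resource
recursion is kept once per presynaptic neuron — every outgoing synapse of a
given spike carries the same efficiency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .column import ColumnNetwork, RECEPTOR_ORDER

__all__ = ["SpikeRaster", "SimulationProtocol", "run_simulation"]


@dataclass
class SpikeRaster:
    """Spike events of one run: parallel arrays of neuron ids (1-based) and
    spike times (ms, multiples of dt)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    t_end: float
    dt: float

    def __post_init__(self):
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.times)

    def count_in(self, t0: float, t1: float) -> int:
        """Number of spikes with t0 <= t < t1."""
        return int(np.count_nonzero((self.times >= t0) & (self.times < t1)))

    def counts_per_neuron(self, t0: float, t1: float, n_neurons: int) -> np.ndarray:
        """Spike count per neuron id (index 0 unused) within [t0, t1)."""
        sel = (self.times >= t0) & (self.times < t1)
        return np.bincount(self.neuron_ids[sel], minlength=n_neurons + 1)

    def active_ids(self, t0: float, t1: float) -> np.ndarray:
        """Sorted ids of neurons with at least one spike in the closed-open
        window [t0, t1)."""
        sel = (self.times >= t0) & (self.times < t1)
        return np.unique(self.neuron_ids[sel])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.neuron_ids, "spike_time_ms": self.times})

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SimulationProtocol:
    """What to run: duration, step, optional stimulus, trace recording."""

    duration: float = 300.0
    dt: float = 0.05
    stimulus: Optional["StimulusLike"] = None
    record_traces: Sequence[int] = field(default_factory=tuple)
    trace_resolution: float = 1.0
    seed: int = 0

    def __post_init__(self):
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration {self.duration} is not a multiple of dt {self.dt}")


class StimulusLike:
    """Anything that can render itself to per-step current events; see
    :mod:`neocolumn.stimulus`."""

    def current_events(self, dt: float, n_steps: int, rng: np.random.Generator):
        raise NotImplementedError


@njit(cache=True)
def _run_core(
    n_steps,
    dt,
    # neuron params
    C, gL, EL, Vr, Vth, DT, tauw, a_ad, b_ad, I_bg,
    exp_clamp, canonical,
    # state
    V, w,
    # synapses (CSR by presynaptic neuron)
    indptr, syn_post, syn_w,
    # receptor constants
    decay_on, decay_off, delay_steps, E_rev, nmda_idx,
    # STP (per presynaptic neuron)
    stp_U, stp_tauf, stp_taur, stp_u, stp_R, stp_tlast,
    # stimulus events (CSR by step)
    stim_indptr, stim_neuron, stim_amp,
    # trace recording
    rec_idx, rec_stride, traces,
    # output
    spike_neuron, spike_step,
):
    N = V.shape[0]
    n_rec = 3
    dmax = 0
    for r in range(n_rec):
        if delay_steps[r] > dmax:
            dmax = delay_steps[r]
    Lbuf = dmax + 2
    buf = np.zeros((Lbuf, N, n_rec))
    x_on = np.zeros((N, n_rec))
    x_off = np.zeros((N, n_rec))
    I_stim = np.zeros(N)
    n_spikes = 0
    delivered = 0
    cap = spike_neuron.shape[0]
    n_trace = rec_idx.shape[0]

    for k in range(n_steps):
        if n_trace > 0 and k % rec_stride == 0:
            row = k // rec_stride
            for j in range(n_trace):
                traces[row, j] = V[rec_idx[j]]
        slot = k % Lbuf
        # 1. absorb due deliveries (kernel value is zero at onset)
        for i in range(N):
            for r in range(n_rec):
                inc = buf[slot, i, r]
                if inc != 0.0:
                    x_on[i, r] += inc
                    x_off[i, r] += inc
                    buf[slot, i, r] = 0.0
        # stimulus for this step
        for i in range(N):
            I_stim[i] = 0.0
        for e in range(stim_indptr[k], stim_indptr[k + 1]):
            I_stim[stim_neuron[e]] += stim_amp[e]
        # 2-4. currents + Euler + reset
        t_next = (k + 1) * dt
        for i in range(N):
            Vi = V[i]
            I_syn = 0.0
            for r in range(n_rec):
                g = x_off[i, r] - x_on[i, r]
                if g != 0.0:
                    if r == nmda_idx:
                        s = 1.08 / (1.0 + 0.19 * math.exp(-0.064 * Vi))
                    else:
                        s = 1.0
                    I_syn += g * s * (Vi - E_rev[r])
            arg = (Vi - Vth[i]) / DT[i]
            if arg > exp_clamp:
                arg = exp_clamp
            if canonical:
                pref = gL[i] * DT[i]
            else:
                pref = gL[i]
            dV = (-gL[i] * (Vi - EL[i]) + pref * math.exp(arg)
                  + I_bg[i] + I_stim[i] - w[i] - I_syn) / C[i]
            V_new = Vi + dt * dV
            w_new = w[i] + dt * (a_ad[i] * (Vi - EL[i]) - w[i]) / tauw[i]
            if not (math.isfinite(V_new) and math.isfinite(w_new)):
                return n_spikes, delivered, i, k + 1
            if V_new > Vth[i]:
                V[i] = Vr[i]
                w[i] = w_new + b_ad[i]
                if n_spikes >= cap:
                    return n_spikes, delivered, -2, k + 1
                spike_neuron[n_spikes] = i
                spike_step[n_spikes] = k + 1
                n_spikes += 1
                # 5. STP at emission time, then enqueue deliveries
                if stp_tlast[i] < -1e29:
                    u = stp_U
                    R = 1.0 - stp_U
                else:
                    dt_sp = t_next - stp_tlast[i]
                    ef = math.exp(-dt_sp / stp_tauf)
                    er = math.exp(-dt_sp / stp_taur)
                    u = stp_u[i] * ef + stp_U * (1.0 - stp_u[i] * ef)
                    R = stp_R[i] * (1.0 - u) * er + 1.0 - er
                stp_u[i] = u
                stp_R[i] = R
                stp_tlast[i] = t_next
                a_eff = u * R
                for s_i in range(indptr[i], indptr[i + 1]):
                    post = syn_post[s_i]
                    for r in range(n_rec):
                        wgt = syn_w[s_i, r]
                        if wgt != 0.0:
                            tgt = (k + 1 + delay_steps[r]) % Lbuf
                            buf[tgt, post, r] += a_eff * wgt
                            delivered += 1
            else:
                V[i] = V_new
                w[i] = w_new
        # 6. decay accumulators
        for i in range(N):
            for r in range(n_rec):
                x_on[i, r] *= decay_on[r]
                x_off[i, r] *= decay_off[r]
    # final trace sample
    if n_trace > 0 and n_steps % rec_stride == 0:
        row = n_steps // rec_stride
        if row < traces.shape[0]:
            for j in range(n_trace):
                traces[row, j] = V[rec_idx[j]]
    return n_spikes, delivered, -1, n_steps


def run_simulation(
    network: ColumnNetwork,
    protocol: SimulationProtocol,
) -> tuple[SpikeRaster, Optional[np.ndarray]]:
    """Run one simulation; returns the spike raster and, when trace
    recording was requested, a (time x neuron) voltage matrix sampled at
    ``protocol.trace_resolution``.

    Initial conditions are V(0) = E_L per neuron and w(0) = 0.  Identical
    network + protocol (including seed) reproduce identical rasters.
    """
    dt = protocol.dt
    n_steps = int(round(protocol.duration / dt))
    N = network.n_neurons

    aeif = network.aeif  # (N, 9) in canonical field order
    V = aeif[:, 2].copy()  # E_L
    w = np.zeros(N)

    decay_on = np.empty(3)
    decay_off = np.empty(3)
    delay_steps = np.empty(3, dtype=np.int64)
    E_rev = np.empty(3)
    for r, name in enumerate(RECEPTOR_ORDER):
        sp = network.synapse_params[name]
        decay_on[r] = math.exp(-dt / sp.tau_on)
        decay_off[r] = math.exp(-dt / sp.tau_off)
        # delays shorter than one step round up to one step
        delay_steps[r] = max(1, int(round(sp.tau_D / dt)))
        E_rev[r] = sp.E_rev
    nmda_idx = RECEPTOR_ORDER.index("NMDA")

    # stimulus events -> CSR by step
    rng = np.random.default_rng(np.random.SeedSequence(protocol.seed))
    if protocol.stimulus is not None:
        steps, neurons, amps = protocol.stimulus.current_events(dt, n_steps, rng)
    else:
        steps = np.empty(0, dtype=np.int64)
        neurons = np.empty(0, dtype=np.int64)
        amps = np.empty(0, dtype=np.float64)
    order = np.argsort(steps, kind="stable")
    steps, neurons, amps = steps[order], neurons[order], amps[order]
    stim_indptr = np.searchsorted(steps, np.arange(n_steps + 1)).astype(np.int64)

    rec_ids = np.asarray(sorted(protocol.record_traces), dtype=np.int64)
    rec_idx = rec_ids - 1  # 1-based ids -> 0-based indices
    rec_stride = max(1, int(round(protocol.trace_resolution / dt)))
    n_rows = n_steps // rec_stride + 1
    traces = np.zeros((n_rows, len(rec_idx))) if len(rec_idx) else np.zeros((0, 0))

    stp = network.stp_params
    stp_u = np.zeros(N)
    stp_R = np.ones(N)
    stp_tlast = np.full(N, -1e30)

    cap = max(100_000, min(N * n_steps, 8_000_000))
    spike_neuron = np.empty(cap, dtype=np.int32)
    spike_step = np.empty(cap, dtype=np.int32)

    n_spikes, delivered, err, err_step = _run_core(
        n_steps, dt,
        np.ascontiguousarray(aeif[:, 0]), np.ascontiguousarray(aeif[:, 1]),
        np.ascontiguousarray(aeif[:, 2]), np.ascontiguousarray(aeif[:, 3]),
        np.ascontiguousarray(aeif[:, 4]), np.ascontiguousarray(aeif[:, 5]),
        np.ascontiguousarray(aeif[:, 6]), np.ascontiguousarray(aeif[:, 7]),
        np.ascontiguousarray(aeif[:, 8]), network.background,
        network.exp_clamp, network.canonical_exp_term,
        V, w,
        network.syn_indptr, network.syn_post, network.syn_weight,
        decay_on, decay_off, delay_steps, E_rev, nmda_idx,
        stp.U, stp.tau_facil, stp.tau_rec, stp_u, stp_R, stp_tlast,
        stim_indptr, neurons.astype(np.int64), amps.astype(np.float64),
        rec_idx, rec_stride, traces,
        spike_neuron, spike_step,
    )
    if err >= 0:
        raise FloatingPointError(
            f"non-finite state in neuron id {err + 1} at t={err_step * dt:g} ms"
        )
    if err == -2:
        raise RuntimeError("spike buffer overflow; raise the cap")

    raster = SpikeRaster(
        neuron_ids=spike_neuron[:n_spikes] + 1,
        times=spike_step[:n_spikes] * dt,
        t_end=protocol.duration,
        dt=dt,
    )
    raster.delivered_events = int(delivered)  # event-accounting hook for tests
    return raster, (traces if len(rec_idx) else None)


def write_run_manifest(
    path: str | Path,
    network: ColumnNetwork,
    protocol: SimulationProtocol,
    extra: Optional[dict] = None,
) -> None:
    """JSON manifest capturing what a run depended on (config hash, seeds,
    durations), sufficient to reproduce it."""
    manifest = {
        "config_sha256": network.config_hash,
        "build_seed": network.seed,
        "species": network.species,
        "n_neurons": network.n_neurons,
        "n_synapses": network.n_synapses,
        "duration_ms": protocol.duration,
        "dt_ms": protocol.dt,
        "protocol_seed": protocol.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
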