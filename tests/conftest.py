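"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neocolumn.config import default_config
from neocolumn.neuron import EXP_ARG_MAX, AEIFParams


@pytest.fixture(scope="session")
def config():
    """The bundled two-species default column configuration."""
    return default_config()


@pytest.fixture()
def tiny_config(config):
    """A 15-neuron single-layer column for fast engine tests."""
    cfg = config.model_copy(deep=True)
    cfg.architecture.layers = {"L2/3": {"PC": 10, "LL-IN": 5}}
    return cfg


def reference_aeif_spikes(p: AEIFParams, I: float, duration: float, max_spikes: int = 500):
    """Independent high-order adaptive integration of the aEIF equations with
    event detection at the threshold crossing, used as the spike-time oracle.
    """

    def rhs(t, y):
        V, w = y
        arg = min((V - p.V_th) / p.Delta_T, EXP_ARG_MAX)
        dV = (-p.g_L * (V - p.E_L) + p.g_L * np.exp(arg) + I - w) / p.C
        dw = (p.a * (V - p.E_L) - w) / p.tau_w
        return [dV, dw]

    def crossing(t, y):
        return y[0] - p.V_th

    crossing.terminal = True
    crossing.direction = 1.0

    t0, y = 0.0, [p.E_L, 0.0]
    spikes = []
    while t0 < duration and len(spikes) < max_spikes:
        sol = solve_ivp(
            rhs, (t0, duration), y, events=crossing,
            rtol=1e-10, atol=1e-12, max_step=1.0,
        )
        if sol.t_events[0].size:
            ts = float(sol.t_events[0][0])
            spikes.append(ts)
            t0 = ts
            y = [p.V_r, float(sol.y_events[0][0][1]) + p.b]
        else:
            break
    return spikes


def random_aeif_protocols(n: int, seed: int = 42):
    """Randomized suprathreshold parameter/current protocols."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = AEIFParams(
            C=rng.uniform(60, 300),
            g_L=rng.uniform(4, 14),
            E_L=rng.uniform(-75, -65),
            V_r=rng.uniform(-65, -55),
            V_th=rng.uniform(-48, -40),
            Delta_T=rng.uniform(0.8, 2.5),
            tau_w=rng.uniform(30, 250),
            a=rng.uniform(0, 4),
            b=rng.uniform(5, 80),
        )
        I = p.g_L * (p.V_th - p.E_L) * rng.uniform(1.2, 2.0)
        out.append((p, float(I)))
    return out
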