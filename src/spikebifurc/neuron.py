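"""Wang-Buzsaki single-compartment neuron with per-trial noise current.

The model has fast sodium (instantaneous activation m = m_inf(V)),
delayed-rectifier potassium and leak currents; gate kinetics for h and n
are accelerated by a dimensionless factor zeta = 5.  An optional slow
potassium current with spike-activated gating variable z produces
long-lasting spike patterns.  Integration is second-order Runge-Kutta
(midpoint) at dt = 0.05 ms; the per-step noise current is drawn once from
a uniform distribution and held constant through both RK stages.

Rate constants are the canonical Wang & Buzsaki (1996) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .ensemble import SpikeTrainEnsemble
from .stimulus import StimulusWaveform

__all__ = [
    "NeuronParams",
    "SimConfig",
    "VoltageTrace",
    "rate_constants",
    "steady_state_gates",
    "wb_derivatives",
    "simulate_trial",
    "detect_spikes",
    "simulate_ensemble",
    "noise_bound",
]


@dataclass
class NeuronParams:
    """Membrane parameters (defaults: standard Wang-Buzsaki values).

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2.
    ``g_slow`` = 0 disables the slow potassium current; when enabled, its
    gate z relaxes to 1 with ``tau_z_fast`` (ms) while V >= V_z (spike
    upstroke) and decays to 0 with ``tau_z_slow`` (ms) otherwise.
    """

    E_L: float = -65.0
    E_Na: float = 55.0
    E_K: float = -90.0
    g_L: float = 0.1
    g_Na: float = 35.0
    g_K: float = 9.0
    C_m: float = 1.0
    zeta: float = 5.0
    g_slow: float = 0.0
    tau_z_fast: float = 10.0
    tau_z_slow: float = 500.0
    V_z: float = -20.0

    def __post_init__(self) -> None:
        if min(self.g_L, self.g_Na, self.g_K, self.g_slow) < 0:
            raise ValueError("conductances must be non-negative")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")


@dataclass
class SimConfig:
    """Integration settings for one trial.

    ``lam`` is the noise intensity lambda (mV^2/ms) of the white-noise
    current: <xi(t) xi(t')> = 2*lambda*delta(t-t').  With
    ``noise_dialect='contract'`` the per-step uniform draw has bounds
    +/- sqrt(6*lambda/dt) so its variance is exactly 2*lambda/dt;
    ``'literal'`` uses bounds +/- 12*lambda/dt instead.
    """

    dt: float = 0.05
    lam: float = 0.0
    V0: float = -70.0
    z0: float = 0.0
    seed: int = 0
    noise_dialect: str = "contract"
    record_voltage: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.noise_dialect not in ("contract", "literal"):
            raise ValueError("noise_dialect must be 'contract' or 'literal'")


@dataclass
class VoltageTrace:
    """Simulated state trajectory sampled every ``dt`` ms."""

    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    z: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.V.size)


# -- kinetics ---------------------------------------------------------------


@njit(cache=True)
def _rates(V):
    """Wang-Buzsaki (1996) rate constants in 1/ms.

    The removable singularities of alpha_m (V = -35) and alpha_n (V = -34)
    are evaluated by their analytic limits.
    """
    x = V + 35.0
    if abs(x) < 1e-7:
        alpha_m = 1.0
    else:
        alpha_m = -0.1 * x / (np.exp(-0.1 * x) - 1.0)
    beta_m = 4.0 * np.exp(-(V + 60.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 58.0) / 20.0)
    beta_h = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    y = V + 34.0
    if abs(y) < 1e-7:
        alpha_n = 0.1
    else:
        alpha_n = -0.01 * y / (np.exp(-0.1 * y) - 1.0)
    beta_n = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def rate_constants(V: float):
    """Public wrapper returning (a_m, b_m, a_h, b_h, a_n, b_n) at ``V`` mV."""
    return _rates(float(V))


def steady_state_gates(V: float):
    """Asymptotic gate values (m_inf, h_inf, n_inf) at voltage ``V``."""
    am, bm, ah, bh, an, bn = _rates(float(V))
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@njit(cache=True)
def _derivs(V, h, n, z, I_inj, xi, E_L, E_Na, E_K, g_L, g_Na, g_K, C_m, zeta,
            g_slow, tau_zf, tau_zs, V_z):
    am, bm, ah, bh, an, bn = _rates(V)
    m_inf = am / (am + bm)
    I_L = g_L * (V - E_L)
    I_Na = g_Na * m_inf**3 * h * (V - E_Na)
    I_K = g_K * n**4 * (V - E_K)
    I_slow = g_slow * z * (V - E_K)
    dV = (-I_L - I_Na - I_K - I_slow + I_inj + xi) / C_m
    dh = zeta * (ah * (1.0 - h) - bh * h)
    dn = zeta * (an * (1.0 - n) - bn * n)
    if V >= V_z:
        dz = (1.0 - z) / tau_zf
    else:
        dz = -z / tau_zs
    return dV, dh, dn, dz


def wb_derivatives(V, h, n, z, I_inj, params: NeuronParams, xi: float = 0.0):
    """Time derivatives (dV/dt, dh/dt, dn/dt, dz/dt) of the model state."""
    return _derivs(
        float(V), float(h), float(n), float(z), float(I_inj), float(xi),
        params.E_L, params.E_Na, params.E_K, params.g_L, params.g_Na,
        params.g_K, params.C_m, params.zeta, params.g_slow,
        params.tau_z_fast, params.tau_z_slow, params.V_z,
    )


# -- integration ------------------------------------------------------------


@njit(cache=True)
def _integrate(I, noise, dt, V0, h0, n0, z0, E_L, E_Na, E_K, g_L, g_Na, g_K,
               C_m, zeta, g_slow, tau_zf, tau_zs, V_z):
    n_steps = I.size
    out = np.empty((4, n_steps + 1))
    V, h, n, z = V0, h0, n0, z0
    out[0, 0], out[1, 0], out[2, 0], out[3, 0] = V, h, n, z
    for k in range(n_steps):
        xi = noise[k]
        dV1, dh1, dn1, dz1 = _derivs(V, h, n, z, I[k], xi, E_L, E_Na, E_K,
                                     g_L, g_Na, g_K, C_m, zeta, g_slow,
                                     tau_zf, tau_zs, V_z)
        Vm = V + 0.5 * dt * dV1
        hm = h + 0.5 * dt * dh1
        nm = n + 0.5 * dt * dn1
        zm = z + 0.5 * dt * dz1
        dV2, dh2, dn2, dz2 = _derivs(Vm, hm, nm, zm, I[k], xi, E_L, E_Na,
                                     E_K, g_L, g_Na, g_K, C_m, zeta, g_slow,
                                     tau_zf, tau_zs, V_z)
        V += dt * dV2
        h += dt * dh2
        n += dt * dn2
        z += dt * dz2
        if not np.isfinite(V):
            return out[:, : k + 1], k
        out[0, k + 1], out[1, k + 1], out[2, k + 1], out[3, k + 1] = V, h, n, z
    return out, -1


def noise_bound(lam: float, dt: float, dialect: str = "contract") -> float:
    """Half-width of the per-step uniform noise distribution.

    The contract dialect makes the discrete-step variance equal 2*lam/dt
    (matching the white-noise autocorrelation); the literal dialect uses
    the alternative printed bound 12*lam/dt.
    """
    if dialect == "contract":
        return float(np.sqrt(6.0 * lam / dt))
    return 12.0 * lam / dt


def simulate_trial(
    params: NeuronParams, stimulus: StimulusWaveform, config: SimConfig
) -> VoltageTrace:
    """Integrate one trial of the model driven by ``stimulus``.

    The stimulus is resampled onto the integration grid by zero-order
    hold.  Gates h and n start at their asymptotic values for ``V0``; the
    slow gate starts at ``config.z0``.  The noise current is drawn once
    per step (seeded) and shared between both RK stages.
    """
    dt = config.dt
    n_steps = int(round(stimulus.duration / dt))
    # zero-order hold resample onto the integration grid
    step_t = stimulus.t0 + dt * np.arange(n_steps)
    I = stimulus.value_at(step_t)
    rng = np.random.default_rng(config.seed)
    if config.lam > 0:
        bound = noise_bound(config.lam, dt, config.noise_dialect)
        noise = rng.uniform(-bound, bound, size=n_steps)
    else:
        noise = np.zeros(n_steps)
    m0, h0, n0 = steady_state_gates(config.V0)
    out, bad = _integrate(
        I, noise, dt, config.V0, h0, n0, config.z0,
        params.E_L, params.E_Na, params.E_K, params.g_L, params.g_Na,
        params.g_K, params.C_m, params.zeta, params.g_slow,
        params.tau_z_fast, params.tau_z_slow, params.V_z,
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite state at integration step {bad}")
    return VoltageTrace(V=out[0], h=out[1], n=out[2], z=out[3], dt=dt)


def detect_spikes(trace: VoltageTrace) -> np.ndarray:
    """Spike times: first sample with V >= 0 mV preceded by V < 0 mV."""
    V = trace.V
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage trace contains non-finite values")
    up = np.flatnonzero((V[1:] >= 0.0) & (V[:-1] < 0.0)) + 1
    return up * trace.dt


def simulate_ensemble(
    params: NeuronParams,
    stimulus: StimulusWaveform,
    n_trials: int,
    config: SimConfig,
    seed_list=None,
    condition: dict | None = None,
    keep_traces: bool = False,
):
    """Simulate ``n_trials`` independent trials of the same stimulus.

    Each trial uses its own noise seed (``seed_list`` or
    ``config.seed + trial``); the per-trial condition record stores the
    condition tags plus the seed.  Returns the ensemble, and the list of
    voltage traces if ``keep_traces``.
    """
    import pandas as pd

    if seed_list is None:
        seed_list = [config.seed + i for i in range(n_trials)]
    if len(set(seed_list)) != len(seed_list):
        raise ValueError("seeds must be distinct across trials")
    if len(seed_list) != n_trials:
        raise ValueError("need one seed per trial")
    condition = dict(condition or {})
    condition.setdefault("condition_id", 0)
    trains, traces, rows = [], [], []
    for s in seed_list:
        trace = simulate_trial(params, stimulus, replace(config, seed=int(s)))
        trains.append(detect_spikes(trace))
        if keep_traces:
            traces.append(trace)
        rows.append({**condition, "lam": config.lam, "seed": int(s)})
    ens = SpikeTrainEnsemble(
        trains, duration=stimulus.duration, conditions=pd.DataFrame(rows),
        t0=stimulus.t0,
    )
    return (ens, traces) if keep_traces else ens
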