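"""Coupled ODE system for the sleep/wake switch and its simulation protocol.

The state vector is ``(Vm, Vv, H, x, y, n)``:

* ``Vm``, ``Vv`` — mean cell-body potentials (mV) of the wake-promoting
  monoaminergic (MA) and sleep-promoting VLPO populations, mutually
  inhibiting each other through sigmoidal firing rates.
* ``H`` — sleep homeostatic pressure (nM), accumulating at rate ``mu * Qm``
  during wake and clearing with time constant ``chi``.
* ``x``, ``y`` — light-forced van der Pol circadian pacemaker.
* ``n`` — fraction of activated photoreceptors, driving the photic input
  ``B`` to the pacemaker.  Light reaches the photoreceptors only while
  awake (``Vm > Vv``).

Wake is defined as ``Vm > Vv`` at every time point.

Two integrators are provided: a numba-compiled fixed-step RK4 (``method=
"rk4"``, the default; dt = 1 s resolves the fastest time constant,
``tau_m`` = 10 s, with large margin and runs a 63-day protocol in about a
second, which is what makes grid sweeps tractable) and an adaptive stiff
reference (``method="lsoda"``, scipy LSODA at rtol 1e-6 / atol 1e-8).  The
test-suite checks that the two agree to well below the resolution of the
fitting grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .params import (SECONDS_PER_DAY, SECONDS_PER_HOUR, LightSchedule,
                     ModelParameters)

__all__ = [
    "ModelState", "SimulationResult", "SimulationError",
    "firing_rate", "light_level", "gated_light", "photic_drive",
    "circadian_output", "sleep_drive", "derivatives", "simulate",
    "DEFAULT_INITIAL_STATE",
]

STATE_NAMES = ("Vm", "Vv", "H", "x", "y", "n")

# Awake at dawn: MA depolarized relative to VLPO, moderate sleep pressure,
# pacemaker near the phase an entrained solution occupies at dawn (starting
# the oscillator at an arbitrary phase leaves a slow residual phase drift
# that a 4-week transient does not fully absorb), photoreceptors half
# activated.  The values are fixed as part of the reproducibility contract.
DEFAULT_INITIAL_STATE = np.array([0.0, -10.0, 10.0, 1.0, -0.1, 0.5])


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class ModelState:
    Vm: float
    Vv: float
    H: float
    x: float
    y: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Vm, self.Vv, self.H, self.x, self.y, self.n])


# ---------------------------------------------------------------------------
# elementary pieces (kept as small pure functions so they can be tested
# against closed forms independently of any integrator)
# ---------------------------------------------------------------------------

def firing_rate(V, params: ModelParameters):
    """Sigmoidal population firing rate Q(V) = Qmax / (1 + exp(-(V-theta)/sigma))."""
    from scipy.special import expit
    return params.Qmax * expit((np.asarray(V, dtype=float) - params.theta) / params.sigma)


def light_level(t_clock_h, schedule: LightSchedule):
    """Environmental light (lux) at clock time ``t_clock_h`` (hours of day).

    Smooth dawn/dusk transitions of steepness ``c`` (s^-1) between the
    evening level ``l_e`` and the daytime level ``l_d``.
    """
    t = np.asarray(t_clock_h, dtype=float) * SECONDS_PER_HOUR
    s1 = schedule.s1 * SECONDS_PER_HOUR
    s2 = schedule.s2 * SECONDS_PER_HOUR
    return schedule.l_e + 0.5 * (schedule.l_d - schedule.l_e) * (
        np.tanh(schedule.c * (t - s1)) - np.tanh(schedule.c * (t - s2)))


def gated_light(t_clock_h, wake, schedule: LightSchedule):
    """Light reaching the photoreceptors: the schedule while awake, 0 asleep."""
    return np.where(wake, light_level(t_clock_h, schedule), 0.0)


def photic_drive(x, y, n, I_gated, params: ModelParameters):
    """Drive B from the photoreceptive pathway to the circadian pacemaker.

    B = G (1-n) (1-b x) (1-b y) alpha0 (I/I0)^p.  The (1-bx)(1-by) factor
    shapes the phase response; b -> 1 biases it toward phase delay.
    """
    alpha_hat = params.alpha0 * (np.asarray(I_gated, dtype=float) / params.I0) ** params.p
    return params.G * (1.0 - n) * (1.0 - params.b * x) * (1.0 - params.b * y) * alpha_hat


def circadian_output(x, y):
    """Circadian process C = (1/2)(1 + 0.80 y - 0.47 x)."""
    return 0.5 * (1.0 + 0.80 * np.asarray(y, dtype=float) - 0.47 * np.asarray(x, dtype=float))


def sleep_drive(H, C, params: ModelParameters):
    """Total drive to the VLPO: D = nu_vh H + nu_vc C + D0."""
    return params.nu_vh * np.asarray(H, dtype=float) + params.nu_vc * C + params.D0


def derivatives(t: float, state, params: ModelParameters,
                schedule: LightSchedule) -> np.ndarray:
    """Right-hand side of the coupled system, time in seconds.

    Hour-denominated constants (chi, kappa, lam) are converted to seconds
    here; ``t`` is seconds since the run origin (midnight), so clock time is
    ``t mod 86400``.  The arousal gate for light uses ``Vm > Vv`` of the
    evaluated state.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise SimulationError(f"non-finite state at t={t}: {state}")
    Vm, Vv, H, x, y, n = state
    Qm = float(firing_rate(Vm, params))
    Qv = float(firing_rate(Vv, params))
    wake = Vm > Vv
    t_clock_h = (t % SECONDS_PER_DAY) / SECONDS_PER_HOUR
    I = float(gated_light(t_clock_h, wake, schedule))
    B = float(photic_drive(x, y, n, I, params))
    C = float(circadian_output(x, y))
    D = float(sleep_drive(H, C, params))

    chi_s = params.chi * SECONDS_PER_HOUR
    kappa_s = params.kappa * SECONDS_PER_HOUR
    lam_s = params.lam / SECONDS_PER_HOUR
    omega2 = (24.0 / (params.f * params.tau_c)) ** 2
    alpha_hat = params.alpha0 * (I / params.I0) ** params.p

    return np.array([
        (-Vm + params.nu_mv * Qv + params.A) / params.tau_m,
        (-Vv + params.nu_vm * Qm + D) / params.tau_v,
        (-H + params.mu * Qm) / chi_s,
        (params.gamma * (x - 4.0 * x ** 3 / 3.0) - y * (omega2 + params.k * B)) / kappa_s,
        (x + B) / kappa_s,
        lam_s * (alpha_hat * (1.0 - n) - params.beta * n),
    ])


# ---------------------------------------------------------------------------
# fast fixed-step integrator
# ---------------------------------------------------------------------------

# indices into the packed constant vector handed to the numba kernel
_C_NAMES = ("Qmax", "theta", "sigma", "A", "nu_vm", "nu_mv", "tau_m", "tau_v",
            "nu_vh", "D0", "mu", "chi_s", "nu_vc", "b", "G", "lam_s", "beta",
            "kappa_s", "gamma", "omega2", "k")


def _pack_constants(params: ModelParameters) -> np.ndarray:
    return np.array([
        params.Qmax, params.theta, params.sigma, params.A, params.nu_vm,
        params.nu_mv, params.tau_m, params.tau_v, params.nu_vh, params.D0,
        params.mu, params.chi * SECONDS_PER_HOUR, params.nu_vc, params.b,
        params.G, params.lam / SECONDS_PER_HOUR, params.beta,
        params.kappa * SECONDS_PER_HOUR, params.gamma,
        (24.0 / (params.f * params.tau_c)) ** 2, params.k,
    ])


def _alpha_hat_table(params: ModelParameters, schedule: LightSchedule,
                     resolution_s: float = 1.0) -> np.ndarray:
    """Per-second lookup of alpha0*(L(t)/I0)^p over one clock day."""
    n = int(round(SECONDS_PER_DAY / resolution_s))
    t_h = np.arange(n) * resolution_s / SECONDS_PER_HOUR
    L = light_level(t_h, schedule)
    return params.alpha0 * (L / params.I0) ** params.p


@njit(cache=True)
def _rhs_njit(u, t, c, ahat, du):  # pragma: no cover - exercised via simulate
    Vm, Vv, H, x, y, n = u[0], u[1], u[2], u[3], u[4], u[5]
    Qm = c[0] / (1.0 + math.exp(-(Vm - c[1]) / c[2]))
    Qv = c[0] / (1.0 + math.exp(-(Vv - c[1]) / c[2]))
    if Vm > Vv:
        idx = int(t) % 86400
        if idx < 0:
            idx += 86400
        ah = ahat[idx]
    else:
        ah = 0.0
    B = c[14] * (1.0 - n) * (1.0 - c[13] * x) * (1.0 - c[13] * y) * ah
    C = 0.5 * (1.0 + 0.80 * y - 0.47 * x)
    D = c[8] * H + c[12] * C + c[9]
    du[0] = (-Vm + c[5] * Qv + c[3]) / c[6]
    du[1] = (-Vv + c[4] * Qm + D) / c[7]
    du[2] = (-H + c[10] * Qm) / c[11]
    du[3] = (c[18] * (x - 4.0 * x ** 3 / 3.0) - y * (c[19] + c[20] * B)) / c[17]
    du[4] = (x + B) / c[17]
    du[5] = c[15] * (ah * (1.0 - n) - c[16] * n)


@njit(cache=True)
def _rk4_njit(u, t0, n_steps, dt, c, ahat, out, sample_every):  # pragma: no cover
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    tmp = np.empty(6)
    n_out = 0
    for i in range(n_steps):
        if sample_every > 0 and i % sample_every == 0:
            out[n_out] = u
            n_out += 1
        t = t0 + i * dt
        _rhs_njit(u, t, c, ahat, k1)
        for j in range(6):
            tmp[j] = u[j] + 0.5 * dt * k1[j]
        _rhs_njit(tmp, t + 0.5 * dt, c, ahat, k2)
        for j in range(6):
            tmp[j] = u[j] + 0.5 * dt * k2[j]
        _rhs_njit(tmp, t + 0.5 * dt, c, ahat, k3)
        for j in range(6):
            tmp[j] = u[j] + dt * k3[j]
        _rhs_njit(tmp, t + dt, c, ahat, k4)
        for j in range(6):
            u[j] = u[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return n_out


# ---------------------------------------------------------------------------
# simulation protocol
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Uniformly sampled trajectory of the run segment.

    ``times`` are seconds since the run origin, which is a clock midnight,
    so ``(times / 3600) % 24`` is clock time.  ``wake[i]`` is
    ``Vm[i] > Vv[i]``.
    """

    times: np.ndarray
    states: np.ndarray          # shape (n, 6), columns ordered as STATE_NAMES
    params: ModelParameters
    schedule: LightSchedule
    sample_dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 6):
            raise ValueError("states must have shape (len(times), 6)")

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        raise AttributeError(name)

    @property
    def wake(self) -> np.ndarray:
        return self.states[:, 0] > self.states[:, 1]

    @property
    def clock_h(self) -> np.ndarray:
        return (self.times % SECONDS_PER_DAY) / SECONDS_PER_HOUR

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.times)
        df.insert(1, "clock_h", self.clock_h)
        df["wake"] = self.wake.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(params: ModelParameters,
             schedule: Optional[LightSchedule] = None,
             transient_days: int = 28,
             run_days: int = 35,
             initial: Optional[np.ndarray] = None,
             method: str = "rk4",
             dt: float = 1.0,
             sample_dt: float = 60.0,
             rtol: float = 1e-6,
             atol: float = 1e-8) -> SimulationResult:
    """Integrate the model under the standard protocol and return the run.

    The transient starts awake at dawn (clock ``schedule.s1``) and lasts
    until the run origin, a midnight ``transient_days`` days later; its final
    state seeds the scoring run of ``run_days`` days.  Only the run segment
    is returned, sampled every ``sample_dt`` seconds.
    """
    if schedule is None:
        schedule = LightSchedule()
    if transient_days < 0 or run_days < 1:
        raise ValueError("need transient_days >= 0 and run_days >= 1")
    u0 = np.array(DEFAULT_INITIAL_STATE if initial is None else initial, dtype=float)
    if u0.shape != (6,):
        raise ValueError("initial state must have 6 components (Vm, Vv, H, x, y, n)")

    # transient covers [dawn - transient_days, 0); run covers [0, run_days)
    t_start = schedule.s1 * SECONDS_PER_HOUR - transient_days * SECONDS_PER_DAY
    if transient_days == 0:
        t_start = 0.0
    t_run_end = run_days * SECONDS_PER_DAY
    n_samples = int(round(t_run_end / sample_dt))

    if method == "rk4":
        c = _pack_constants(params)
        ahat = _alpha_hat_table(params, schedule)
        if abs(round(sample_dt / dt) * dt - sample_dt) > 1e-9:
            raise ValueError("sample_dt must be an integer multiple of dt")
        # transient: no sampling
        if t_start < 0.0:
            n_steps = int(round(-t_start / dt))
            _rk4_njit(u0, t_start, n_steps, dt, c, ahat, np.empty((0, 6)), 0)
        out = np.empty((n_samples, 6))
        n_steps = int(round(t_run_end / dt))
        _rk4_njit(u0, 0.0, n_steps, dt, c, ahat, out, int(round(sample_dt / dt)))
        times = np.arange(n_samples) * sample_dt
        states = out
    elif method == "lsoda":
        def rhs(t, u):
            return derivatives(t, u, params, schedule)
        if t_start < 0.0:
            sol = solve_ivp(rhs, (t_start, 0.0), u0, method="LSODA",
                            rtol=rtol, atol=atol, max_step=600.0)
            if not sol.success:
                raise SimulationError(
                    f"transient integration failed for combo {params.combo}: {sol.message}")
            u0 = sol.y[:, -1]
        times = np.arange(n_samples) * sample_dt
        sol = solve_ivp(rhs, (0.0, t_run_end), u0, method="LSODA",
                        rtol=rtol, atol=atol, max_step=600.0, t_eval=times)
        if not sol.success:
            raise SimulationError(
                f"run integration failed for combo {params.combo}: {sol.message}")
        states = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r} (expected 'rk4' or 'lsoda')")

    if not np.all(np.isfinite(states)):
        raise SimulationError(f"non-finite trajectory for combo {params.combo}")
    return SimulationResult(times=times, states=states, params=params,
                            schedule=schedule, sample_dt=sample_dt)
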