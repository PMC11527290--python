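"""Model parameters and the environmental light schedule.

The sleep/wake switch model couples three subsystems:

* a mean-field mutual-inhibition switch between the wake-promoting
  monoaminergic (MA) population and the sleep-promoting ventrolateral
  preoptic (VLPO) population,
* a first-order sleep homeostat (somnogen level ``H``, accumulation rate
  ``mu``, clearance time ``chi``),
* a light-forced van der Pol circadian pacemaker with a photoreceptor
  activation process ``n``.

All published constants live here as dataclass defaults.  Time constants are
stored in the units they are usually quoted in (seconds for the switch, hours
for the homeostat and pacemaker); the integrator converts everything to
seconds on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import IO, Union

import yaml

__all__ = ["ModelParameters", "LightSchedule", "adult_defaults"]

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class LightSchedule:
    """Smooth day/night light profile, gated by the arousal state elsewhere.

    L(t) = l_e + (l_d - l_e)/2 * [tanh(c*(t - s1)) - tanh(c*(t - s2))]

    with ``t``, ``s1``, ``s2`` in seconds of clock time and ``c`` in s^-1.

    Parameters
    ----------
    l_e : float
        Evening/indoor light level while awake at night (lux).
    l_d : float
        Daytime light level (lux).  The default of 1000 lux reflects the
        mixed indoor/outdoor exposure of an infant rather than full outdoor
        illuminance.
    c : float
        Steepness of the dawn/dusk transitions (s^-1).
    s1, s2 : float
        Clock time of dawn and dusk (hours).
    """

    l_e: float = 20.0
    l_d: float = 1000.0
    c: float = 1.0 / 6000.0
    s1: float = 8.0
    s2: float = 17.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.l_e <= self.l_d):
            raise ValueError(f"require 0 <= l_e <= l_d, got l_e={self.l_e}, l_d={self.l_d}")
        if not (0.0 <= self.s1 < self.s2 < 24.0):
            raise ValueError(f"require 0 <= s1 < s2 < 24 h, got s1={self.s1}, s2={self.s2}")
        if self.c <= 0.0:
            raise ValueError("transition steepness c must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """All physiological constants of the switch/homeostat/pacemaker model.

    The four developmentally varying parameters are ``mu`` (homeostatic
    accumulation rate, nM s), ``chi`` (homeostatic clearance time, h),
    ``nu_vc`` (circadian drive strength onto the VLPO, mV, <= 0) and ``b``
    (phase-response shape of the clock's light response; larger values bias
    toward phase delay).  Defaults are the adult values; everything else is
    fixed across age.
    """

    # sleep/wake switch
    Qmax: float = 100.0      # maximal population firing rate (s^-1)
    theta: float = 10.0      # half-activation voltage (mV)
    sigma: float = 3.0       # sigmoid width (mV)
    A: float = 1.3           # orexinergic/cholinergic excitation of MA (mV)
    nu_vm: float = -2.1      # VLPO <- MA weight (mV s)
    nu_mv: float = -1.8      # MA <- VLPO weight (mV s)
    tau_m: float = 10.0      # MA membrane time constant (s)
    tau_v: float = 10.0      # VLPO membrane time constant (s)
    # sleep drive
    nu_vh: float = 1.0       # homeostatic weight (mV nM^-1)
    D0: float = -10.2        # background VLPO drive (mV)
    mu: float = 4.2          # somnogen accumulation rate (nM s)
    chi: float = 45.0        # somnogen clearance time (h)
    nu_vc: float = -3.37     # circadian drive strength (mV, <= 0)
    # circadian pacemaker / photic pathway
    b: float = 0.4           # phase-response shape (dimensionless, in [0, 1])
    alpha0: float = 0.16     # photoreceptor activation rate scale (min^-1)
    I0: float = 9500.0       # light intensity scale (lux)
    p: float = 0.6           # light intensity exponent
    G: float = 19.9          # photic drive gain
    lam: float = 60.0        # per-hour conversion of the per-minute rates
    beta: float = 0.013      # photoreceptor deactivation rate (min^-1)
    kappa: float = field(default=12.0 / 3.141592653589793)  # oscillator stiffness (h)
    gamma: float = 0.23      # van der Pol nonlinearity
    f: float = 0.99669       # period correction factor
    tau_c: float = 24.2      # intrinsic circadian period (h)
    k: float = 0.55          # light-period coupling

    def __post_init__(self) -> None:
        positive = ("Qmax", "sigma", "tau_m", "tau_v", "chi", "mu",
                    "alpha0", "I0", "p", "G", "lam", "beta", "kappa", "tau_c")
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.nu_vc > 0.0:
            raise ValueError(f"nu_vc must be <= 0 (circadian drive inhibits VLPO), got {self.nu_vc}")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError(f"b must lie in [0, 1], got {self.b}")

    def with_combo(self, mu: float, chi: float, nu_vc: float, b: float) -> "ModelParameters":
        """Return a copy with the four free parameters replaced."""
        return replace(self, mu=mu, chi=chi, nu_vc=nu_vc, b=b)

    @property
    def combo(self) -> tuple[float, float, float, float]:
        return (self.mu, self.chi, self.nu_vc, self.b)


def adult_defaults() -> ModelParameters:
    """Published adult parameter set (mu=4.2 nM s, chi=45 h, nu_vc=-3.37 mV, b=0.4)."""
    return ModelParameters()


# -- plain-text (YAML) round trip -------------------------------------------

def save_config(params: ModelParameters, schedule: LightSchedule,
                stream: Union[str, IO[str]]) -> None:
    """Serialize parameters and light schedule to a YAML config."""
    payload = {"parameters": asdict(params), "schedule": asdict(schedule)}
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
    else:
        yaml.safe_dump(payload, stream, sort_keys=True)


def load_config(stream: Union[str, IO[str]]) -> tuple[ModelParameters, LightSchedule]:
    """Inverse of :func:`save_config`; missing keys fall back to defaults."""
    if isinstance(stream, str):
        with open(stream) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(stream)
    payload = payload or {}
    params = ModelParameters(**payload.get("parameters", {}))
    schedule = LightSchedule(**payload.get("schedule", {}))
    return params, schedule
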