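"""Currents, gating functions and parameters of the parsimonious rabbit (PR) model.

The PR model is a three-variable (``Vm``, ``m``, ``h``) cardiac action
potential model: a Hodgkin–Huxley fast sodium current

.. math:: I_{Na} = g_{Na}\\, m^3 h\\, (V_m - E_{Na})

coupled to a time-independent, outwardly rectifying potassium current

.. math:: I_K = g_K\\, e^{-b (V_m - E_K)} (V_m - E_K).

Gating steady states follow a Boltzmann sigmoid and the time constants the
thermodynamically consistent bell form; the activation time constant
``tau_m`` is a voltage-independent constant.

Units convention (used verbatim throughout the package, no conversions in
the core): mV, ms, mS/uF, uA/uF (Cm = 1 uF/cm^2, so uA/uF == uA/cm^2 and
pA/pF == uA/uF), cm, cm^2/ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace, asdict

__all__ = [
    "SodiumParams",
    "PotassiumParams",
    "CellState",
    "RateConstants",
    "InvalidParameterError",
    "default_parameters",
    "steady_state_gate",
    "gate_time_constant",
    "gate_rate_constants",
    "sodium_current",
    "potassium_current",
    "invert_inactivation_tau",
    "resting_potential",
    "params_to_config",
    "params_from_config",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraint."""


@dataclass(frozen=True)
class SodiumParams:
    """Fast sodium current (INa) parameters.

    Attributes
    ----------
    g_na : float
        Maximal conductance, mS/uF.
    e_na : float
        Sodium reversal potential, mV.
    e_m, k_m : float
        Activation midpoint (mV) and slope (mV, negative for activation).
    tau_m : float
        Activation time constant, ms (voltage independent).
    e_h, k_h : float
        Inactivation midpoint (mV) and slope (mV, positive for inactivation).
    tau_h0 : float
        Inactivation time-constant scale, ms (the value of tau_h at e_h).
    delta_h : float
        Asymmetry factor of the tau_h bell, dimensionless in [0, 1].
    """

    g_na: float = 11.0
    e_na: float = 65.0
    e_m: float = -41.0
    k_m: float = -4.0
    tau_m: float = 0.12
    e_h: float = -74.9
    k_h: float = 4.4
    tau_h0: float = 6.80738
    delta_h: float = 0.799163

    def __post_init__(self) -> None:
        if self.g_na <= 0:
            raise InvalidParameterError(f"g_na must be > 0, got {self.g_na}")
        if self.k_m >= 0:
            raise InvalidParameterError(f"k_m must be < 0 (activation), got {self.k_m}")
        if self.k_h <= 0:
            raise InvalidParameterError(f"k_h must be > 0 (inactivation), got {self.k_h}")
        if self.tau_m <= 0:
            raise InvalidParameterError(f"tau_m must be > 0, got {self.tau_m}")
        if self.tau_h0 <= 0:
            raise InvalidParameterError(f"tau_h0 must be > 0, got {self.tau_h0}")
        if not 0.0 <= self.delta_h <= 1.0:
            raise InvalidParameterError(f"delta_h must be in [0, 1], got {self.delta_h}")

    def with_scaled_g_na(self, scale: float) -> "SodiumParams":
        return replace(self, g_na=self.g_na * scale)


@dataclass(frozen=True)
class PotassiumParams:
    """Rectifying potassium current (IK) parameters.

    ``g_k`` (mS/uF) sets the magnitude, ``b`` (1/mV) the rectification
    shape, ``e_k`` (mV) the reversal potential, set to the resting potential.
    """

    g_k: float = 0.3
    b: float = 0.047
    e_k: float = -83.0

    def __post_init__(self) -> None:
        if self.g_k <= 0:
            raise InvalidParameterError(f"g_k must be > 0, got {self.g_k}")
        if self.b <= 0:
            raise InvalidParameterError(f"b must be > 0, got {self.b}")


@dataclass
class CellState:
    """Instantaneous state of the 0D model: membrane potential and gates."""

    vm: float
    m: float
    h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise InvalidParameterError(f"m must be in [0, 1], got {self.m}")
        if not 0.0 <= self.h <= 1.0:
            raise InvalidParameterError(f"h must be in [0, 1], got {self.h}")


@dataclass(frozen=True)
class RateConstants:
    """On/off rates (1/ms) of a gate; alpha/(alpha+beta) = y_inf, 1/(alpha+beta) = tau."""

    alpha: float
    beta: float


def default_parameters() -> tuple[SodiumParams, PotassiumParams]:
    """Return the nominal PR model parameters."""
    return SodiumParams(), PotassiumParams()


def steady_state_gate(vm: float, e_half: float, slope: float) -> float:
    """Boltzmann steady-state gate fraction 1/(1 + exp((vm - e_half)/slope)).

    ``slope`` < 0 gives an activation curve (rising with vm), ``slope`` > 0
    an inactivation curve.
    """
    if slope == 0:
        raise InvalidParameterError("gate slope must be nonzero")
    return 1.0 / (1.0 + math.exp((vm - e_half) / slope))


def gate_time_constant(
    vm: float, e_half: float, slope: float, tau0: float, delta: float
) -> float:
    """Bell-shaped gate time constant 2*tau0*exp(delta*u)/(1+exp(u)), u=(vm-e_half)/slope.

    Peaks near ``e_half`` with asymmetry controlled by ``delta``;
    ``tau(e_half) = tau0`` exactly.
    """
    if slope == 0:
        raise InvalidParameterError("gate slope must be nonzero")
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be > 0, got {tau0}")
    u = (vm - e_half) / slope
    return 2.0 * tau0 * math.exp(delta * u) / (1.0 + math.exp(u))


def gate_rate_constants(
    vm: float, e_half: float, slope: float, tau0: float, delta: float
) -> RateConstants:
    """Derived on/off rates alpha = y_inf/tau, beta = (1 - y_inf)/tau."""
    y_inf = steady_state_gate(vm, e_half, slope)
    tau = gate_time_constant(vm, e_half, slope, tau0, delta)
    return RateConstants(alpha=y_inf / tau, beta=(1.0 - y_inf) / tau)


def sodium_current(state: CellState, p: SodiumParams) -> float:
    """INa = g_na * m^3 * h * (vm - e_na), uA/uF (negative = inward)."""
    return p.g_na * state.m**3 * state.h * (state.vm - p.e_na)


def potassium_current(vm: float, p: PotassiumParams) -> float:
    """IK = g_k * exp(-b*(vm - e_k)) * (vm - e_k), uA/uF.

    Zero at ``e_k``; rises to a single maximum g_k/(b*e) at ``e_k + 1/b``
    and rectifies (decays) beyond — the nonlinearity that shapes
    repolarization in this model.
    """
    dv = vm - p.e_k
    return p.g_k * math.exp(-p.b * dv) * dv


def invert_inactivation_tau(
    pair1: tuple[float, float],
    pair2: tuple[float, float],
    e_h: float,
    k_h: float,
) -> tuple[float, float]:
    """Closed-form (tau0, delta) reproducing two (vm, tau) calibration pairs.

    The ratio of the two bell-curve instances isolates ``delta``; ``tau0``
    follows by substitution.  The round-trip residual of the returned pair
    through :func:`gate_time_constant` is below 1e-12 relative.

    Raises
    ------
    InvalidParameterError
        If the two voltages coincide (degenerate system) or a tau is
        non-positive.  A ``delta`` outside [0, 1] is returned with a warning.
    """
    (v1, t1), (v2, t2) = pair1, pair2
    if v1 == v2:
        raise InvalidParameterError("calibration voltages must be distinct")
    if t1 <= 0 or t2 <= 0:
        raise InvalidParameterError("calibration time constants must be positive")
    u1 = (v1 - e_h) / k_h
    u2 = (v2 - e_h) / k_h
    # log of ratio t1/t2 = exp(delta*(u1-u2)) * (1+e^u2)/(1+e^u1)
    delta = (
        math.log(t1 / t2) + math.log1p(math.exp(u1)) - math.log1p(math.exp(u2))
    ) / (u1 - u2)
    tau0 = t1 * (1.0 + math.exp(u1)) / (2.0 * math.exp(delta * u1))
    if not 0.0 <= delta <= 1.0:
        warnings.warn(
            f"inverted delta = {delta:.6g} lies outside [0, 1]", stacklevel=2
        )
    return tau0, delta


def resting_potential(na: SodiumParams, k: PotassiumParams) -> float:
    """Root of INa + IK = 0 (gates at steady state) near e_k.

    The true resting point sits slightly above ``e_k`` because the small
    steady-state sodium window current must be balanced by outward IK.
    """
    from scipy.optimize import brentq

    def net(vm: float) -> float:
        st = CellState(
            vm=vm,
            m=steady_state_gate(vm, na.e_m, na.k_m),
            h=steady_state_gate(vm, na.e_h, na.k_h),
        )
        return sodium_current(st, na) + potassium_current(vm, k)

    lo, hi = k.e_k - 10.0, k.e_k + 15.0
    return float(brentq(net, lo, hi, xtol=1e-10))


# --- flat key-value config round trip -------------------------------------

def params_to_config(na: SodiumParams, k: PotassiumParams) -> dict[str, float]:
    """Flatten parameters to a key-value mapping (keys are the field names)."""
    out = dict(asdict(na))
    out.update(asdict(k))
    return out


def params_from_config(cfg: dict[str, float]) -> tuple[SodiumParams, PotassiumParams]:
    """Build parameter sets from a flat mapping; unknown keys are rejected."""
    na_fields = set(SodiumParams.__dataclass_fields__)
    k_fields = set(PotassiumParams.__dataclass_fields__)
    unknown = set(cfg) - na_fields - k_fields
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    na = SodiumParams(**{f: float(cfg[f]) for f in na_fields if f in cfg})
    k = PotassiumParams(**{f: float(cfg[f]) for f in k_fields if f in cfg})
    return na, k
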