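"""Hodgkin-Huxley membrane and conductance equations.

Implements the squid-axon action potential model in two forms:

* the *simplified* form, in which the six gating rate constants
  (``alpha_n`` ... ``beta_h``) are free parameters, and
* the *full* form, in which the six rates are functions of membrane
  voltage governed by 14 voltage-dependency constants (the ``k_*``
  parameters of :class:`VoltageDependencyParams`).

Sign convention
---------------
The original squid-axon convention is used throughout: ``V`` is the
displacement of the membrane potential from rest, the resting potential
is ``V = 0``, and a *depolarization* of ``d`` mV corresponds to
``V = -d`` (action potentials drive ``V`` strongly negative, toward the
sodium reversal potential at ``V = -115`` mV).  Hyperpolarization is
positive ``V``.  :func:`to_modern_convention` converts output traces to
the modern membrane-potential convention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MembraneConstants",
    "GatingRates",
    "VoltageDependencyParams",
    "MembraneState",
    "MembraneCurrents",
    "Segment",
    "SimulationResult",
    "IntegrationError",
    "DegenerateGateError",
    "RESTING_GATES",
    "rates_from_voltage",
    "gating_derivatives",
    "conductances",
    "steady_state_gating",
    "membrane_currents",
    "membrane_derivative",
    "simulate",
    "to_modern_convention",
    "K_PARAM_NAMES",
    "K_PARAMS_POTASSIUM",
    "K_PARAMS_SODIUM",
    "RATE_NAMES",
]

# Largest exponent argument passed to exp(); |arg| above this is clamped.
# exp(+-500) is finite in float64 and far outside any physiological regime.
_EXP_CLAMP = 500.0

# Relative half-width (in units of the exponent denominator k3) of the
# removable-singularity branch of the (V + k2)/(exp((V + k2)/k3) - 1) form.
_SINGULARITY_TOL = 1e-7

K_PARAM_NAMES = (
    "k_an1", "k_an2", "k_an3", "k_bn1", "k_bn2",
    "k_am1", "k_am2", "k_am3", "k_bm1", "k_bm2",
    "k_ah1", "k_ah2", "k_bh1", "k_bh2",
)
K_PARAMS_POTASSIUM = ("k_an1", "k_an2", "k_an3", "k_bn1", "k_bn2")
K_PARAMS_SODIUM = (
    "k_am1", "k_am2", "k_am3", "k_bm1", "k_bm2",
    "k_ah1", "k_ah2", "k_bh1", "k_bh2",
)
RATE_NAMES = ("alpha_n", "beta_n", "alpha_m", "beta_m", "alpha_h", "beta_h")


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; carries the offending parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


class DegenerateGateError(ValueError):
    """A gate with alpha + beta = 0 has no steady state."""


@dataclass(frozen=True)
class MembraneConstants:
    """Fixed electrical constants of the membrane circuit.

    Defaults are the squid-axon values of the original 1952
    parametrization (original sign convention), treated here as
    configuration rather than fitted quantities.
    """

    C_M: float = 1.0          # membrane capacitance, uF/cm^2
    gbar_K: float = 36.0      # max potassium conductance, mS/cm^2
    gbar_Na: float = 120.0    # max sodium conductance, mS/cm^2
    g_l: float = 0.3          # leak conductance, mS/cm^2
    V_Na: float = -115.0      # sodium reversal potential, mV
    V_K: float = 12.0         # potassium reversal potential, mV
    V_l: float = -10.613      # leak reversal potential, mV

    def __post_init__(self):
        if not self.C_M > 0:
            raise ValueError("C_M must be positive")
        if min(self.gbar_K, self.gbar_Na, self.g_l) < 0:
            raise ValueError("conductances must be non-negative")


@dataclass(frozen=True)
class GatingRates:
    """The six first-order gating rate constants (1/ms)."""

    alpha_n: float
    beta_n: float
    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"rate {f.name} must be >= 0, got {v}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class VoltageDependencyParams:
    """The 14 constants of the voltage-dependent rate functions.

    Defaults reproduce the reported 1952 parametrization, i.e.
    :func:`rates_from_voltage` with these values yields the classic
    empirical rate curves.
    """

    k_an1: float = 0.01
    k_an2: float = 10.0
    k_an3: float = 10.0
    k_bn1: float = 0.125
    k_bn2: float = 80.0
    k_am1: float = 0.1
    k_am2: float = 25.0
    k_am3: float = 10.0
    k_bm1: float = 4.0
    k_bm2: float = 18.0
    k_ah1: float = 0.07
    k_ah2: float = 20.0
    k_bh1: float = 30.0
    k_bh2: float = 10.0

    _DENOMINATORS = ("k_an3", "k_bn2", "k_am3", "k_bm2", "k_ah2", "k_bh2")

    def __post_init__(self):
        for name in self._DENOMINATORS:
            if not getattr(self, name) > 0:
                raise ValueError(f"exponent denominator {name} must be > 0")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in K_PARAM_NAMES}

    def with_updates(self, **updates) -> "VoltageDependencyParams":
        return replace(self, **updates)

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageDependencyParams":
        return cls(**{k: d[k] for k in K_PARAM_NAMES if k in d})


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous membrane state (original sign convention)."""

    t: float
    V: float
    n: float
    m: float
    h: float


@dataclass(frozen=True)
class MembraneCurrents:
    """Component membrane currents (uA/cm^2); I_i = I_Na + I_K + I_l."""

    I: float
    I_i: float
    I_Na: float
    I_K: float
    I_l: float


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def _expm1_ratio(V, k1, k2, k3):
    """k1*(V + k2) / (exp((V + k2)/k3) - 1) with the removable
    singularity at V = -k2 replaced by its analytic limit k1*k3."""
    V = np.asarray(V, dtype=float)
    u = V + k2
    singular = np.abs(u) < _SINGULARITY_TOL * k3
    u_safe = np.where(singular, 1.0, u)
    denom = np.expm1(np.clip(u_safe / k3, -_EXP_CLAMP, _EXP_CLAMP))
    out = np.where(singular, k1 * k3, k1 * u_safe / denom)
    return out


def rates_from_voltage(k: VoltageDependencyParams, V) -> GatingRates:
    """Evaluate the six voltage-dependent gating rates at voltage ``V``.

    ``V`` may be a scalar or an array (mV, original convention).  The
    removable singularity of the alpha_n / alpha_m functional form at
    ``V = -k2`` is handled by an explicit limit branch, and exponent
    arguments are clamped to +-500 to guard against overflow.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    scalar = V.ndim == 0

    alpha_n = _expm1_ratio(V, k.k_an1, k.k_an2, k.k_an3)
    beta_n = k.k_bn1 * _safe_exp(V / k.k_bn2)
    alpha_m = _expm1_ratio(V, k.k_am1, k.k_am2, k.k_am3)
    beta_m = k.k_bm1 * _safe_exp(V / k.k_bm2)
    alpha_h = k.k_ah1 * _safe_exp(V / k.k_ah2)
    beta_h = 1.0 / (_safe_exp((V + k.k_bh1) / k.k_bh2) + 1.0)

    vals = [alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h]
    if scalar:
        vals = [float(v) for v in vals]
    return GatingRates(*vals)


def gating_derivatives(n, m, h, rates: GatingRates):
    """dx/dt = alpha_x (1 - x) - beta_x x for x in (n, m, h)."""
    dn = rates.alpha_n * (1.0 - n) - rates.beta_n * n
    dm = rates.alpha_m * (1.0 - m) - rates.beta_m * m
    dh = rates.alpha_h * (1.0 - h) - rates.beta_h * h
    return dn, dm, dh


def conductances(n, m, h, consts: MembraneConstants):
    """(g_K, g_Na) = (gbar_K n^4, gbar_Na m^3 h) in mS/cm^2."""
    return consts.gbar_K * n ** 4, consts.gbar_Na * m ** 3 * h


def steady_state_gating(rates: GatingRates):
    """Fixed point x_inf = alpha / (alpha + beta) of each gate ODE."""
    out = []
    for a, b in ((rates.alpha_n, rates.beta_n),
                 (rates.alpha_m, rates.beta_m),
                 (rates.alpha_h, rates.beta_h)):
        tot = a + b
        if np.any(np.asarray(tot) <= 0):
            raise DegenerateGateError("gate with alpha + beta = 0 has no steady state")
        out.append(a / tot)
    return tuple(out)


def membrane_currents(V, n, m, h, consts: MembraneConstants,
                      I_applied: float = 0.0) -> MembraneCurrents:
    g_K, g_Na = conductances(n, m, h, consts)
    I_Na = g_Na * (V - consts.V_Na)
    I_K = g_K * (V - consts.V_K)
    I_l = consts.g_l * (V - consts.V_l)
    I_i = I_Na + I_K + I_l
    return MembraneCurrents(I=I_applied, I_i=I_i, I_Na=I_Na, I_K=I_K, I_l=I_l)


def membrane_derivative(V, n, m, h, consts: MembraneConstants,
                        I_applied: float = 0.0):
    """dV/dt = (I_applied - I_i) / C_M (mV/ms)."""
    cur = membrane_currents(V, n, m, h, consts, I_applied)
    return (I_applied - cur.I_i) / consts.C_M


# Resting gating variables: the steady state of the default rate
# functions at V = 0 (matches the reported resting values n ~ 0.3177,
# m ~ 0.0529, h ~ 0.5961).
def _resting_gates() -> tuple:
    r = rates_from_voltage(VoltageDependencyParams(), 0.0)
    return steady_state_gating(r)


RESTING_GATES = _resting_gates()


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise drive schedule.

    kind: "clamp_v" (V held at ``value``), "clamp_i" (applied current
    ``value`` uA/cm^2), or "free" (no drive).  ``v_step`` is an
    instantaneous offset added to V at the start of the segment
    (a discontinuous state reset, used for step depolarizations).
    """

    duration_ms: float
    kind: str
    value: float = 0.0
    v_step: float = 0.0

    def __post_init__(self):
        if self.kind not in ("clamp_v", "clamp_i", "free"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.duration_ms > 0:
            raise ValueError("segment duration must be positive")


@dataclass
class SimulationResult:
    """Sampled trajectory of a :func:`simulate` run (arrays share length)."""

    t: np.ndarray
    V: np.ndarray
    n: np.ndarray
    m: np.ndarray
    h: np.ndarray
    g_K: np.ndarray
    g_Na: np.ndarray

    @property
    def final_state(self) -> MembraneState:
        return MembraneState(t=float(self.t[-1]), V=float(self.V[-1]),
                             n=float(self.n[-1]), m=float(self.m[-1]),
                             h=float(self.h[-1]))


def _integrate_segment(k, consts, seg, y0, t0, t1, t_eval, rtol, atol):
    """Integrate one drive segment; y0 = (V, n, m, h) at t0.

    Returns (samples, y_end) where samples is a (len(t_eval), 4) array of
    (V, n, m, h) at the requested times.
    """
    if seg.kind == "clamp_v":
        Vc = seg.value
        rates = rates_from_voltage(k, Vc)

        def rhs(t, y):
            return gating_derivatives(y[0], y[1], y[2], rates)

        y_gates = y0[1:]
        sol = solve_ivp(rhs, (t0, t1), y_gates, method="LSODA",
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(sol.message, params=k)
        if len(t_eval):
            g = sol.sol(t_eval).T
            samples = np.column_stack([np.full(len(t_eval), Vc), g])
        else:
            samples = np.empty((0, 4))
        y_end = np.concatenate([[Vc], sol.y[:, -1]])
        return samples, y_end

    I_app = seg.value if seg.kind == "clamp_i" else 0.0

    def rhs(t, y):
        V, n, m, h = y
        rates = rates_from_voltage(k, V)
        dV = membrane_derivative(V, n, m, h, consts, I_app)
        dn, dm, dh = gating_derivatives(n, m, h, rates)
        return (dV, dn, dm, dh)

    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA",
                    rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise IntegrationError(sol.message, params=k)
    samples = sol.sol(t_eval).T if len(t_eval) else np.empty((0, 4))
    return samples, sol.y[:, -1]


def simulate(k: VoltageDependencyParams,
             consts: MembraneConstants,
             segments: Sequence[Segment],
             t_grid: np.ndarray,
             initial_state: MembraneState | None = None,
             rtol: float = 1e-6,
             atol: float = 1e-8) -> SimulationResult:
    """Integrate the membrane system under a piecewise drive schedule.

    ``t_grid`` (ms, strictly increasing, relative to the start of the
    first segment) gives the exact output sample times.  Under a
    clamped-V segment only the three gating ODEs are integrated and the
    output voltage equals the clamp value exactly; otherwise the full
    four-dimensional system is integrated with an adaptive solver
    (LSODA, dense output).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    total = sum(s.duration_ms for s in segments)
    if t_grid[0] < 0 or t_grid[-1] > total + 1e-9:
        raise ValueError("t_grid must lie within the schedule duration")

    if initial_state is None:
        n0, m0, h0 = RESTING_GATES
        initial_state = MembraneState(t=0.0, V=0.0, n=n0, m=m0, h=h0)

    y = np.array([initial_state.V, initial_state.n,
                  initial_state.m, initial_state.h], dtype=float)
    out = np.empty((len(t_grid), 4))
    t0 = 0.0
    cursor = 0
    for i, seg in enumerate(segments):
        t1 = t0 + seg.duration_ms
        if seg.v_step:
            y[0] += seg.v_step
        last = i == len(segments) - 1
        # samples in (t0, t1]; the very first grid point (t_grid[0] == t0
        # of the first segment) reports the post-step initial state.
        hi = len(t_grid) if last else np.searchsorted(t_grid, t1, side="right")
        t_eval = t_grid[cursor:hi]
        lead = 0
        if cursor == 0 and len(t_eval) and t_eval[0] <= t0:
            V0 = seg.value if seg.kind == "clamp_v" else y[0]
            out[0] = [V0, y[1], y[2], y[3]]
            t_eval = t_eval[1:]
            lead = 1
        t_eval = np.minimum(t_eval, t1)  # guard fp rounding at the end
        samples, y = _integrate_segment(k, consts, seg, y, t0, t1,
                                        t_eval, rtol, atol)
        out[cursor + lead:hi] = samples
        cursor = hi
        t0 = t1

    V, n, m, h = out.T
    # gates are probabilities; the solver may overshoot [0, 1] by up to
    # its tolerance, so nudge samples back inside
    n, m, h = (np.clip(x, 0.0, 1.0) for x in (n, m, h))
    g_K, g_Na = conductances(n, m, h, consts)
    return SimulationResult(t=t_grid.copy(), V=V, n=n, m=m, h=h,
                            g_K=g_K, g_Na=g_Na)


def to_modern_convention(V_original, E_rest: float = -65.0):
    """Convert original-convention displacement V to modern membrane
    potential E = E_rest - V (so depolarization raises E)."""
    return E_rest - np.asarray(V_original, dtype=float)
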