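"""Experimental drive schedules applied to the membrane model.

Five protocols are provided: the standard voltage clamp (the data-fitting
protocol) plus four advanced stimulus schedules — anode break release,
threshold excitation, positive phase depolarization, and oscillation
induction.  Each maps a voltage-dependency parameter vector to recorded
output traces.  All voltages use the original sign convention of
:mod:`hhabc.model` (depolarization of ``d`` mV means ``V = -d``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

from .model import (
    RESTING_GATES,
    IntegrationError,
    MembraneConstants,
    MembraneState,
    Segment,
    VoltageDependencyParams,
    rates_from_voltage,
    simulate,
)

__all__ = [
    "ConductanceTrace",
    "VoltageTrace",
    "ProtocolSpec",
    "settle",
    "run_voltage_clamp",
    "clamped_conductance_matrix",
    "run_anode_break",
    "run_threshold_excitation",
    "run_positive_phase",
    "run_oscillation_induction",
    "detect_ap",
    "AP_THRESHOLD_MV",
    "SETTLE_MS",
    "THRESHOLD_DEPOLARIZATIONS",
    "POSITIVE_PHASE_DELAYS",
    "OSCILLATION_AMPLITUDE",
    "OSCILLATION_UNITS",
]

#: Default action-potential detection threshold (mV of depolarization
#: displacement).  Responses are bimodal (~90-100 mV full spike vs a
#: few-mV subthreshold decay), so any mid-range cut is robust.
AP_THRESHOLD_MV = 50.0

#: Pre-stimulus free-run duration used by the advanced protocols (ms).
SETTLE_MS = 1000.0

THRESHOLD_DEPOLARIZATIONS = (-10.0, 2.0, 5.0, 6.0, 7.0)
POSITIVE_PHASE_DELAYS = (5.0, 6.0, 8.0)

#: Sustained current-clamp amplitude for oscillation induction, stored
#: with the units exactly as printed in the protocol description.  The
#: magnitude is physiologically anomalous in mA/cm^2 (squid-axon-era
#: stimuli are uA/cm^2-scale); the unit system is configurable and the
#: printed reading is the default.
OSCILLATION_AMPLITUDE = -1.49
OSCILLATION_UNITS = "mA/cm2"

_UNIT_TO_UA = {"mA/cm2": 1000.0, "uA/cm2": 1.0}


@dataclass(frozen=True)
class ConductanceTrace:
    """Sampled conductance time series for one species at one clamp step."""

    t: np.ndarray                 # ms
    g: np.ndarray                 # mS/cm^2
    species: str                  # "K" or "Na"
    depolarization_mV: float

    def __post_init__(self):
        if len(self.t) != len(self.g):
            raise ValueError("t and g must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass(frozen=True)
class VoltageTrace:
    """Sampled membrane-voltage time series (original convention)."""

    t: np.ndarray
    V: np.ndarray
    protocol: str = ""

    def __post_init__(self):
        if len(self.t) != len(self.V):
            raise ValueError("t and V must have equal length")
        if len(self.t) == 0:
            raise ValueError("trace must be non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of a drive schedule (for config files)."""

    name: str
    settle_ms: float
    segments: tuple
    sample_interval_ms: float

    def __post_init__(self):
        if not self.sample_interval_ms > 0:
            raise ValueError("sample_interval_ms must be positive")


def _grid(duration_ms: float, dt: float) -> np.ndarray:
    n = int(round(duration_ms / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _resting_state() -> MembraneState:
    n0, m0, h0 = RESTING_GATES
    return MembraneState(t=0.0, V=0.0, n=n0, m=m0, h=h0)


def settle(k: VoltageDependencyParams,
           consts: MembraneConstants,
           settle_ms: float = SETTLE_MS,
           rtol: float = 1e-6, atol: float = 1e-8) -> MembraneState:
    """Free-run from the resting state until steady for the given
    parametrization; returns the settled state (time reset to 0)."""
    res = simulate(k, consts, [Segment(settle_ms, "free")],
                   np.array([0.0, settle_ms]), initial_state=_resting_state(),
                   rtol=rtol, atol=atol)
    st = res.final_state
    return MembraneState(t=0.0, V=st.V, n=st.n, m=st.m, h=st.h)


def run_voltage_clamp(k: VoltageDependencyParams,
                      depolarization: float,
                      consts: MembraneConstants | None = None,
                      duration_ms: float = 12.0,
                      sample_interval_ms: float = 0.1,
                      initial_state: MembraneState | None = None,
                      rtol: float = 1e-6, atol: float = 1e-8):
    """Clamp V to ``-depolarization`` and record both conductances.

    Starts from the fixed configured resting gating values (not a
    per-parameter steady state) and integrates a 12 ms time course,
    sampling every 0.1 ms (121 samples by default).  Returns the
    potassium and sodium :class:`ConductanceTrace` pair.
    """
    if not np.isfinite(depolarization):
        raise ValueError("depolarization must be finite")
    consts = consts or MembraneConstants()
    if initial_state is None:
        initial_state = _resting_state()
    t_grid = _grid(duration_ms, sample_interval_ms)
    res = simulate(k, consts, [Segment(duration_ms, "clamp_v", -depolarization)],
                   t_grid, initial_state=initial_state, rtol=rtol, atol=atol)
    gK = ConductanceTrace(t=res.t, g=res.g_K, species="K",
                          depolarization_mV=depolarization)
    gNa = ConductanceTrace(t=res.t, g=res.g_Na, species="Na",
                           depolarization_mV=depolarization)
    return gK, gNa


def clamped_conductance_matrix(k: VoltageDependencyParams,
                               depolarizations: Sequence[float],
                               species: str,
                               t_eval: np.ndarray,
                               consts: MembraneConstants | None = None,
                               rtol: float = 1e-6, atol: float = 1e-8) -> np.ndarray:
    """Conductance of one species under M simultaneous voltage clamps.

    Stacks the (mutually independent) clamped-gate ODEs of all M
    depolarizations into one system and integrates it with a single
    adaptive-solver call — the fast path used by the ABC simulators.
    Returns an (M, len(t_eval)) array; row order follows
    ``depolarizations``.  Agrees with :func:`run_voltage_clamp` to
    solver tolerance.
    """
    consts = consts or MembraneConstants()
    if species not in ("K", "Na"):
        raise ValueError("species must be 'K' or 'Na'")
    t_eval = np.asarray(t_eval, dtype=float)
    M = len(depolarizations)
    if M == 0:
        raise ValueError("need at least one depolarization")
    V = -np.asarray(depolarizations, dtype=float)
    r = rates_from_voltage(k, V)  # arrays of length M
    n0, m0, h0 = RESTING_GATES

    if species == "K":
        a, b = np.asarray(r.alpha_n), np.asarray(r.beta_n)
        y0 = np.full(M, n0)
        decay = -(a + b)

        def rhs(y, t):
            return a + decay * y
    else:
        am, bm = np.asarray(r.alpha_m), np.asarray(r.beta_m)
        ah, bh = np.asarray(r.alpha_h), np.asarray(r.beta_h)
        y0 = np.concatenate([np.full(M, m0), np.full(M, h0)])
        gain = np.concatenate([am, ah])
        decay = -np.concatenate([am + bm, ah + bh])

        def rhs(y, t):
            return gain + decay * y

    # the stacked system is diagonal-linear; a banded analytic Jacobian
    # keeps the stiff solver from estimating an MxM one numerically
    jac_band = decay[None, :]

    def jac(y, t):
        return jac_band

    # odeint needs the initial time on the grid; prepend it if absent.
    prepend = t_eval[0] > 0.0
    ts = np.concatenate([[0.0], t_eval]) if prepend else t_eval
    y, info = odeint(rhs, y0, ts, rtol=rtol, atol=atol, full_output=True,
                     Dfun=jac, ml=0, mu=0, col_deriv=False)
    if info["message"] != "Integration successful.":
        raise IntegrationError(info["message"], params=k)
    y = np.clip((y[1:] if prepend else y).T, 0.0, 1.0)
    if species == "K":
        return consts.gbar_K * y ** 4
    m, h = y[:M], y[M:]
    return consts.gbar_Na * m ** 3 * h


def run_anode_break(k: VoltageDependencyParams,
                    consts: MembraneConstants | None = None,
                    clamp_mV: float = 30.0,
                    clamp_ms: float = 200.0,
                    record_ms: float = 30.0,
                    sample_interval_ms: float = 0.1,
                    settle_ms: float = SETTLE_MS) -> VoltageTrace:
    """Anode-break excitation: settle, clamp V 30 mV below rest
    (``V = +30``) for 200 ms, release, and record the free-running
    voltage every 0.1 ms for 30 ms (t = 0 at release)."""
    consts = consts or MembraneConstants()
    st = settle(k, consts, settle_ms)
    grid = _grid(record_ms, sample_interval_ms) + clamp_ms
    res = simulate(k, consts,
                   [Segment(clamp_ms, "clamp_v", clamp_mV),
                    Segment(record_ms, "free")],
                   grid, initial_state=st)
    return VoltageTrace(t=res.t - clamp_ms, V=res.V, protocol="anode_break")


def run_threshold_excitation(k: VoltageDependencyParams,
                             depolarization: float,
                             consts: MembraneConstants | None = None,
                             record_ms: float = 10.0,
                             sample_interval_ms: float = 0.01,
                             settle_ms: float = SETTLE_MS) -> VoltageTrace:
    """Instantaneous depolarization step then 10 ms free run at 0.01 ms
    sampling.  ``depolarization`` of d steps V by -d (negative d
    hyperpolarizes)."""
    consts = consts or MembraneConstants()
    st = settle(k, consts, settle_ms)
    grid = _grid(record_ms, sample_interval_ms)
    res = simulate(k, consts,
                   [Segment(record_ms, "free", v_step=-depolarization)],
                   grid, initial_state=st)
    return VoltageTrace(t=res.t, V=res.V, protocol="threshold_excitation")


def run_positive_phase(k: VoltageDependencyParams,
                       delay_ms: float,
                       consts: MembraneConstants | None = None,
                       first_step_mV: float = 15.0,
                       second_step_mV: float = 90.0,
                       total_ms: float = 15.0,
                       sample_interval_ms: float = 0.01,
                       settle_ms: float = SETTLE_MS) -> VoltageTrace:
    """Positive-phase depolarization: a 15 mV step, a free run of
    ``delay_ms`` (5, 6 or 8 ms), an additional 90 mV step, and a free
    run for the remainder of a 15 ms total recorded time course."""
    if not 0 < delay_ms < total_ms:
        raise ValueError("delay_ms must lie inside the recorded time course")
    consts = consts or MembraneConstants()
    st = settle(k, consts, settle_ms)
    grid = _grid(total_ms, sample_interval_ms)
    res = simulate(k, consts,
                   [Segment(delay_ms, "free", v_step=-first_step_mV),
                    Segment(total_ms - delay_ms, "free", v_step=-second_step_mV)],
                   grid, initial_state=st)
    return VoltageTrace(t=res.t, V=res.V, protocol="positive_phase")


def run_oscillation_induction(k: VoltageDependencyParams,
                              consts: MembraneConstants | None = None,
                              amplitude: float = OSCILLATION_AMPLITUDE,
                              units: str = OSCILLATION_UNITS,
                              clamp_ms: float = 15.0,
                              release_ms: float = 10.0,
                              sample_interval_ms: float = 0.1,
                              settle_ms: float = SETTLE_MS) -> VoltageTrace:
    """Sustained current clamp for 15 ms, then a 10 ms free run, with
    0.1 ms sampling over the whole 25 ms."""
    if units not in _UNIT_TO_UA:
        raise ValueError(f"units must be one of {sorted(_UNIT_TO_UA)}")
    consts = consts or MembraneConstants()
    amp_uA = amplitude * _UNIT_TO_UA[units]
    st = settle(k, consts, settle_ms)
    grid = _grid(clamp_ms + release_ms, sample_interval_ms)
    segments = [Segment(clamp_ms, "clamp_i", amp_uA),
                Segment(release_ms, "free")]
    res = simulate(k, consts, segments, grid, initial_state=st)
    return VoltageTrace(t=res.t, V=res.V, protocol="oscillation_induction")


def run_protocol(name: str, k: VoltageDependencyParams,
                 consts: MembraneConstants | None = None, **kwargs) -> VoltageTrace:
    """Dispatch an advanced protocol by name."""
    runners = {
        "anode_break": run_anode_break,
        "threshold_excitation": run_threshold_excitation,
        "positive_phase": run_positive_phase,
        "oscillation_induction": run_oscillation_induction,
    }
    if name not in runners:
        raise ValueError(f"unknown protocol {name!r}; choose from {sorted(runners)}")
    return runners[name](k, consts=consts, **kwargs)


def detect_ap(trace: VoltageTrace, threshold_mV: float = AP_THRESHOLD_MV) -> bool:
    """True iff the peak depolarization displacement (-V, original
    convention) exceeds ``threshold_mV`` at any recorded time."""
    if len(trace.t) == 0:
        raise ValueError("trace must be non-empty")
    return bool(np.max(-trace.V) > threshold_mV)
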