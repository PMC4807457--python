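"""Orchestration of the three study stages.

1. simplified-model fits: per-depolarization posteriors over the six
   gating rates;
2. full-model fits: per-species posteriors over the voltage-dependency
   constants, with identifiability classification;
3. protocol studies: posterior-ensemble responses to the advanced
   stimulus protocols.

Every stage is deterministic given (config, seed) and consumes only
in-repo inputs (datasets from :mod:`hhabc.synthetic` or equivalent
CSVs on disk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import odeint

from . import abc_smc
from .abc_smc import (
    AbcResult,
    default_kernel,
    default_prior,
    distance_multi,
    param_names_for,
    run_abc_smc,
)
from .model import (
    RESTING_GATES,
    IntegrationError,
    MembraneConstants,
    VoltageDependencyParams,
)
from .posterior import (
    ClassificationThresholds,
    classify_identifiability,
    ensemble_protocol_response,
    output_variation_scores,
    pairwise_correlations,
    summarize,
)
from .protocols import (
    ConductanceTrace,
    clamped_conductance_matrix,
)

__all__ = [
    "RunConfig",
    "reduced_test_config",
    "make_simplified_simulator",
    "make_full_simulator",
    "fit_simplified",
    "fit_full",
    "run_simplified_study",
    "run_full_study",
    "run_protocol_study",
    "write_report",
]

_SPECIES_GATES = {"K": ("alpha_n", "beta_n"),
                  "Na": ("alpha_m", "beta_m", "alpha_h", "beta_h")}


@dataclass
class RunConfig:
    """Settings shared by the study runners (seed is mandatory)."""

    seed: int
    model_form: str = "full"               # "simplified" | "full"
    species: tuple = ("K", "Na")
    n_particles: int = abc_smc.DEFAULT_N_PARTICLES
    max_draws: int = abc_smc.DEFAULT_MAX_DRAWS
    tau: float = abc_smc.DEFAULT_TAU
    max_generations: int = 60
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    out_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


def reduced_test_config(seed: int, **overrides) -> RunConfig:
    """Named fast profile exercising the full path in minutes."""
    cfg = RunConfig(seed=seed, n_particles=30, max_draws=2000,
                    max_generations=20)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# Simulators mapping a parameter vector to a data distance

def _constant_rate_conductance(theta, gate_names, species, t_eval,
                               consts: MembraneConstants):
    """Integrate the clamped-gate ODEs with *constant* (fitted) rates.

    Used by simplified-model fits, where the rates at the experimental
    depolarization are themselves the free parameters.
    """
    vals = dict(zip(gate_names, theta))
    n0, m0, h0 = RESTING_GATES
    prepend = t_eval[0] > 0.0
    ts = np.concatenate([[0.0], t_eval]) if prepend else t_eval
    if species == "K":
        a, b = vals["alpha_n"], vals["beta_n"]
        y, info = odeint(lambda y, t: a * (1.0 - y) - b * y, [n0], ts,
                         rtol=1e-6, atol=1e-8, full_output=True)
        if info["message"] != "Integration successful.":
            raise IntegrationError(info["message"])
        y = y[1:] if prepend else y
        return consts.gbar_K * y[:, 0] ** 4
    am, bm = vals["alpha_m"], vals["beta_m"]
    ah, bh = vals["alpha_h"], vals["beta_h"]

    def rhs(y, t):
        m, h = y
        return (am * (1.0 - m) - bm * m, ah * (1.0 - h) - bh * h)

    y, info = odeint(rhs, [m0, h0], ts, rtol=1e-6, atol=1e-8, full_output=True)
    if info["message"] != "Integration successful.":
        raise IntegrationError(info["message"])
    y = y[1:] if prepend else y
    m, h = y[:, 0], y[:, 1]
    return consts.gbar_Na * m ** 3 * h


def make_simplified_simulator(observed: ConductanceTrace,
                              consts: MembraneConstants | None = None):
    """theta -> RMSE of one constant-rate clamp trace against one
    observed trace (rates for the observed species only)."""
    consts = consts or MembraneConstants()
    species = observed.species
    gate_names = _SPECIES_GATES[species]
    obs_g = np.asarray(observed.g, dtype=float)
    obs_t = np.asarray(observed.t, dtype=float)

    def simulator(theta):
        g = _constant_rate_conductance(theta, gate_names, species,
                                       obs_t, consts)
        # vectorized RMSE; equals distance_single on the shared grid
        return float(np.sqrt(np.mean((obs_g - g) ** 2)))

    return simulator


def make_full_simulator(observed: list,
                        consts: MembraneConstants | None = None,
                        base: VoltageDependencyParams | None = None):
    """theta -> multi-trace RMSE of the voltage-dependent model.

    ``observed`` holds traces of a single species; theta overlays that
    species' k constants on the default vector.  All traces are
    simulated in one stacked adaptive-solver call when they share a
    time grid.
    """
    consts = consts or MembraneConstants()
    base = base or VoltageDependencyParams()
    if not observed:
        raise ValueError("need at least one observed trace")
    species = observed[0].species
    if any(tr.species != species for tr in observed):
        raise ValueError("full-model fits are per species")
    names = param_names_for("full", species)
    depols = [tr.depolarization_mV for tr in observed]
    grids = [tr.t for tr in observed]
    shared = all(len(g) == len(grids[0]) and np.allclose(g, grids[0])
                 for g in grids)

    obs_mat = np.vstack([tr.g for tr in observed]) if shared else None

    def simulator(theta):
        k = base.with_updates(**dict(zip(names, map(float, theta))))
        if shared:
            mat = clamped_conductance_matrix(k, depols, species, grids[0],
                                             consts=consts)
            # vectorized form of distance_multi on the shared grid
            return float(np.mean(np.sqrt(np.mean((obs_mat - mat) ** 2,
                                                 axis=1))))
        sims = []
        for j, tr in enumerate(observed):
            mat = clamped_conductance_matrix(k, [depols[j]], species,
                                             tr.t, consts=consts)
            sims.append(ConductanceTrace(t=tr.t, g=mat[0], species=species,
                                         depolarization_mV=depols[j]))
        return distance_multi(observed, sims)

    return simulator


# ---------------------------------------------------------------------------
# Fits

def fit_simplified(observed: ConductanceTrace, cfg: RunConfig,
                   consts: MembraneConstants | None = None,
                   rng: np.random.Generator | None = None) -> AbcResult:
    """ABC-SMC over the gating rates of one species at one clamp step."""
    names = param_names_for("simplified", observed.species)
    prior, kernel = default_prior(names), default_kernel(names)
    sim = make_simplified_simulator(observed, consts)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return run_abc_smc(sim, prior, kernel, n_particles=cfg.n_particles,
                       max_draws=cfg.max_draws, tau=cfg.tau, rng=rng,
                       max_generations=cfg.max_generations, seed=cfg.seed)


def fit_full(observed: list, cfg: RunConfig,
             consts: MembraneConstants | None = None,
             rng: np.random.Generator | None = None) -> AbcResult:
    """ABC-SMC over the voltage-dependency constants of one species
    against all of its clamp traces at once."""
    species = observed[0].species
    names = param_names_for("full", species)
    prior, kernel = default_prior(names), default_kernel(names)
    sim = make_full_simulator(observed, consts)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return run_abc_smc(sim, prior, kernel, n_particles=cfg.n_particles,
                       max_draws=cfg.max_draws, tau=cfg.tau, rng=rng,
                       max_generations=cfg.max_generations, seed=cfg.seed)


# ---------------------------------------------------------------------------
# Studies

def run_simplified_study(traces: list, cfg: RunConfig,
                         consts: MembraneConstants | None = None) -> dict:
    """Per-depolarization simplified-model fits for every trace.

    Returns {(species, depolarization): {"result", "summary"}}; traces
    of a missing species are simply absent (callers may warn).
    """
    if not traces:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for tr in traces:
        if tr.species not in cfg.species:
            continue
        res = fit_simplified(tr, cfg, consts, rng=rng)
        names = param_names_for("simplified", tr.species)
        summary = summarize(res.final, default_prior(names))
        out[(tr.species, tr.depolarization_mV)] = {
            "result": res, "summary": summary}
    if not out:
        raise ValueError("no traces matched the configured species")
    return out


def run_full_study(traces: list, cfg: RunConfig,
                   consts: MembraneConstants | None = None) -> dict:
    """Per-species full-model fit + identifiability report.

    Returns {species: {"result", "summary", "report", "correlations",
    "output_variation"}}.
    """
    if not traces:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for species in cfg.species:
        obs = [tr for tr in traces if tr.species == species]
        if not obs:
            continue
        res = fit_full(obs, cfg, consts, rng=rng)
        prior = default_prior(param_names_for("full", species))
        sim = make_full_simulator(obs, consts)
        reported_d = sim(np.array([getattr(VoltageDependencyParams(), n)
                                   for n in prior.names]))
        summary = summarize(res.final, prior, reported_distance=reported_d)
        corr = pairwise_correlations(res.final)
        ov = output_variation_scores(res.final)
        report = classify_identifiability(summary, corr, ov, prior,
                                          cfg.thresholds)
        out[species] = {"result": res, "summary": summary, "report": report,
                        "correlations": corr, "output_variation": ov}
    if not out:
        raise ValueError("no traces matched the configured species")
    return out


DEFAULT_PROTOCOL_SET = (
    ("anode_break", {}),
    ("threshold_excitation", {"depolarization": 7.0}),
    ("positive_phase", {"delay_ms": 5.0}),
    ("oscillation_induction", {}),
)


def run_protocol_study(populations: dict, protocols=DEFAULT_PROTOCOL_SET,
                       consts: MembraneConstants | None = None,
                       settle_ms: float | None = None) -> dict:
    """Posterior-ensemble responses for each species population.

    ``populations`` maps species -> Population (full-model fit); the
    other species is held at default values by construction of the
    overlay.  Returns {(species, protocol): EnsembleResponse}.
    """
    out = {}
    for species, pop in populations.items():
        for name, kwargs in protocols:
            kw = dict(kwargs)
            if settle_ms is not None:
                kw["settle_ms"] = settle_ms
            out[(species, name)] = ensemble_protocol_response(
                pop, name, consts=consts, **kw)
    return out


# ---------------------------------------------------------------------------
# Reporting

def _summary_payload(summary) -> dict:
    return {
        "params": [
            {"parameter": n, "mean": summary.mean[n],
             "variance": summary.variance[n],
             "p5": summary.p5[n], "p95": summary.p95[n]}
            for n in summary.param_names],
        "distance_min": summary.distance_min,
        "distance_max": summary.distance_max,
        "epsilon": summary.epsilon,
        "reported_distance": summary.reported_distance,
    }


def write_report(study: dict, out_dir, cfg: RunConfig) -> Path:
    """Serialize a full-study result to JSON + per-species CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": {"seed": cfg.seed, "n_particles": cfg.n_particles,
                          "max_draws": cfg.max_draws, "tau": cfg.tau},
               "species": {}}
    for species, block in study.items():
        res, summary, report = block["result"], block["summary"], block["report"]
        payload["species"][species] = {
            "summary": _summary_payload(summary),
            "labels": report.labels,
            "relative_spread": report.relative_spread,
            "max_abs_correlation": {k: (None if not np.isfinite(v) else v)
                                    for k, v in report.max_abs_correlation.items()},
            "output_variation": report.output_variation,
            "epsilon_history": res.epsilon_history,
            "draws_per_generation": res.draws_per_generation,
        }
        lines = ["parameter,mean,variance,p5,p95"]
        for n, mean, var, p5, p95 in summary.as_table():
            lines.append(f"{n},{mean!r},{var!r},{p5!r},{p95!r}")
        (out / f"summary_{species}.csv").write_text("\n".join(lines) + "\n")
        (out / f"population_{species}.json").write_text(res.final.to_json())
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
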