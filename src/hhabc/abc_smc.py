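"""Sequential Monte Carlo ABC with an adaptive tolerance schedule.

The sampler maintains a fixed-size weighted particle population.
Generation 0 is drawn from the prior with uniform weights; each later
generation resamples by weight from its predecessor, perturbs with a
Gaussian kernel (redrawing until inside the prior box), simulates, and
accepts iff the trace distance is within the current tolerance.

The tolerance schedule is adaptive: each generation first tries
``0.5 * eps_prev``; if the population cannot be filled within the draw
budget, the tolerance backtracks halfway toward ``eps_prev``
(``eps <- eps_prev + 0.5 * d_eps``), and the run terminates once the
attempted decrease ``|d_eps|`` falls below the no-improvement threshold
``tau``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .model import K_PARAMS_POTASSIUM, K_PARAMS_SODIUM

__all__ = [
    "PriorSpec",
    "KernelSpec",
    "Population",
    "ScheduleState",
    "AbcResult",
    "default_prior",
    "default_kernel",
    "distance_single",
    "distance_multi",
    "sample_prior",
    "perturb",
    "advance_schedule",
    "run_abc_smc",
    "DEFAULT_N_PARTICLES",
    "DEFAULT_MAX_DRAWS",
    "DEFAULT_TAU",
]

DEFAULT_N_PARTICLES = 100
DEFAULT_MAX_DRAWS = 10_000
DEFAULT_TAU = 0.003

# (prior lower, prior upper, kernel variance) per parameter name, for
# both the simplified-model rates and the full-model k constants.
_PRIOR_TABLE = {
    **{name: (0.0, 1.0, 0.1) for name in ("alpha_n", "beta_n")},
    **{name: (0.0, 10.0, 1.0)
       for name in ("alpha_m", "beta_m", "alpha_h", "beta_h")},
    **{name: (0.0, 1.0, 0.1)
       for name in ("k_an1", "k_bn1", "k_am1", "k_ah1")},
    "k_bm1": (0.0, 10.0, 1.0),
    **{name: (1.0, 100.0, 10.0)
       for name in ("k_an3", "k_bn2", "k_am3", "k_bm2", "k_ah2", "k_bh2")},
    **{name: (0.0, 100.0, 10.0) for name in ("k_an2", "k_am2", "k_bh1")},
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (lower, upper) pair per parameter."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if not (len(self.names) == len(lo) == len(hi)):
            raise ValueError("names and bounds must have equal length")
        if np.any(lo >= hi):
            raise ValueError("every prior must have lower < upper")

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


@dataclass(frozen=True)
class KernelSpec:
    """Zero-mean Gaussian perturbation kernel, one variance per parameter."""

    variances: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "variances", v)
        if np.any(v <= 0):
            raise ValueError("kernel variances must be positive")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variances)


def default_prior(names: Sequence[str]) -> PriorSpec:
    """Prior box for the given parameter names (see module table):
    tight uniform(0, 1) boxes around order-1 rates and scalings, wider
    boxes for voltage offsets and exponent denominators."""
    lo, hi = zip(*[_PRIOR_TABLE[n][:2] for n in names])
    return PriorSpec(names=tuple(names), lower=np.array(lo), upper=np.array(hi))


def default_kernel(names: Sequence[str]) -> KernelSpec:
    """Matching kernel: zero-centred normal with variance roughly 10%
    of the associated prior width."""
    return KernelSpec(variances=np.array([_PRIOR_TABLE[n][2] for n in names]))


def param_names_for(model_form: str, species: str) -> tuple:
    """Parameter vector layout for a (model form, species) fit."""
    if model_form == "simplified":
        return ("alpha_n", "beta_n") if species == "K" else \
            ("alpha_m", "beta_m", "alpha_h", "beta_h")
    if model_form == "full":
        return K_PARAMS_POTASSIUM if species == "K" else K_PARAMS_SODIUM
    raise ValueError("model_form must be 'simplified' or 'full'")


# ---------------------------------------------------------------------------
# Distances

def distance_single(observed, simulated, *, squared: bool = False) -> float:
    """Root-mean-square error between two traces on identical time grids.

    Set ``squared=True`` for the plain mean-squared-error variant.
    Mismatched grids raise — the simulator must be evaluated at the
    observed sample times; no silent interpolation.
    """
    t_obs, g_obs = np.asarray(observed.t), np.asarray(observed.g)
    t_sim, g_sim = np.asarray(simulated.t), np.asarray(simulated.g)
    if t_obs.shape != t_sim.shape or not np.allclose(t_obs, t_sim, atol=1e-9):
        raise ValueError("trace time grids do not match")
    mse = float(np.mean((g_obs - g_sim) ** 2))
    return mse if squared else float(np.sqrt(mse))


def distance_multi(observed: Sequence, simulated: Sequence, *,
                   squared: bool = False) -> float:
    """Per-trace distance averaged over M matched trace pairs."""
    if len(observed) == 0:
        raise ValueError("need at least one trace pair")
    if len(observed) != len(simulated):
        raise ValueError("observed and simulated lists differ in length")
    return float(np.mean([distance_single(o, s, squared=squared)
                          for o, s in zip(observed, simulated)]))


# ---------------------------------------------------------------------------
# Sampling primitives

def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(prior.lower, prior.upper)


def perturb(theta: np.ndarray, kernel: KernelSpec, prior: PriorSpec,
            rng: np.random.Generator, max_tries: int = 100_000) -> np.ndarray:
    """Jitter ``theta`` with the Gaussian kernel, redrawing until the
    proposal lands inside the prior box."""
    if not prior.contains(theta):
        raise ValueError("theta must start inside the prior support")
    for _ in range(max_tries):
        proposal = theta + rng.normal(0.0, kernel.sd)
        if prior.contains(proposal):
            return proposal
    raise RuntimeError("no legal perturbation found; kernel is pathological "
                       "relative to the prior box")


def _kernel_density(deltas: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Unnormalized product-Gaussian kernel density for rows of deltas."""
    z = deltas / kernel.sd
    return np.exp(-0.5 * np.sum(z * z, axis=1))


# ---------------------------------------------------------------------------
# Populations

@dataclass
class Population:
    """A weighted particle set estimating the posterior at tolerance eps."""

    thetas: np.ndarray          # (N, dim)
    weights: np.ndarray         # (N,), sums to 1
    distances: np.ndarray       # (N,)
    epsilon: float              # tolerance met (inf for generation 0)
    generation: int
    n_draws: int                # proposals attempted to fill this population
    param_names: tuple

    @property
    def size(self) -> int:
        return len(self.weights)

    def theta_dict(self, i: int) -> dict:
        return dict(zip(self.param_names, self.thetas[i]))

    def to_json(self) -> str:
        return json.dumps({
            "generation": self.generation,
            "epsilon": self.epsilon,
            "n_draws": self.n_draws,
            "param_names": list(self.param_names),
            "thetas": self.thetas.tolist(),
            "weights": self.weights.tolist(),
            "distances": self.distances.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "Population":
        d = json.loads(text)
        return cls(thetas=np.array(d["thetas"], dtype=float),
                   weights=np.array(d["weights"], dtype=float),
                   distances=np.array(d["distances"], dtype=float),
                   epsilon=float(d["epsilon"]),
                   generation=int(d["generation"]),
                   n_draws=int(d["n_draws"]),
                   param_names=tuple(d["param_names"]))


@dataclass
class ScheduleState:
    """Bookkeeping for the adaptive tolerance schedule."""

    epsilon_t: float
    epsilon_prev: float
    delta_eps: float
    tau: float
    max_draws: int


def advance_schedule(state: ScheduleState, succeeded: bool):
    """One adaptive-schedule transition.

    On success the next generation starts at half the achieved
    tolerance.  On failure the current target backtracks halfway toward
    the previous tolerance; returns None (terminate) once the attempted
    decrease falls below ``tau``.
    """
    if succeeded:
        eps_prev = state.epsilon_t
        if 0.5 * eps_prev < state.tau:
            return None   # next targeted decrease already below tau
        return ScheduleState(epsilon_t=0.5 * eps_prev, epsilon_prev=eps_prev,
                             delta_eps=-0.5 * eps_prev, tau=state.tau,
                             max_draws=state.max_draws)
    delta = state.epsilon_t - state.epsilon_prev   # negative
    if abs(delta) < state.tau:
        return None
    new_delta = 0.5 * delta
    new_eps = state.epsilon_prev + new_delta
    return ScheduleState(epsilon_t=new_eps, epsilon_prev=state.epsilon_prev,
                         delta_eps=new_delta, tau=state.tau,
                         max_draws=state.max_draws)


@dataclass
class AbcResult:
    """All populations of a run plus schedule/acceptance metadata."""

    populations: list
    epsilon_history: list
    draws_per_generation: list
    seed: int | None = None

    @property
    def final(self) -> Population:
        return self.populations[-1]

    def write_csv(self, csv_path, metadata_path=None) -> None:
        """Flat CSV of every particle of every generation (columns:
        generation, particle_id, weight, distance, then one column per
        parameter), with run metadata in a JSON sidecar."""
        csv_path = Path(csv_path)
        names = self.populations[0].param_names
        lines = ["generation,particle_id,weight,distance,"
                 + ",".join(names)]
        for pop in self.populations:
            for i in range(pop.size):
                vals = ",".join(repr(float(v)) for v in pop.thetas[i])
                lines.append(f"{pop.generation},{i},{pop.weights[i]!r},"
                             f"{pop.distances[i]!r},{vals}")
        csv_path.write_text("\n".join(lines) + "\n")
        if metadata_path is None:
            metadata_path = csv_path.with_suffix(".meta.json")
        Path(metadata_path).write_text(json.dumps({
            "seed": self.seed,
            "epsilon_history": [e if np.isfinite(e) else None
                                for e in self.epsilon_history],
            "draws_per_generation": self.draws_per_generation,
            "param_names": list(names),
            "n_particles": self.populations[0].size,
        }, indent=2))


# ---------------------------------------------------------------------------
# Main sampler

def run_abc_smc(simulator: Callable[[np.ndarray], float | None],
                prior: PriorSpec,
                kernel: KernelSpec,
                *,
                n_particles: int = DEFAULT_N_PARTICLES,
                max_draws: int = DEFAULT_MAX_DRAWS,
                tau: float = DEFAULT_TAU,
                rng: np.random.Generator,
                epsilon0: float | None = None,
                max_generations: int = 60,
                budget_mode: str = "per_particle",
                seed: int | None = None) -> AbcResult:
    """Run adaptive-tolerance ABC-SMC.

    ``simulator(theta)`` must return the distance between the trace
    simulated under ``theta`` and the observed data, or None / raise to
    signal an integration failure (treated as a rejection).

    ``epsilon0`` defaults to the maximum distance among the
    generation-0 prior draws, so the first conditioned generation
    targets half of it.  ``budget_mode`` selects how ``max_draws``
    bounds a generation attempt: "per_particle" (default) allows up to
    ``max_draws`` consecutive rejected proposals for each particle slot
    before declaring the attempt failed; "per_generation" pools the
    budget across the whole population.  Either way a failed attempt
    discards its partial population and retries at the backtracked
    tolerance.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if budget_mode not in ("per_particle", "per_generation"):
        raise ValueError("budget_mode must be 'per_particle' or 'per_generation'")

    def try_simulate(theta):
        try:
            d = simulator(theta)
        except Exception:
            return None
        if d is None or not np.isfinite(d):
            return None
        return float(d)

    # Generation 0: unconditioned prior draws, uniform weights.
    dim = prior.dim
    thetas = np.empty((n_particles, dim))
    dists = np.empty(n_particles)
    draws0 = 0
    for i in range(n_particles):
        while True:
            draws0 += 1
            theta = sample_prior(prior, rng)
            d = try_simulate(theta)
            if d is not None:
                thetas[i], dists[i] = theta, d
                break
    gen0 = Population(thetas=thetas, weights=np.full(n_particles, 1.0 / n_particles),
                      distances=dists, epsilon=float("inf"), generation=0,
                      n_draws=draws0, param_names=prior.names)
    populations = [gen0]
    eps_history = [float("inf")]
    draws_history = [draws0]

    if epsilon0 is None:
        epsilon0 = float(np.max(dists))
    state = ScheduleState(epsilon_t=0.5 * epsilon0, epsilon_prev=epsilon0,
                          delta_eps=-0.5 * epsilon0, tau=tau, max_draws=max_draws)

    generation = 1
    while state is not None and generation <= max_generations:
        prev = populations[-1]
        new_thetas = np.empty((n_particles, dim))
        new_dists = np.empty(n_particles)
        draws = 0
        filled = 0
        tries = 0
        while filled < n_particles:
            if budget_mode == "per_generation" and draws >= max_draws:
                break
            tries += 1
            draws += 1
            idx = rng.choice(prev.size, p=prev.weights)
            theta = perturb(prev.thetas[idx], kernel, prior, rng)
            d = try_simulate(theta)
            if d is not None and d <= state.epsilon_t:
                new_thetas[filled], new_dists[filled] = theta, d
                filled += 1
                tries = 0
            elif budget_mode == "per_particle" and tries >= max_draws:
                break
        if filled == n_particles:
            # Importance weights: w_i proportional to
            # prior(theta_i) / sum_j w_prev_j K(theta_i - theta_j);
            # the prior factor is constant inside the uniform box.
            w = np.empty(n_particles)
            for i in range(n_particles):
                dens = _kernel_density(new_thetas[i] - prev.thetas, kernel)
                w[i] = 1.0 / max(np.dot(prev.weights, dens), 1e-300)
            w /= w.sum()
            pop = Population(thetas=new_thetas, weights=w, distances=new_dists,
                             epsilon=state.epsilon_t, generation=generation,
                             n_draws=draws, param_names=prior.names)
            populations.append(pop)
            eps_history.append(state.epsilon_t)
            draws_history.append(draws)
            state = advance_schedule(state, succeeded=True)
            generation += 1
        else:
            state = advance_schedule(state, succeeded=False)

    return AbcResult(populations=populations, epsilon_history=eps_history,
                     draws_per_generation=draws_history, seed=seed)
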