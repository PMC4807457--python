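"""Synthetic voltage-clamp conductance datasets.

The historical recordings behind the fits (sparse conductance traces at
a ladder of depolarizations, one per ion species) are not deposited in
machine-readable form; this module emulates their statistical structure
by simulating the clamp protocol under a known ground-truth
parametrization, optionally decimating to a sparse digitization-like
grid, and adding seeded Gaussian noise.  The ground truth is always
emitted next to the dataset so parameter-recovery tests are
self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MembraneConstants, VoltageDependencyParams
from .protocols import ConductanceTrace, run_voltage_clamp

__all__ = [
    "SyntheticDatasetSpec",
    "DepolarizationSet",
    "default_depolarization_sets",
    "generate_clamp_dataset",
    "write_dataset",
    "load_dataset",
]

# Representative depolarization ladders (mV) spanning the small
# (|dV| < 10) through large (~100) regimes probed by the historical
# clamp series.  The exact historical magnitudes are not printed in
# machine-readable form anywhere we consume; these are configurable
# defaults, not asserted historical values.  The 6 mV potassium entry
# (the trace with an unreliable published ordinate) is flagged excluded
# by default, leaving M = 11 potassium and M = 12 sodium traces.
_DEFAULT_DEPOLS = (109.0, 100.0, 88.0, 76.0, 63.0, 51.0,
                   38.0, 32.0, 26.0, 19.0, 10.0, 6.0)
_DEFAULT_K_EXCLUSIONS = (6.0,)


@dataclass(frozen=True)
class DepolarizationSet:
    """A per-species depolarization ladder with default exclusions."""

    values: tuple
    excluded: tuple = ()

    @property
    def active(self) -> tuple:
        return tuple(v for v in self.values if v not in self.excluded)


def default_depolarization_sets(K=None, Na=None) -> dict:
    """Default clamp ladders per species; user-supplied lists pass
    through unchanged (with no implicit exclusions)."""
    return {
        "K": DepolarizationSet(tuple(K), ()) if K is not None
        else DepolarizationSet(_DEFAULT_DEPOLS, _DEFAULT_K_EXCLUSIONS),
        "Na": DepolarizationSet(tuple(Na), ()) if Na is not None
        else DepolarizationSet(_DEFAULT_DEPOLS, ()),
    }


@dataclass
class SyntheticDatasetSpec:
    """Recipe for one synthetic clamp dataset.

    noise_sd is interpreted per ``noise_mode``: "absolute" uses it
    directly (mS/cm^2); "relative" scales it by each trace's peak
    amplitude (default 2% of max).
    """

    true_params: VoltageDependencyParams = field(
        default_factory=VoltageDependencyParams)
    depolarizations: dict | None = None      # species -> DepolarizationSet
    duration_ms: float = 12.0
    sample_interval_ms: float = 0.1
    subsample: int = 1                       # keep every subsample-th point
    noise_sd: float = 0.02
    noise_mode: str = "relative"
    seed: int = 0
    species: tuple = ("K", "Na")

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        if self.noise_mode not in ("absolute", "relative"):
            raise ValueError("noise_mode must be 'absolute' or 'relative'")
        if self.depolarizations is None:
            self.depolarizations = default_depolarization_sets()
        for sp in self.species:
            if not self.depolarizations[sp].active:
                raise ValueError(f"no depolarizations left for {sp} after exclusions")


def generate_clamp_dataset(spec: SyntheticDatasetSpec,
                           consts: MembraneConstants | None = None):
    """Simulate noisy clamp traces for every active depolarization.

    Returns ``(traces, truth)`` where ``traces`` is a list of
    :class:`ConductanceTrace` and ``truth`` a JSON-serializable record
    of the generating parameters and spec.  Noise is additive Gaussian
    (seeded); negative conductances are clipped to zero.
    """
    consts = consts or MembraneConstants()
    rng = np.random.default_rng(spec.seed)
    traces = []
    for sp in spec.species:
        for depol in spec.depolarizations[sp].active:
            gK, gNa = run_voltage_clamp(
                spec.true_params, depol, consts=consts,
                duration_ms=spec.duration_ms,
                sample_interval_ms=spec.sample_interval_ms)
            clean = gK if sp == "K" else gNa
            t = clean.t[::spec.subsample]
            g = clean.g[::spec.subsample].copy()
            if spec.noise_sd > 0:
                sd = spec.noise_sd
                if spec.noise_mode == "relative":
                    sd = sd * float(np.max(np.abs(g)))
                g = g + rng.normal(0.0, sd, size=g.shape)
                np.clip(g, 0.0, None, out=g)
            traces.append(ConductanceTrace(t=t, g=g, species=sp,
                                           depolarization_mV=depol))
    truth = {
        "true_params": spec.true_params.as_dict(),
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "noise_mode": spec.noise_mode,
        "subsample": spec.subsample,
        "duration_ms": spec.duration_ms,
        "sample_interval_ms": spec.sample_interval_ms,
        "depolarizations": {
            sp: {"values": list(spec.depolarizations[sp].values),
                 "excluded": list(spec.depolarizations[sp].excluded)}
            for sp in spec.species},
    }
    return traces, truth


def write_dataset(traces, truth, out_dir) -> Path:
    """Write one CSV per trace plus a manifest with the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for tr in traces:
        name = f"{tr.species}_depol_{tr.depolarization_mV:g}.csv"
        df = pd.DataFrame({"time_ms": tr.t, "g": tr.g})
        df["species"] = tr.species
        df["depolarization_mV"] = tr.depolarization_mV
        df.to_csv(out / name, index=False, float_format="%.10g")
        files.append(name)
    manifest = dict(truth)
    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_dataset(in_dir):
    """Read back a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    traces = []
    for name in manifest["files"]:
        df = pd.read_csv(in_dir / name)
        traces.append(ConductanceTrace(
            t=df["time_ms"].to_numpy(), g=df["g"].to_numpy(),
            species=str(df["species"].iloc[0]),
            depolarization_mV=float(df["depolarization_mV"].iloc[0])))
    return traces, manifest
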