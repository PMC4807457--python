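# hhabc

ABC-SMC parameter inference and identifiability analysis for the
Hodgkin–Huxley action potential model.

The package simulates the squid-axon membrane equations under voltage
clamp and four advanced stimulus protocols, fits both the simplified
(six constant gating rates) and the full (14 voltage-dependency
constants) model forms with an adaptive-tolerance sequential Monte
Carlo ABC sampler, and characterizes posterior identifiability
(practical vs structural candidates). A synthetic-data generator stands
in for the historical digitized voltage-clamp recordings, so every
stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `hhabc.model` | membrane/gating ODEs, voltage-dependent rate functions, general simulator |
| `hhabc.protocols` | voltage clamp, anode break, threshold excitation, positive phase, oscillation induction, AP detection |
| `hhabc.abc_smc` | priors/kernels, RMSE distances, adaptive-tolerance ABC-SMC |
| `hhabc.posterior` | weighted summaries, rate-curve ensembles, correlations, identifiability classification, ensemble protocol responses |
| `hhabc.synthetic` | synthetic clamp datasets with ground truth |
| `hhabc.pipeline` | study orchestration, run configs, reports |
| `hhabc.cli` | `hhabc` command-line interface |

Sign convention: voltages are displacements from rest in the original
squid-axon convention (rest `V = 0`, a depolarization of `d` mV sets
`V = -d`). `hhabc.model.to_modern_convention` converts outputs.

## CLI

```bash
# synthetic voltage-clamp dataset (one CSV per trace + manifest with truth)
hhabc synth make --out data/ --seed 1 --noise-sd 0.02

# one advanced protocol under reported (default) parameters
hhabc protocol run --name anode_break --out anode.csv

# per-depolarization simplified-model fits
hhabc fit simplified --data data/ --out fits/ --seed 1

# per-species full-model fits + identifiability report
hhabc fit full --data data/ --out fits/ --seed 1 --species K

# posterior-ensemble protocol responses
hhabc protocol ensemble --population fits/population_K.json \
    --name anode_break --out ensemble.json
```

## Notes

- ABC runs are deterministic given a seed; population files serialize
  to JSON byte-identically across repeated runs.
- The oscillation-induction current amplitude is stored with the units
  as printed in the protocol description (mA/cm²); the magnitude is
  physiologically anomalous, and a µA/cm² mode is available
  (`units="uA/cm2"`).
- Reduced-scale profiles (`hhabc.pipeline.reduced_test_config`) run the
  full path in minutes for CI.
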