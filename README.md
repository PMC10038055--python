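# vclamp

Whole-cell voltage-clamp analysis pipeline with a matching stochastic
channel-ensemble simulator.  Every analysis stage — I-V Boltzmann fitting,
activation kinetics, steady-state inactivation, r250/5-s inactivation
metrics, ON-gating-charge integration, and non-stationary fluctuation
analysis (NSFA) — can be validated end-to-end by parameter recovery
against synthetic sweep data with known ground truth.

## Layout

| module                 | purpose                                                          |
|------------------------|------------------------------------------------------------------|
| `vclamp.sweeps`        | sweep-set / voltage-protocol data model, CSV-S text I/O          |
| `vclamp.simulate`      | stochastic & deterministic ensemble simulation, gating currents  |
| `vclamp.preprocess`    | P/4 and offline leak subtraction, filtering, peak extraction     |
| `vclamp.activation`    | I-V fit, G-V curves, activation threshold, kinetics              |
| `vclamp.inactivation`  | SSI Boltzmann fit, r250, 5-s residual, CDI index                 |
| `vclamp.nsfa`          | Q_ON integration, Q-I slope, variance-mean parabola analysis     |
| `vclamp.stats`         | mean ± SEM summaries, normality-gated group comparisons          |

Conventions: inward current is negative pA; time is ms on a uniform grid;
windows are half-open `[start, end)` in samples; `k_inact` is reported
with the conventional negative sign (its magnitude enters the math);
channel density uses 1 µF/cm² (1 pF ↔ 100 µm²).

## Quick start (Python)

```python
from vclamp import (ChannelEnsembleModel, simulate_iv_family,
                    measure_peaks, fit_iv)

model = ChannelEnsembleModel(act_v05_mv=1.48, act_k_mv=8.69,
                             v_rev_mv=60.25, i_ss=1.0, q_gating_e0=0.0)
sweeps, truth = simulate_iv_family(model, -80, 70, 5, 50)
peaks = measure_peaks(sweeps, epoch_index=1)
fit = fit_iv([(p.step_level, p.peak) for p in peaks])
print(fit.v05_act, fit.k_act, fit.v_rev)   # 1.48  8.69  60.25
```

## CLI

```sh
vclamp simulate --model model.txt --protocol iv --mode deterministic --out sweeps.csv
vclamp preprocess --in sweeps.csv --leak offline --out clean.csv
vclamp analyze iv   --in clean.csv --out iv_fit.json
vclamp analyze ssi  --in ssi.csv  --out ssi_fit.json
vclamp analyze nsfa --in tails.csv --bins 50 --start-offset-ms 0.1 --out nsfa.json
vclamp analyze qon  --in sweeps.csv --window-ms 2 --out qon.json
vclamp report --glob "results/*.json" --param v05_act --out table.csv
```

The model file is flat `key=value` text matching the
`ChannelEnsembleModel` fields (see `vclamp.simulate.write_model`).

## File formats

Sweep files ("CSV-S") are plain text: `# key=value` header lines
(required: `sample_rate_khz`, `capacitance_pf`, `charge_carrier`,
`protocol_name`), a `time_ms,sweep_000,...` column header, then numeric
rows.  Serialization is deterministic and round-trips the numeric matrix
at full double precision.  Protocol config files are flat `key=value`
with epochs as `level_mv:duration_ms` tokens (`var` marks the per-sweep
test level).
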