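# iedtools

Analysis pipeline for interictal hippocampal–cortical dynamics:
detection of interictal epileptiform discharges (IEDs), sleep spindles
and cortical DOWN states from LFP; convolution-method cross-correlograms
with the coupling-modulation statistic M = (a − b)/b; multitaper
coherence and Gabor spectrograms; peri-event single-unit modulation with
a jitter-permutation significance test; a detection-free LFP
gradient-sharpness ("epileptogenicity") index; and a causal emulation of
an IED-triggered closed-loop stimulation controller. Everything is
exercised against a seeded synthetic-data generator that emulates
kindling progression (rising hippocampal IED rate, decaying
hippocampal→cortical coupling, late emergence of independent cortical
IEDs, rising LFP sharpness) and provides full ground truth.

## Layout

| module | contents |
| --- | --- |
| `iedtools.types` | session data model (channels, states, events, spike units) |
| `iedtools.io` | Neuroscope-style `.dat` + YAML sidecar + TSV session directories |
| `iedtools.synth` | seeded session/cohort generator, kindling schedules, stimulation effects |
| `iedtools.detect` | sleep scoring, MUA, IED, spindle and DOWN-state detectors |
| `iedtools.coupling` | CCG/coupling-M, coherence, spectrograms, trend statistics |
| `iedtools.spiking` | population rate, peri-event modulation, category partition |
| `iedtools.epi` | gradient-sharpness index and its longitudinal trend |
| `iedtools.closedloop` | causal stream detector, stimulation scheduler, sham, cohort contrasts |

All event and spike times are seconds from session start; intervals are
half-open `[start, end)`; LFP amplitudes are microvolts; the canonical
analysis rate is 1250 Hz (other rates are resampled on read).

## CLI

One entry point with subcommands operating on session directories:

```sh
iedtools --seed 1 simulate --condition KINDLED_ONLY --days 5 --duration-min 10 --out cohort/
iedtools score-sleep cohort/day00
iedtools detect cohort/day00 --what all
iedtools couple cohort/day00 --ref ied_hc0 --tgt spindle_mpfc0 --bin-ms 100 --window-s 2 --kernel-sd-ms 400
iedtools spiking cohort/day00 --events ied_hc0
iedtools epi-index cohort/ --baseline-days 0,1
iedtools closed-loop --mode cl --p-eff 1.0 --days 5 --out cl_cohort/
iedtools report cohort/
```

Global flags `--config <yaml>` (see `iedtools.config.PipelineConfig`),
`--seed`, `--log-level`.

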