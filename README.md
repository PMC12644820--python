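# qreplay

Analysis pipeline for a three-arm stochastic maze task: Q-learning models
with four between-session replay policies fitted to behavioural trial logs,
and hippocampal–striatal reactivation analysis (sharp-wave-ripple
detection, explained variance EV/REV, per-pair contributions, peri-event
coactivity) for paired CA1 / ventral-striatum recordings.  Synthetic
generators with known ground truth stand in for animal data, so every
pipeline stage has a no-download recovery test.

## Layout

| module | contents |
| --- | --- |
| `qreplay.behavior` | trial-log data model, CSV I/O, optimal-choice coding, arm frequencies, performance z-tests, trial-order shuffling |
| `qreplay.agent` | 3×3 Q table (0 diagonal / 0.7 off-diagonal initialisation), TD update, softmax action forecasts, reward-prediction error |
| `qreplay.replay` | memory buffer and the four replay policies (random, reward-biased, RPE-prioritised, RPE-proportional) with recency weighting |
| `qreplay.fitting` | reliability error score, sequential evaluation, bounded derivative-free fitting, perturbation analysis, reliability diagram, policy comparison |
| `qreplay.reactivation` | ripple detection (120–250 Hz, 3.5–25 SD, 10–500 ms, 30–1000 µV), binless 50-ms-equivalent rates, reward-modulation classification, EV/REV with drop-one-pair-out contributions, reactivated-pair labels, min-based z-scored coactivity |
| `qreplay.synthetic` | ground-truth behaviour generator (staged 75/50/25 → 87.5/50/12.5 → reversed schedule, quota or Bernoulli rewards), synthetic ephys sessions with tunable TASK→POST carry-over, the 10-trial worked replay fixture |
| `qreplay.experiments` | self-contained recovery experiments used by the acceptance suite |
| `qreplay.cli` | `qreplay` command-line entry point |

## CLI

```bash
qreplay simulate-behavior --seed 1 --out trials.csv --policy rpe_prioritised --n-replay 50
qreplay fit --trials trials.csv --out fit.json --policy rpe_prioritised --n-replay 5
qreplay compare-policies --trials trials.csv --out table.csv
qreplay shuffle-control --trials trials.csv --seed 1 --out shuffled.csv
qreplay simulate-ephys --seed 1 --out session.h5 --truth-out truth.json --carryover 0.8
qreplay detect-ripples --ephys session.h5 --epoch post --out ripples.csv
qreplay reactivation --ephys session.h5 --out reactivation.json
qreplay coactivity --ephys session.h5 --out coactivity.csv
qreplay report --run-dir results/ --out summary.json
```

`qreplay fit --config fit.yaml` accepts a YAML file overriding policy,
replay count, seed counts, optimiser budget and parameter bounds.  All
randomness is seeded explicitly; a rerun with the same configuration is
byte-identical.

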