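# larvahab

Habituation analysis of *Drosophila* larva responses to pulsed vertical
vibration.

Crawling larvae answer a vibration pulse with one of four actions of
ascending avoidance strength — **continuation**, **pause**, **turn**,
**reverse crawl** — and the strong reversal response fades under repeated
stimulation.  `larvahab` is a toolkit for people who quantify that
adaptation from tracker output (per-larva trajectory tables): it
classifies the four behaviors from 2D kinematics, computes population
response fractions F_ACTION = N_ACTION / N per pulse, builds
individual-level transition matrices, fits the habituation kinetics with
a parametric-bootstrap uncertainty, demonstrates the failure of a linear
time-invariant (LTI) convolution predictor, and simulates a
capacitor-switch circuit analog of the whole process.  Seeded synthetic
generators reproduce the statistical structure of the recordings so every
stage is testable without data.

## The model

Three constants describe adaptation of the reversal fraction F_REV:

* de-sensitization while the stimulus is on:
  `F_REV(t) = F0_REV · exp(−t/τ_des)`;
* re-sensitization while it is off:
  `F_REV(T_OFF) = F0_REV · (1 − exp(−T_OFF/τ_res))`;
* acceleration of recovery with pulse number: τ_res is a schedule
  τ_res(n) that collapses below one second after a few pulses.

Combined, the predicted reversal-event probability during the ON window
of pulse *n* of a train with period T is

    F_REV(t) = F0_REV · [1 − exp(−T_OFF/τ_res(n−1))] · exp(−(t − nT)/τ_des)

and zero while the stimulus is off.  Fits use `y0 + A·exp(−t/τ)` with y0
fixed at the baseline fraction; uncertainties come from 1000 Gaussian
resamples of the data points by their SEMs, refit independently.  The
circuit analog accumulates charge packets `Q1 = C1·V` on a leaky
capacitor, `Q2(t) = Σ_n Q1·θ(t−nT)·e^{−(t−nT)/RC2}`, and maps charge to
event probability by `F = F0·e^{−Q2}`.

See `docs/methods.md` for assumptions, defaults, and numerical details.

## Worked example

Fit the de-sensitization constant from a simulated continuous-vibration
experiment (100 animals, 1-s bins), then build the individual transition
matrix under the reference pulse train:

```python
from larvahab import (GeneratorConfig, StimulusProtocol,
                      generate_count_timeseries, generate_response_records,
                      ExponentialDecayModel, transition_matrix)

config = GeneratorConfig.from_preset("wildtype", n_larvae=100, seed=42)
protocol = StimulusProtocol.continuous(500, 2, duration=120.0)
counts = generate_count_timeseries(config, protocol, 120.0)
results = ExponentialDecayModel.from_timeseries(counts).fit(n_boot=1000, seed=42)
print(results.summary())

pulses = StimulusProtocol(500, 2, t_on=10, t_off=20, n_pulses=10)
records = generate_response_records(GeneratorConfig(n_larvae=450, seed=42), pulses)
tm = transition_matrix(records, lag=1)
print(tm.to_frame().round(1))
```

prints

```
Exponential habituation fit: y0 + A exp(-t/tau)
------------------------------------------------
tau            18.170 s   (bootstrap sd 0.739)
A              0.5157     (bootstrap sd 0.0202)
y0 (fixed)     0.0300
n_boot           1000
converged        True

        CONT  PAUSE  TURN   REV
CONT   100.0    0.0   0.0   0.0
PAUSE   52.0   48.0   0.0   0.0
TURN    20.8   22.2  57.0   0.0
REV      1.8    3.4  10.5  84.3
```

The fitted τ = 18.2 ± 0.7 s recovers the wild-type de-sensitization
constant (18.9 s) configured into the generator, from one 100-animal
experiment.  The transition matrix shows the one-way structure of
habituation: each row gives, in percent, what larvae performing a
behavior at pulse *n* did at pulse *n+1* — reversals repeat ~84% of the
time, weaker behaviors never escalate back to reversal (the REV column is
empty off the diagonal), and continuation is absorbing.

## Command line

Stages compose through files, with one global seed deriving every stage
seed and a checksummed manifest for reproducibility:

```bash
larvahab simulate --config generator.json --protocol protocol.json --out sim/ --trajectories
larvahab classify --trajectories sim/trajectories.csv --protocol protocol.json --out cls/
larvahab analyze  --records cls/records.csv --out analysis/
larvahab fit      --counts sim/counts.csv --out fit/ --seed 1
larvahab circuit  --config circuit.json --out circuit/
larvahab report   --manifest sim/manifest.json
larvahab run      --config run.json --seed 1 --out results/   # end to end
```

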