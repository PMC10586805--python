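# Methods

`larvahab` quantifies how crawling *Drosophila* larvae respond — and stop
responding — to trains of vertical sinusoidal vibration pulses.  This note
documents the models it implements, the synthetic-data generators it is
tested against, the numerical choices inside the fits, and the limits of
what passing tests demonstrate.

## Stimulus description

A stimulus is a train of `n_pulses` identical vibration bursts: frequency
`f` (Hz), dimensionless peak acceleration `Γ = A ω² / g` (the
force-proportional intensity, `ω = 2πf`, `g = 9.81 m/s²`), duration `t_on`
(s), gap `t_off` (s), period `T = t_on + t_off`.  Pulse `n` (counted from
0) occupies the half-open interval `[n·T, n·T + t_on)`; half-open bounds
avoid double counting at pulse edges.  `g` is a fixed constant — it only
enters the `Γ ↔ A` unit conversion.  Continuous vibration is represented
as a single pulse spanning the recording.

## Behavior classification

Responses are one of four actions of ascending avoidance strength:
continuation, pause, turn, reverse crawl.  From a 2D trajectory
(positions and a head-orientation unit vector at 15 frames/s):

* **Stop**: smoothed speed (5-frame centered moving average) below a
  threshold for ≥ 0.5 s.  The default threshold is 0.2 × that larva's
  median smoothed speed — per-larva normalization absorbs size and vigor
  differences; an absolute mm/s threshold is available.
* **Reversal**: head·velocity dot product negative for ≥ 0.5 s during or
  within 2 s after a stop (the sustain requirement rejects single-frame
  jitter).
* **Pause vs turn**: heading change Δθ between the mean unit-velocity
  direction over 1 s before the stop and 1 s after resumption (skipping
  2 frames at each edge, where central differences blend directions).
  Δθ < 30° is a pause, Δθ ≥ 30° a turn — the boundary ties toward the
  stronger behavior.  A stop that runs off the record is unresolved and
  excluded from every denominator.
* **Per-pulse label**: the response window is the first 3 s after pulse
  onset.  An action ongoing at onset counts as the response, unless
  forward crawling transitions into a new action inside the window, in
  which case the new action is assigned; no stop at all is a
  continuation.  Windows the trajectory does not span, or containing
  collision-flagged frames, are missing.  Widening the window to 5 s
  leaves aggregate fractions essentially unchanged on synthetic data
  (events cluster at onsets).

Population fractions are exact count ratios over the larvae with resolved
labels, `F_CONT + F_PAUSE + F_TURN + F_REV = 1`,
`F_STOP = 1 − F_CONT`.  Pairwise condition comparisons use two-sided
Fisher's exact tests, reported unadjusted at p < 0.05 (matching the
analysis convention this pipeline reproduces; no FDR correction is
added).

## Habituation kinetics

Three parameters describe adaptation of the strong (reversal) response:

* **De-sensitization** — during sustained stimulation the reversal
  fraction decays `F(t) = F0_REV · exp(−t/τ_des)` toward baseline
  (wild-type default τ_des = 18.9 s).
* **Re-sensitization** — while the stimulus is off, sensitivity recovers
  `1 − exp(−t_off/τ_res(n))`, where the schedule τ_res(n) is indexed by
  the pulse the gap follows.  Default schedule: τ_res(0) = τ_res(1) =
  strain value (5.3 s wild type), τ_res(n ≥ 2) = 0.8 s — recovery
  collapses to sub-second speed after two pulses.  The first pulse meets
  a naive animal (recovery factor 1; the schedule has no index −1).
* **Pulse-train prediction** — during the ON window of pulse n,
  `F(t) = F0_REV · [1 − exp(−t_off/τ_res(n−1))] · exp(−(t − nT)/τ_des)`,
  and 0 during OFF windows: this is a reversal-*event* probability, not
  the instantaneous behavioral state.

Strain presets (τ_des, τ_res(0), seconds): wildtype (18.9, 5.3),
rut (5.2, 3.6), dnc (14.3, 9.8), cam0 (25.6, 6.5).

### Exponential fitting and bootstrap

Fits use `y0 + A·exp(−t/τ)` with `y0` *fixed* at the baseline fraction
and bounded least squares for (A, τ): τ ∈ (0.1, 300) s, A ∈ (0, 1),
initialized at τ = 10 s and A = first point minus y0.  When the per-bin
animal count is known, weights come from the *fitted* curve's binomial
SEM in a second pass (IRLS); weights read off the observed counts
correlate with the noise and bias τ low by ~10% at 100 animals.
Observed-fraction SEMs use add-half counts so empty bins keep a finite
weight.

Uncertainty is a parametric bootstrap: every data point redrawn from a
Gaussian centered at its observed value with its SEM as width (negative
draws clipped to zero), the fit repeated 1000 times, and the standard
deviation of the fitted constants reported.  All-zero SEMs give
identical replicates and zero uncertainty.  Fixed seeds make the
bootstrap fully reproducible.

Two fitted constants are compared with an SD-based z statistic on the
bootstrap sets, `z = (τ_A − τ_B)/√(sd_A² + sd_B²)`, with a two-sided
p-value from the t distribution on the pooled degrees of freedom.  Using
the bootstrap-set SD (not SEM) makes the statistic independent of the
number of bootstrap resamples, which is the point of the construction.

### Re-sensitization ratio analysis

τ_res(n) is estimated from a family of experiments sharing (f, Γ, t_on)
and differing in t_off: per condition, the ratio `F_n,REV / F_{n−1},REV`
reduces to a count ratio over the same animals, and the curve
`ratio(t_off)` is fitted with `A · (1 − exp(−t_off/τ))`.  The free
amplitude *is* the normalization for incomplete recovery: it absorbs the
individual-level repeat attenuation and any residual de-sensitization of
the reference pulse, so the fitted asymptote needs no externally
estimated plateau.  (Dividing by a plateau estimated from the largest
t_off tercile — the obvious alternative — is biased low here, because at
τ ≈ 5 s the tercile includes t_off = 10 s where recovery is only ~85%
complete; `fix_amplitude` still provides that route.)  Conditions with
fewer than 3 reversing animals at the reference pulse carry almost no
information and are dropped; a zero denominator leaves the ratio
undefined.

When counts are available the fit maximizes the conditional binomial
likelihood `k_n ~ Bin(k_{n−1}, A(1−e^{−t_off/τ}))` — unbiased where
SEM-weighted least squares is not — with a matching bootstrap that
resamples counts around the fitted curve.  Plain ratio curves fall back
to SEM-weighted least squares with the Gaussian-resampling bootstrap.

For late-pulse recoveries (τ_res(3) and beyond) the family holds the
earlier gaps long (40 s, full recovery) and varies only the gap under
study.  With every gap short, almost no animals are still reversing by
pulse 3, the short-t_off ratio points vanish, and a sub-second τ is
unidentifiable; isolating the final gap keeps ~34% of animals reversing
at pulse 3 in every condition.

### LTI prediction and its failure

If the response were linear and time-invariant, the reversal fraction
under any stimulus would be the discrete convolution
`R[t] = Σ S[τ]·h[t−τ]` (1-s steps) of the stimulus with the impulse
response `h`, measured with 1-s bursts separated by 300-s gaps: segments
after each burst are aligned, averaged, baseline-subtracted, and
truncated where the mean first returns to within one SEM of baseline
after the peak (with a small absolute floor so noiseless curves still
truncate).  Applied to a continuous stimulus the convolution predicts a
sustained, accumulating response; the habituation model returns to
baseline with τ_des — past 20 s the two differ by far more than half the
impulse peak.  That divergence, not any single number, is the
diagnostic.

## Capacitor-switch circuit analog

Habituation is pictured as charge: every period `T` a switch dumps a
packet `Q1 = C1·V` from a battery-fed small capacitor onto a large one
(`C2 ≫ C1`, so the full packet transfers each time — the idealization is
implemented literally, a warning fires if `C2/C1 < 10`), which leaks
through `R` with time constant `R·C2`:

    Q2(t) = Σ_n C1·V · θ(t − nT) · exp(−(t − nT)/(R·C2)),   θ(0) = 1,

with `C2` initially uncharged; pre-transfer values at switch instants are
available as left limits.  The event fraction is `F = F0·exp(−Q2)`.
Post-switch peak charge has the geometric closed form
`Q1(1 − ρ^{n+1})/(1 − ρ)`, `ρ = e^{−T/RC2}`, saturating at
`Q1/(1 − ρ)`; the term-by-term summation agrees to 10⁻¹⁰ over 1000
switches.  Units are arbitrary-but-consistent.  Because the circuit
transfers a whole cycle's habituation instantaneously, it cannot show the
within-pulse decline of reversal probability — only the per-switch peaks
are compared (per-peak Fisher tests at a given animal count), and that
limitation is part of the model, not hidden by it.

## Synthetic data: what it emulates, what it does not

Three seeded generators stand in for recordings; identical configs give
identical output, and a config file without an explicit seed is
rejected.

**Event-stream generator** (per-larva, per-pulse labels).  Pulse-0 labels
come from the naive fractions — reversal 0.55, any-stop 0.90 at the
reference stimulus (f = 500 Hz, Γ = 2); baselines 0.03 and 0.24 with no
stimulus; pause/turn split 0.35/0.65 of non-reversal stops — interpolated
by a sensitivity factor (logistic thresholds in Γ and log f, normalized
to 1 at the reference), which produces the sharp reversal threshold in
intensity space.  Later pulses evolve each larva through a one-way
transition kernel: continuation absorbing, no entries into reversal from
weaker behaviors, and the REV→REV entry 0.85 multiplied by the recovery
factor of the preceding gap (deficit redistributed toward weaker
outcomes).  This is the only reconciliation of three constraints that
cannot hold exactly at once — recovery-dependent population ratios, an
~85% individual repeat, and strictly one-way habituation; under the
reference pulse train the pooled lag-1 repeat lands at 84–85%.

**Population-rate generator** (binned counts).  Per 1-s bin, binomial
draws around a deterministic rate: at each onset the reversal rate jumps
to `baseline + s·(0.55 − baseline)·r_n` and relaxes with τ_des,
continuing through OFF periods (switching the stimulus off does not
itself perturb the reversal fraction).  Stops follow the same kinetics
between their own baseline and naive levels, coherently (a reversing
larva is always stopped); the zero-noise expectation curve is returned
alongside the draws.  Note the deliberate difference from the
event-stream generator: this instrument realizes the population model,
without the individual-level repeat attenuation.

**Trajectory generator**.  Constant-speed runs (0.5 mm/s) at 15 frames/s;
pauses/turns as 1.2-s stops resumed with heading changes drawn from
[0°, 30°) / (30°, 150°]; reversals as a 1-s stop followed by 1.5 s of
0.3 mm/s motion opposing the head vector; events begin 0.3 s after
onset.  Paths are exactly the features the classifier keys on, so
round-trip agreement runs at ~100% (the invariant requires ≥ 99%).

Not emulated: body contours or peristalsis, collisions, hunching or
rolling, speed variability within runs, spontaneous (non-pulse-locked)
stops, or bin-to-bin autocorrelation of the population counts (bins are
drawn independently).  Passing tests therefore demonstrates that the
*pipeline* recovers the constants generating its inputs at realistic
sample sizes — not that real larvae obey single-exponential kinetics.

## Default problem sizes

Acceptance-style recoveries use the study-scale sizes: 100 animals per
continuous-vibration fit (1-s bins, 120 s); 100 animals per condition
over t_off ∈ {0.5, 1, 2, 5, 10, 20, 40} s for first-recovery fits
(T_ON = 30 s); 200 per condition for the late-recovery family; 10,000
draws for baseline checks; ~450 animals × 10 pulses for the transition
matrix (≥ 1000 reversal transitions).  At these sizes a single
recovery-family fit estimates τ_res with ≈ 15% sampling spread
(Monte-Carlo), so reported constants average the fit over a few
replicate families — tightening the estimate without changing any
per-experiment condition — and recovery tests compare that mean against
the configured value.

## Known limitations

* The event-stream and population-rate generators are intentionally
  different instruments (individual kernel vs population rate); their
  late-pulse peak levels differ, and no analysis mixes the two.
* τ_res estimates degrade when the largest available t_off is only ~4×τ
  (the dnc preset): the plateau is barely reached and the amplitude-τ
  trade-off widens the spread.
* The IRF decay inherits τ_des, so its "return to baseline" is the 1-SEM
  truncation point, not a sharp feature.
* Fisher comparisons across condition grids are unadjusted by design;
  with 29 conditions some significant edges are expected by chance.
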