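# ringwm

A spiking ring-attractor model of spatial-orientation working memory in the
fly central complex, together with the Buridan-arena trajectory statistics
used to quantify fixation behavior.

The package has two halves:

1. **Circuit simulation** — a leaky integrate-and-fire network of the
   EB-PB circuit: 18 EIP wedge neurons, PEI and PEN neurons (9 PB glomeruli
   per side) wired from the reference synaptic weight table, and three
   GABAergic ring-neuron pools (EIP-ring, C-ring, P-ring). The recurrent
   C circuit (EIP+PEI) stabilizes a localized activity bump; the shifter
   P circuit (EIP+PEN) moves it under unilateral PB input; ring pools gate
   the two circuits. A two-state Markov locomotor model (forward/rotation,
   300 ms steps, switch probabilities 0.40/0.60) drives the gating, and a
   protocol runner reproduces the experimental conditions: wild type,
   EIP-ring/P-ring suppression (-0.04 / -0.25 nA) and transient
   photoactivation (+0.20 nA) during the stimulus or poststimulus stage.
   Bump metrics (presence, position, FWHM, heading-bump deviation,
   loss fraction) are computed from wedge-wise rate profiles.

2. **Trajectory analysis** — movement-direction projection onto the LED
   screen, 12-quantile direction histograms (15-s window / 5-s step),
   fixation density and performance index (PI), radar pairing, the
   closed-form fixation deviation angle (sigma_f) and fixation strength
   (FS = 1 - Mmin/Mmax), locomotion metrics and the laser-escape rate.
   A synthetic-track generator emulates free-walking flies with tunable
   fixation bias, so the whole analysis pipeline is testable without
   recordings.

## CLI

```bash
# simulate a batch of trials for one condition
ringwm simulate --condition wildtype --n-trials 20 --seed 1 --out out/sim

# generate synthetic fly tracks
ringwm synth --preset wildtype-like --n 20 --seed 1 --out out/tracks

# per-stage fixation statistics for one track file
ringwm analyze --track out/tracks/wildtype_like_fly000.tsv --out out/analysis
```

Conditions: `wildtype`, `eip_suppress`, `p_suppress`, `eip_photo_stim`,
`eip_photo_post`, `p_photo_stim`, `p_photo_post`. Track files are
tab-separated with columns `time_s, x_mm, y_mm[, stage]`; a missing stage
column is filled from the default 90/60/90-s schedule.

Configuration is a nested YAML file (see
`src/ringwm/data/default.yaml`); any subset of fields may be overridden and
passed with `--config`.

## Calibration notes

Only the synaptic weight table and the manipulation currents (-0.04,
-0.25, +0.20 nA) are externally constrained; the single-neuron parameters
are standard LIF values, with the membrane capacitance (0.07 nF) and the
conductance scales calibrated so that those currents reproduce the target
bump phenotypes (wild-type FWHM ~1.86 rad, widened ~2.04 rad under
suppression, abolition under poststimulus photoactivation).
`CalibrationParams` in `ringwm.network` holds every free scale; the
packaged defaults are the calibrated operating point.
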