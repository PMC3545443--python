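# flygait

Footprint-based gait analysis for freely walking hexapods.

`flygait` tracks the body and tarsal ground-contact footprints of a walking
insect in high-speed contact-imaging sequences (bright, stationary footprint
spots plus a dim body glow) and computes a full suite of walking parameters:

* **Temporal** — instantaneous/average speed, step period, stance and swing
  durations, step length, swing speed, metachronal lag, inter-leg phases.
* **Spatial** — body-frame stance traces, anterior/posterior extreme
  positions (AEP/PEP), stance-linearity index, footprint clustering,
  follow-the-leader footprint alignment.
* **Gait** — per-frame 6-bit leg-combination codes (digit order
  LF LM LH RF RM RH), tripod/tetrapod/noncanonical classification, gait map,
  sliding gait index (+1 tripod / −1 tetrapod / 0 noncanonical), tripod and
  tetrapod indexes, combination frequency tables.
* **Statistics** — circular phase means with Rayleigh tests, OLS fits.

A synthetic walking-fly generator (`flygait.synth`) produces parametric
tripod / tetrapod / wave step patterns in continuous time, simulates straight
walks with world-frame ground truth, and renders image sequences with
realistic signal structure (stationary contact spots, dim body ellipse,
pre-entry dust, sensor noise) so that the entire pipeline is testable with no
external data.

## Command line

```sh
# render a synthetic walk (frames + ground truth)
flygait synth --config synth.json --seed 1 --out run/

# track body + footprints (thresholds are multiples of pre-entry noise MAD)
flygait track --frames run/frames --fps 250 --um-per-px 40 \
    --out run/track.json

# compute all parameters -> CSV tables + summary.json
flygait analyze --track run/track.json --out run/analysis

# optional PNG plots from the CSVs
flygait report --analysis run/analysis --out run/plots
```

`synth.json` sections: `spec` (gait name, period, duty factor, cycles, fps,
speed), `render` (image geometry, spot/body amplitudes, noise, dust,
pre-entry frames), `plan` (per-leg neutral AEP/PEP geometry) and `jitter`
(per-step AEP/PEP scatter).  Manual corrections go in a JSON edit log
(`--edits`) with `add` / `remove` / `relabel` records.

All distances in outputs are micrometres unless a column is suffixed
`_norm` (body lengths) or `_mm_s`.  Stance intervals are half-open
`[touchdown, liftoff)`; frame `i` is at time `i / fps`.

## Layout

| module                | contents                                             |
| --------------------- | ---------------------------------------------------- |
| `flygait.core`        | shared types: calibration, stance events, step patterns, body tracks, body-frame transforms |
| `flygait.synth`       | gait specs, walk simulation, ground truth, renderer, optics helper |
| `flygait.imaging_io`  | TIFF/PNG stack loading, frame writing, CSV/JSON tables |
| `flygait.tracking`    | background subtraction, blob detection, body tracking, leg labeling, edit log, stance extraction |
| `flygait.kinematics`  | speeds, step timings, step lengths, metachronal lags, phases |
| `flygait.spatial`     | stance traces, AEP/PEP, linearity, clustering, alignment |
| `flygait.gait`        | combination codes, classification, gait index, summaries |
| `flygait.stats`       | circular statistics, Rayleigh test, OLS              |
| `flygait.cli`         | `flygait synth|track|analyze|report`                 |
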