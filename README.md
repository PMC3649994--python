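# netrack

Quantitative analysis of chromosome-end mobility on the meiotic nuclear
envelope, with the zone-based cytology statistics that accompany such
studies — built so that every stage runs against seeded synthetic data with
known ground truth.

During early meiotic prophase in *C. elegans*, chromosome ends attached to
the nuclear envelope concentrate into SUN-1 protein aggregates that are
dragged along the envelope by cytoplasmic dynein (processive runs around
190 nm/s) interspersed with slow surface diffusion.  Movement-defective
mutants show more, smaller, slower aggregates, fail at homology search, and
end up with unpaired chromosomes: fewer chiasmata at diakinesis and
synaptonemal complex (SC) stretches installed between non-homologous
chromosomes.  `netrack` reimplements the measurement chain behind those
claims:

* a **synthetic movie generator**: aggregates move on the envelope sphere by
  a two-state run/diffuse process, fuse and split, and are rendered through
  a Gaussian PSF with photobleaching, Poisson shot noise and camera read
  noise (1 µm z-stacks, 5 s frame interval, 181 frames, ~0.107 µm/px);
* the **movie pipeline**: maximum-intensity projection → large-Gaussian
  background subtraction → subpixel drift correction → multiscale LoG spot
  detection with intensity-weighted localization → optimal-assignment track
  linking with gap closing and fusion/split annotation;
* **kinematics**: projected speeds per linked interval
  (`v_i = ‖Δr_i‖ / Δt` in nm/s, with headline fractions above 40 nm/s and
  at/above 160 nm/s), per-track **arc coverage**
  (`path length / (2πR) × 360°`, the angle the traveled distance would
  subtend on the nucleus circumference), and track-overlap maps;
* **cytology statistics**: equal-length germline zone assignment, FISH
  pairing calls with two-tailed Fisher's exact tests, SUN-1 focus/patch
  classification at 1.1 µm diameter with per-zone count histograms,
  diakinesis DAPI-body ↔ bivalent accounting for 2n = 12
  (`bivalents = 12 − bodies`) with exact/tie-corrected two-tailed
  Mann-Whitney comparisons, HIM-8/SC-stretch association classes, and
  per-worm respiration normalization with a two-sample t-test.

## Worked example

The numbered scripts under `analysis/` run the study end to end on synthetic
data (everything is derived from `--seed`):

```sh
python analysis/01_simulate_movies.py --seed 1      # writes TIFFs + ground truth
python analysis/02_track_and_summarize.py --seed 1  # full pipeline + comparison
python analysis/03_movement_report.py               # three-panel figures
python analysis/04_cytology_stats.py --seed 1       # zone/pairing/karyotype stats
```

`02_track_and_summarize.py` prints, for seed 1:

```
condition  n_tracks  arc_mean_deg  pct_above_40  pct_at_or_above_160
       wt        21         562.9          73.4                28.39
     spd3        37         248.1          24.8                 6.54
     jf18        17         133.5           0.5                 0.20

mean-arc ordering wt > spd3 > jf18: holds
```

Read this as: tracked aggregates in the wild-type-like condition cover the
largest arcs on the nucleus circumference and show the largest share of
fast (motor-driven) intervals; the mutant-like condition is intermediate;
the diffusion-only condition barely moves.  The absolute numbers are
properties of the simulation presets — the scientifically meaningful output
is the strict ordering of the three conditions in both statistics, which the
test suite checks across ten seeded replicates.

`04_cytology_stats.py` prints (among other tables) the diakinesis
accounting, e.g. a group simulated at chiasma probability 0.8 lands at
~7.0 mean DAPI bodies ≈ 5.0 bivalents, while the recombination-deficient
group sits at 11.9 bodies ≈ 0.1 bivalents, with all pairwise two-tailed
Mann-Whitney p-values far below 0.001 except between groups simulated at the
same rate.

A `netrack` console command exposes the same stages individually
(`netrack simulate movie|cytology`, `prep`, `detect`, `track`, `kinematics`,
`cytostats`, `run`, `report`); `netrack run --config run.yaml` executes a
whole configured pipeline and writes a manifest with content hashes, so
identical (config, seed) pairs produce identical outputs.

## Layout

```
src/netrack/     library: config, simulate, cytosim, prep, detect, linking,
                 kinematics, cytostats, pipeline, io, cli
analysis/        numbered end-to-end drivers (write under results/)
tests/           pytest suite, including the acceptance checks
scripts/         acceptance.py
docs/methods.md  model, parameter and design documentation
```
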