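# tnt — single-molecule translation & tethering analysis

Live-cell experiments can now watch individual mRNAs being translated:
the transcript is tagged in one color (MS2 stem-loops bound by fluorescent
coat protein), its nascent peptides in a second (dye-labeled α-FLAG Fab
binding an N-terminal epitope cassette), and a tethered regulatory factor
in a third (recruited to BoxB sites in the 3'UTR). The scientific
questions — how fast do ribosomes elongate, does tethering a factor
silence translation, do silenced mRNAs cluster — all reduce to image
analysis: find diffraction-limited spots, track them, measure
background-subtracted intensities per channel, and fit kinetic models.

This package provides that full chain plus a ground-truth simulator:

- `tnt.simulate` — synthetic three-color movies with Brownian mRNA motion,
  Poisson initiation / deterministic elongation, birth–death tethering,
  photon-conserving Gaussian rendering, camera noise, and exported truth;
- `tnt.detect` — band-pass spot detection and greedy nearest-neighbor
  tracking (10 px max step, ≥ 5 frames);
- `tnt.register` — projective two-camera registration from fiducial beads;
- `tnt.quantify` — disc/ring (or corner-quadrant) intensity measurement,
  best-Z traces, tethered/translating classification, colocalization,
  nucleus segmentation;
- `tnt.kinetics` — photobleach correction, runoff normalization and the
  tanh runoff-model fit, track averaging, phenotype classification;
- `tnt.metrics` — degree of labeling, nuclear accumulation, clustering
  curves, tether–translation Spearman correlation (exact for n ≤ 8);
- `tnt.pipeline` / `tnt.cli` — a deterministic end-to-end pipeline and a
  `tnt` command-line interface.

The core kinetic model is the ribosome runoff curve measured after
translation initiation is blocked:

    I(v, t) = ½ (1 − tanh(2 v (t − t_half) / L)),   L = 1885 aa

which equals 0.5 at t = t_half with slope −v/L, so fitting normalized
runoff curves yields the elongation rate v. See `docs/methods.md` for the
full model, parameter table, and known limitations (including a
documented bias of the tanh fit on simulator-generated runoff shapes).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
bundled fixture (`configs/smoke.yaml`: 20 mRNAs, 60 frames, 5 Z planes):

```bash
python analysis/01_simulate_movie.py
python analysis/02_detect_and_track.py
python analysis/03_quantify_traces.py
python analysis/04_runoff_elongation.py
python analysis/05_summary_metrics.py
```

Actual output:

```
movie: (60, 5, 3, 128, 128) (T,Z,C,Y,X) -> results/01_movie/movie.tif
channels: ('mrna', 'translation', 'tether'); mRNA frames every 10 s, translation/tether every 100 s
20 mRNAs; mean ribosome load at t=0: 31.6 (Poisson expectation 31.4)
mean tether occupancy: 4.38 of 15 sites

detected 1127 spots over 60 frames; recall vs truth (2 px): 0.935
81 tracks from 20 molecules (median length 9 frames, max 42)

quantified 81 tracks; 75 classified observations
tethered: 0.61; translating (all): 0.87; translating (tethered only): 1.0

v_true = 1 aa/s: median fitted v = 1.36 aa/s (IQR 1.33-1.38; ratio to truth 1.36)
v_true = 2 aa/s: median fitted v = 2.94 aa/s (IQR 2.90-3.00; ratio to truth 1.47)
v_true = 3 aa/s: median fitted v = 4.64 aa/s (IQR 4.55-4.73; ratio to truth 1.55)
median t_half for v_true = 2: 519 s (runoff time L/v = 942 s)

tether-translation Spearman rho = 0.351 (p = 0.00309, n = 69)
degree of labeling (A280 = 0.62, A_dye = 1.05): 0.91
nuclear accumulation (nuc 10->30, cyto 5->10): 1.50
```

The same pipeline is available as one command:

```bash
tnt run-all --config configs/smoke.yaml --out results/run
```

which writes `spots.csv`, `tracks.csv`, `traces.csv`,
`classifications.csv`, `runoff_fits.csv`, `summary_metrics.csv`, the
resolved configuration, and a run log — byte-identical on re-run with the
same config and seed.

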