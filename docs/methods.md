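# Methods

This note describes the model, the simulator, and the numerical choices
behind the `tnt` package, which analyzes (and synthesizes) three-color
single-molecule movies of mRNA translation and factor tethering.

## Imaging model

A movie is a 5-D array in (T, Z, C, Y, X) order with three channels:

- **mRNA** — the transcript itself, labeled through MS2 stem-loops bound by
  fluorescent MS2 coat protein; imaged every 10 s.
- **translation** — nascent peptides carrying an N-terminal FLAG epitope
  cassette bound by dye-conjugated α-FLAG Fab; imaged every 100 s.
- **tether** — a fluorescent factor recruited to BoxB stem-loops in the
  3'UTR via the λN peptide; imaged every 100 s.

Defaults: 130 nm pixels, 13 Z planes at 500 nm spacing, staggered
acquisition on a union time grid (channels not exposed at a given time are
stored as NaN planes). The slow-channel interval must be an integer
multiple of the mRNA interval; this is validated at configuration time.

## Synthetic movie generator

The generator is a forward model with exported ground truth, so every
analysis step can be tested against an oracle.

**Motion.** Each mRNA performs Brownian motion: per-axis displacements are
Gaussian with SD √(2 D Δt), converted to pixel (lateral) or z-step (axial)
units; trajectories reflect specularly at the field boundaries.

**Translation kinetics.** Ribosomes initiate as a Poisson process at rate
`init_rate_per_s` (default 1/30 s⁻¹), optionally gated by a hard silencing
time, an exponential decline, or an on/off burst schedule (implemented by
thinning). Elongation is deterministic at `v` aa/s along an ORF of
L = 1885 aa; a ribosome leaves the transcript when it passes L. At t = 0
the transcript is preloaded with a steady-state ribosome complement
(Poisson with mean `init_rate · L / v`, positions uniform on [0, L]).

**Translation signal.** Each ribosome at codon position p contributes
min(p, E)/E, a linear ramp across the N-terminal epitope cassette that
saturates at 1 past its end. E = 318 aa reflects a multi-epitope FLAG tag
region at the reporter's N terminus: the signal of one nascent chain grows
while the cassette is being synthesized and Fab-bound, then stays constant.

**Tethering.** Occupancy of the 15 BoxB sites follows a birth–death chain
(per-site on/off rates) simulated exactly with the Gillespie algorithm.

**Rendering.** Each emitter is rendered as an erf-integrated 2-D Gaussian
(exact pixel integrals, so photons are conserved under subpixel shifts)
with PSF σ = 1.3 px laterally, weighted across Z planes by a normalized
axial Gaussian (σ = 1.4 z-steps) so the photon total is independent of the
axial position. Camera model: Poisson shot noise on (signal + background),
multiplied by the gain, plus Gaussian read noise. Per-channel
photobleaching multiplies emission by exp(−b·k) with k the number of
exposures of that channel. An optional projective `camera_offset_matrix`
displaces the translation/tether channels to emulate a two-camera system.

**Reproducibility.** One seed drives three independent child streams
(trajectories, kinetics, noise) via `numpy.random.SeedSequence.spawn`, so
e.g. the same trajectories can be rendered under different noise.

## Detection and tracking

Detection on the max-Z projected mRNA channel: difference-of-Gaussians
band-pass for a 1–7 px FWHM size band (σ = FWHM/2.355), threshold (Otsu,
or mean + 3 SD of the band-passed pixels — the bundled configurations use
the latter, because Otsu assumes a bimodal histogram and collapses into
the noise mode on sparse single-molecule fields), 8-connected components,
area filter 2–49 px, and an eccentricity ≤ 0.9 cut applied only to
components ≥ 9 px (second-moment shape is meaningless for smaller ones).
A hysteresis-style second threshold (component peak > mean + 3.5 SD)
suppresses single-pixel noise components that slip past the area filter.
Components touching the mask border are discarded. Centroids are
intensity-weighted on the band-passed image.

Tracking is greedy nearest-neighbor: candidate links between consecutive
frames are sorted globally by distance and accepted greedily, with a hard
maximum step of 10 px, no gap closing, and a minimum track length of
5 frames. On simulated fields where ~99% of steps fall below the step
limit, ≥ 95% of ground-truth trajectories are recovered without any
identity mixing (splits forced by the step rule itself occur exactly at
true > 10 px steps).

## Registration

Two-camera offsets are estimated from matched fiducial bead positions by a
least-squares projective transform (normalized DLT, via scikit-image's
`ProjectiveTransform`), requiring ≥ 4 pairs; known transforms are
recovered to < 1e-9 px on noiseless beads.

## Quantification

Each tracked particle is measured in a small crop centered on the rounded
centroid. Three geometries:

| geometry | crop | central disc | background |
|---|---|---|---|
| `hilo_maxz` | 15×15 | disc ⌀3 | median of four 3×3 corner quadrants |
| `hilo_bestz` | 11×11 | disc ⌀6 | ring ⌀10, width 1 (mean) |
| `confocal` | 17×17 | disc ⌀5 | ring ⌀15, width 2 (mean) |

Intensity = central disc mean − background. Best-Z traces pick, per time
point, the Z plane maximizing the mRNA disc mean, max-project that plane
±1, and measure every exposed channel at the same xy (after applying the
channel registration transform where applicable). A channel is called
positive when its intensity strictly exceeds 3× the local background SD.

## Runoff kinetics

After initiation is blocked (Harringtonine, or silencing at t = 0),
the cell-summed translation signal is (1) divided by a single-exponential
photobleach model fitted to a whole-cell trace, (2) normalized so the mean
of the first three points is 1 and the mean over the 40–60 min baseline
window is 0, and (3) fit over the first 30 points to

  I(v, t) = ½ (1 − tanh(2 v (t − t_half) / L)),  L = 1885 aa,

whose value at t_half is exactly 0.5 and whose slope there is −v/L. Fits
use bounded least squares (v ∈ (0, 50] aa/s, t_half within the fitted
window) with the initial t_half from the first downward 0.5-crossing.

**Known estimator bias.** The simulator's runoff decay is piecewise
linear (each preloaded ribosome exits after (L − x₀)/v), while the fitted
model is a tanh. Least-squares fitting of a tanh to a clipped-ramp shape
systematically steepens the inflection slope, so the fitted v
overestimates the true elongation rate by ~1.3–1.5× (measured medians
1.36 / 2.94 / 4.64 aa/s for true 1 / 2 / 3 aa/s over 50 simulated cells
each; the bias persists in noiseless fits and is therefore a model/shape
mismatch, not a noise effect). The recovery is monotone and stable, so
relative comparisons between conditions remain valid, but absolute rates
carry this bias. The corresponding acceptance test asserts the stricter
25% tolerance and is intentionally left failing rather than hidden; see
the decision ledger for the full analysis.

Per-track averaging renormalizes each track to the mean of its first
4 points, interpolates onto the union time grid, averages with equal
weight per track, and bootstraps a pointwise 95% CI over tracks.

Track phenotypes are classified with precedence
split → low-off → burst → runoff: *split* when the translation and mRNA
centroids separate by > 10 px; *low-off* when fewer than 10% of frames
are translation-positive; *burst* on an off→on→off excursion of ≥ 2
positive frames after ≥ 2 silent frames; *runoff* on a significant
monotone decline (one-sided Mann–Kendall test, α = 0.05); otherwise
unclassified.

## Scalar metrics

- **Degree of labeling** of a dye-conjugated Fab:
  DOL = (ε_Fab/ε_dye) / (A280/A_dye − CF) with ε_Fab = 70,000,
  ε_dye = 150,000 M⁻¹cm⁻¹, CF = 0.08; Fabs with DOL < 0.8 are re-labeled.
- **Nuclear accumulation**:
  (I_nuc,late/I_nuc,early) / (I_cyto,late/I_cyto,early).
- **Clustering curve**: mean per-focus mRNA intensity over time,
  normalized to 1 at t₀, with a bootstrap 95% CI (pooled or per-cell).
- **Tether–translation correlation**: Spearman ρ; for n ≤ 8 an exact
  two-sided p-value by full permutation enumeration.

## Problem sizes and limitations

Bundled problem sizes (the 20-mRNA/60-frame fixture; 50-cell runoff
conditions) are package choices sized for a single CPU and minutes of
runtime, not study-calibrated defaults. The simulator omits several
realities of live-cell data: no cell boundaries or organelle exclusion,
no mRNA synthesis/decay during the movie, deterministic (dispersion-free)
elongation, no Fab binding/unbinding kinetics, no focal drift, and a
spatially uniform background. The tanh-fit bias above is the one known
case where these simplifications interact with the published analysis
model; all other analysis steps are validated against exact oracles.
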