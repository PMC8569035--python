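# Methods

## Coordinate convention

Lab frame, millimetres. `x` is the beam direction with `x = 0` at the
entrance face of the phantom in its origin position; `y` is transverse
in-plane; `z` points toward the camera. The image plane is the `z = 0`
plane containing the beam axis; the first Si layer plane sits at
`z = +140`. Shifting the phantom by `s` mm moves every emission point
to `x + s` while the camera stays fixed, so the nominal BP position in
the lab frame is `bp_depth + phantom_shift`.

## Event generator

The generator produces list-mode trigger groups with ground-truth
tags; it emulates the statistical structure of a beam-on Compton-camera
measurement, not radiation transport. Per signal event:

- **Emission point.** Depth along `x` is drawn from a two-component
  mixture: with probability `plateau_fraction` (default 0.5) uniform
  over `(0, bp_depth)` — emission along the entrance channel — and
  otherwise Gaussian at `bp_depth + peak_depth_offset` with
  `peak_sigma = 5 mm`, truncated at the entrance face. The true depth
  distribution of ¹⁰B* production is not known quantitatively; this
  mixture is a stand-in with the two features the analysis must cope
  with (an end-of-range peak riding on a track-long plateau), not a
  physics claim. Lateral `y`, `z` are Gaussian with the beam's
  σ = 11 mm.
- **Photon transport.** The 718 keV photon is emitted isotropically
  and kept if its ray crosses the 50 × 50 mm aperture of the first Si
  plane. The scatter layer is the last Si layer with probability 0.5
  and uniform over the rest — the measured instrument takes almost all
  its coincidences from the last-Si/first-CdTe pair — and the CdTe
  layer is the first with probability 0.7, uniform otherwise (both
  configurable). The scattering angle is sampled from the
  Klein–Nishina cross-section (rejection sampling against a uniform
  proposal; the unnormalised density is bounded by its forward value
  2), the azimuth uniformly; energies follow the forward Compton
  split, so every unsmeared event is exactly kinematically consistent
  and its cone passes through the emission point. The scattered ray
  must cross the chosen CdTe aperture and survives a Bernoulli
  full-absorption trial (`absorb_prob`, default 0.5, a representative
  CdTe photopeak efficiency at a few hundred keV). Phantom
  self-attenuation and inter-layer attenuation are ignored: the
  phantom is deliberately thin (15 mm) and the analysis applies no
  attenuation correction.
- **Energy response.** Each deposit is smeared with Gaussian noise of
  FWHM(E) = 0.022 · 662 · √(E/662) keV (statistical √E broadening,
  the default; a constant-fraction mode is kept for sensitivity
  checks), anchored to the instrument's 2.2 % FWHM at 662 keV.
  Negative smeared energies clamp to zero.
- **Background.** Random coincidences are uncorrelated two-hit pairs:
  uniform positions in random Si and CdTe layers, summed energy flat
  over 40–1600 keV split uniformly between the two hits. The default
  `background_fraction = 0.5` means half the generator's output is
  background; in the measured beam-on regime background outnumbers
  signal by orders of magnitude, which is why the 718 keV line is
  invisible in the raw summed spectrum — the spectrum-level property
  test uses a 0.98 background share to represent that regime.
- **Bookkeeping.** Timestamps are uniform within the 1 s beam-on part
  of each 3 s pulse; `total_projectiles` counts whole pulses times
  3 × 10⁹ ions. Dead time is not simulated (the measured 8 % live
  time is metadata). A single integer seed drives three spawned
  sub-streams (signal, background, timestamps), so runs are
  bit-reproducible.

What passing tests on this generator do **not** show about real data:
no Doppler broadening, no depth-of-interaction or strip pixelation in
the detectors, no multi-hit topologies (triggers are emitted as clean
two-hit pairs; the 20 keV threshold can still demote them), no
energy-correlated background structure, and no phantom placement
error.

## Reconstruction

Simple back-projection, no iterative deconvolution. For each pixel
centre `p` on `z = 0` the angular residual between the apex-to-pixel
direction and the cone axis is `α(p) − θ`; the pixel weight is a
Gaussian in that residual with σ = 5.4°/2.3548 (the instrument ARM),
or 1 inside a fixed shell half-width for the hard-shell kernel. Both
kernels satisfy the same per-pixel oracle test; the Gaussian is the
default because the measured images are plainly resolution-smoothed.
Each cone is normalised to unit total mass before accumulation
(default on) so large shells do not outweigh small ones; pixel values
are kernel evaluations at pixel centres — at 1 mm pixels against a
~12 mm spatial resolution, area integration would change nothing
visible. 2-D only: the beam trail lives in the `z = 0` plane; no 3-D
volume is reconstructed.

## Scatter correction

DEW: `clip(main − k · upper, 0)` with `k` the main/upper window-width
ratio (1 for the standard 20 keV windows). TEW:
`clip(main − (lower · w_m/(2 w_l) + upper · w_m/(2 w_u)), 0)`, the
conventional SPECT estimator, which reduces to subtracting the
side-window average at equal widths. Correction is applied in the
image domain (per-window back-projections are subtracted), because the
per-window images are the published objects the correction operates
on. Clipping at zero is part of the operation: corrected surroundings
are expected to sit near zero and negative intensity is meaningless
downstream.

## Range analysis

The depth profile sums pixels over the |y| ≤ 10 mm band (20 mm full
width, about twice the beam diameter). A Gaussian plus constant
offset is least-squares fitted (scipy `curve_fit`) over ±15 mm around
the profile argmax — the only landmark available without human input;
initial values are mu = argmax, amplitude = max − min,
sigma = 5 mm (a third of the half-width), offset = min. The offset
term absorbs the plateau-plus-background pedestal the profiles ride
on. The reported peak is the fitted mu (sub-pixel), not the argmax.
An optimizer failure or a mu escaping the fit window marks the fit
unconverged; reports refuse unconverged fits.

## Numerical choices and known behaviour

- m_e c² = 511.0 keV; kinematic validity is |cos θ| ≤ 1 + 1e−9 (the
  tolerance only guards float round-off; smeared pairs landing exactly
  on the boundary are measure-zero).
- Energy windows are closed on both ends, so window tests are
  bit-exact.
- Layer spacings (Si pitch 4 mm, Si→CdTe gap 8 mm, CdTe pitch 4 mm)
  are unpublished for the instrument; they are config values and no
  result in this package depends on the defaults.
- At 718 keV the Klein–Nishina mean cosine is 0.327 (quadrature,
  cross-checked against the closed-form total cross-section); the
  distribution is forward-peaked but far from collimated, which is
  why a large share of scattered rays miss the CdTe stack and the
  geometric acceptance is ~0.2 % of emitted photons.
- With the default emission mixture the fitted peak sits ~2–3 mm
  upstream of the BP even without noise: the entrance-channel plateau
  ends at the BP and adds left-side weight inside the fit window. The
  same-direction offset (−4.0 mm) is seen in the real measurement.
  Noiseless-oracle tests that demand ≤2 mm recovery therefore use a
  plateau-free emission model, which isolates the end-of-range
  component; the end-to-end acceptance test keeps the full default
  mixture and passes its 3 mm bound with a measured mean error of
  ~2.5 mm over 20 seeds.
- Problem sizes: study-condition runs use 300 signal coincidences
  (the ~300 photopeak events per 10-minute run of the motivating
  measurement); property tests use 30–200 events, and distributional
  tests 10⁴–10⁵ draws.

## Limitations

The generator's acceptance model (layer-occupancy probabilities, one
Bernoulli absorption trial) reproduces where events land, not the
instrument's absolute efficiency; the 5 × 10⁻¹⁰ detection ratio is
bookkeeping from printed counts, not an emergent prediction. BP depth
is an input (from external transport calculations), never computed.
DEW/TEW here corrects a window-independent random background well; a
real energy-correlated scatter continuum may behave differently.
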