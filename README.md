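# pgrange

Prompt-gamma Compton-camera imaging and beam-range verification for
carbon-ion therapy.

## The problem

Carbon-ion radiotherapy delivers most of its dose at the Bragg peak
(BP), the sharp maximum at the end of the particle track, so the
treatment is only as accurate as the knowledge of the beam range.
Nuclear fragmentation along the track produces excited ¹⁰B* nuclei
that relax within a nanosecond by emitting 718 keV prompt gamma rays,
and the depth distribution of that emission tracks the beam range. A
two-plane semiconductor Compton camera — a stack of Si scatterer
layers in front of CdTe absorber layers — can image this line in real
time during irradiation.

`pgrange` is a tested implementation of the full analysis chain for
this measurement, aimed at medical-physics researchers prototyping
range-verification analyses:

1. **Synthetic list-mode data** — a Monte-Carlo event generator for a
   290 MeV/u carbon pencil beam (lateral σ = 11 mm) on a graphite
   phantom: parametrized 718 keV emission-depth profile, isotropic
   emission, Klein–Nishina scattering in an 8-layer Si / 4-layer CdTe
   stack (50 × 50 mm layers, first Si plane 140 mm from the beam
   axis), Gaussian energy smearing (2.2 % FWHM at 662 keV), and a
   flat-spectrum random-coincidence background that buries the line in
   the raw spectrum.
2. **Event selection** — "two-hit" Compton events (exactly one Si hit
   and one CdTe hit above a 20 keV threshold) and summed-energy
   windowing (photopeak 708–728 keV; side windows 670–690 and
   750–770 keV).
3. **Reconstruction** — list-mode simple back-projection. Each event
   defines a cone with apex at the scatter position, axis from the
   absorber hit through the apex, and half-angle θ from

       cos θ = 1 − m_e c² E₁ / (E₂ (E₁ + E₂))

   where E₁ and E₂ are the scatterer and absorber deposits. Cones are
   painted onto the 200 × 200 mm, 1 mm/px image plane containing the
   beam axis, weighted by a Gaussian of the instrument's 5.4° angular
   resolution measure (a hard-shell kernel is also provided).
4. **Scatter correction** — dual- and triple-energy-window (DEW/TEW)
   images: the contamination under the photopeak is estimated from the
   side-window back-projections and subtracted per pixel, clipped at
   zero.
5. **Range analysis** — depth profile (pixel sum over a ±10 mm
   transverse band), Gaussian + offset fit within ±15 mm of the
   profile maximum, and a range report: fitted peak position, its
   difference from the nominal BP depth, and its shift from a
   reference run.

## Worked example

```bash
pgrange run --seed 1 --output-dir demo
```

runs the whole chain with the default study conditions (BP depth
98.4 mm, 300 signal coincidences, half the output random background)
and prints:

```
outputs in demo
718: peak 95.8 mm (BP 98.4 mm, diff -2.6 mm)
DEW: peak 95.8 mm (BP 98.4 mm, diff -2.6 mm)
TEW: peak 95.8 mm (BP 98.4 mm, diff -2.6 mm)
```

The photopeak-window image localises the emission peak at 95.8 mm,
2.6 mm short of the nominal BP — the entrance-channel emission pulls
the fitted peak slightly upstream, the same direction as the offset
seen in measurements — and the scatter-corrected DEW/TEW images agree
with the photopeak image to well under a millimetre. The output
directory contains the selected-event CSV, per-window and corrected
images (float TIFF + text matrix + YAML sidecar), depth profiles, the
range report, a stage-count log, and a manifest with SHA-256 hashes;
`pgrange run` twice with the same seed reproduces every file
byte-for-byte.

Other subcommands: `pgrange generate` (events CSV only),
`pgrange reconstruct` / `pgrange analyze` (resume from a saved CSV),
and `pgrange table1` (a three-position phantom-shift experiment,
0/30/60 mm, reported as a four-row range-verification table).

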