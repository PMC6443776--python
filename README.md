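# silkstruct

Analysis pipeline for hierarchically structured protein fibres (silk-like
materials), combining:

* **synthgen** — forward models for every input the analysis stages consume:
  two-phase lamellar meridional SAXS (up to 8 harmonic orders), an
  equatorial fibril-packing peak with finite-bundle broadening, β-sheet
  WAXD 2θ profiles and 2D fibre diagrams with known crystallinity and
  azimuthal orientation spread, piecewise-linear stress–strain curves,
  and fibroin-like tandem-repeat protein sequences. Every generator
  records its ground truth, so the analysis stages are testable by
  parameter recovery without any experimental data.
* **waxd** — crystallinity by Gaussian peak deconvolution (crystalline
  centres fixed from an orthorhombic unit cell), unit-cell indexing from
  the 200/210/002 d-spacings, crystal strain from the 002 spacing, 2θ
  scans of 2D fibre diagrams, and the azimuthal orientation index
  (180 − FWHM)/180 of the equatorial 200 reflection.
* **saxs** — Kratky transform, harmonic long-period peak detection, the
  1D electron-density correlation function K(z) with the standard
  two-phase decomposition (invariant, long period, core and mean phase
  thicknesses), long-period strain, Scherrer bundle thickness with
  instrumental-broadening correction, and assembly of time-resolved
  deformation series.
* **mechanics** — tilt-corrected elliptical cross-sections, force→stress
  conversion, tensile properties (modulus, strength, extensibility,
  toughness), crystal-modulus regression, and stage segmentation of
  stress–strain curves.
* **seqmotif** — polyalanine-block detection, PAB+NPAB tandem-motif
  segmentation with insert localisation, NPAB dipeptide/tripeptide
  chemistry, and the residue-count → phase-length mapping.
* **pipeline / cli** — end-to-end synthesise→analyse→report runs with
  full config provenance and bit-reproducible outputs.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: exactly
recomputable worked examples (strain arithmetic, phase closure,
sequence-length arithmetic) plus property-based recovery (crystallinity
under Poisson noise, correlation-function vs real-space-autocorrelation
oracle agreement, Scherrer size recovery, tensile-property recovery,
exact motif-span recovery).

## CLI

All commands live under a single entry point:

```sh
silkstruct synth saxs-meridional --out meridional.dat
silkstruct saxs long-period meridional.dat
silkstruct saxs corrfunc meridional.dat

silkstruct synth waxd --crystallinity 0.44 --out waxd.dat
silkstruct waxd fit-crystallinity waxd.dat --cell 9.39,9.50,6.98
silkstruct waxd unit-cell --d200 4.695 --d210 4.2094 --d002 3.49
silkstruct waxd crystal-strain 3.52 3.54 3.57

silkstruct mech area --la-apparent 4.42 --tilt 10.37
silkstruct seq phase-map --pab 22 --npab-crystal 45 --amorphous 90 \
    --phase-thickness 15.7

silkstruct run static --seed 1 --out report/
silkstruct run deformation --seed 1 --out report_deform/
silkstruct run sequence --seed 1 --out report_seq/
```

Profiles are two-column text with `#` headers (abscissa kind and
wavelength); 2D diagrams are float TIFF plus a JSON geometry sidecar;
sequences are FASTA; results are JSON and tidy CSV. Exit codes: 0 ok,
1 domain error, 2 usage error.

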