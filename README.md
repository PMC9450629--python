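# cochlen

Quantized-chord ("digitized ruler") measurement of the cochlear spiral
canal's length on 3D volumes, plus a synthetic helico-spiral phantom that
supplies ground-truth arc lengths for validating the method.

The measurement walks an extracted vestibule-to-apex centerline with
predefined straight rulers — six mandatory 2.0 mm chords (R1–R6), then
greedily the largest of {2.0, 1.5, 1.0} mm that still hugs the curve within a
deviation tolerance — and sums the nominal chord lengths into a total. Since
a chord never exceeds the arc it spans, the total systematically
underestimates the true arc length on curved canals; the phantom quantifies
that bias.

## Modules

- `cochlen.phantom` — parametric helico-spiral phantom (`PhantomSpec`,
  `COCHLEA25` preset), centerline sampling, ground-truth arc length by
  adaptive quadrature, tube rasterization into voxel volumes (optional blur +
  seeded noise), NIfTI and centerline-CSV I/O.
- `cochlen.centerline` — Otsu/fixed thresholding (`segment_canal`), 3D
  thinning + spur pruning + 26-connected shortest path between snapped seed
  points (`extract_path`), uniform resampling, optional best-fit-plane
  projection.
- `cochlen.ruler` — the core method: `place_chord` (first-crossing chord
  placement with root refinement), `chord_walk` (prefix + greedy scheme),
  `sum_segments`, `chord_bias`.
- `cochlen.report_io` — packaged per-case readings of the six measured
  specimens (checksummed CSV), `verify_fixtures` cross-checks every case's
  segment sum against its expected total, segments-CSV round-trip, plain-text
  reports including the multi-case DNM matrix.

## CLI

```sh
# 1. generate a phantom volume with known true arc length
cochlen phantom --preset cochlea25 --spacing 0.2 \
    --out vol.nii.gz --truth truth.json --centerline-out truth_curve.csv

# 2. segment + extract the vestibule-to-apex centerline
cochlen measure --volume vol.nii.gz \
    --vestibule 4.0,0.0,0.0 --apex 1.0,-0.0,5.0 \
    --threshold auto --out path.csv

# 3. walk the centerline with the ruler scheme
cochlen chordwalk --centerline path.csv --scheme default \
    --out segments.csv --report report.txt

# cross-check the packaged per-case readings
cochlen fixtures
```

Custom schemes are JSON:
`{"fixed_prefix": [...], "allowed_set": [...], "deviation_tol_mm": 0.5, "max_segments": 100}`.

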