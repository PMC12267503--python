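# myomap3d

Structure-tensor "myomapping" and collagen quantification for transmural
myocardial tissue volumes.

Given a 3-D grayscale tomographic volume (multi-page TIFF or NRRD) with voxel
size in µm, the package computes per-voxel 3-D structure tensors at a stated
physical integration window (default 123.5 µm), extracts the local
myocyte-aggregate direction (eigenvector of the smallest eigenvalue) and maps
it into a local ventricular-wall frame to produce:

- **HA** — helical angle, degrees in (−90, 90]
- **IA** — intrusion angle (elevation out of the wall-tangent plane; a
  `to_radial` convention is available)
- **FA** — fractional anisotropy of the tensor eigenvalues, in [0, 1]

plus transmural profiles (axial statistics with angle doubling), regional FA
means, and collagen volume-fraction reports from binary segmentation masks
over labelled ROIs (sub-epicardium / mid-myocardium / sub-endocardium, with
their unweighted average).

A synthetic-data module generates fiber phantoms (helical-ramp tube texture
with optional angular dispersion, a disorganised zone, Gaussian noise and
ring artefacts) and collagen masks with exactly known volume fractions, so
every pipeline stage is validated against generator ground truth.

## CLI

A single `myomap3d` entry point with subcommands:

```bash
# generate a 128^3 helical-ramp phantom (HA +60 -> -60 deg) with ground truth
myomap3d phantom --dims 128,128,128 --voxel-size 5.8,5.8,5.8 --seed 1 --outdir runs/phantom

# full myomapping run: HA/IA/FA volumes, transmural profiles, regional mean FA
myomap3d myomap --input runs/phantom/phantom.nrrd --window-um 123.5 \
    --bins 20 --roi-config rois.yaml --outdir runs/myomap

# collagen percentages in labelled ROIs (CSV in table layout + JSON with counts)
myomap3d collagen --mask collagen_mask.nrrd --roi-config rois.yaml \
    --sample-id ICM-1 --outdir runs/collagen

# orthogonal 2-D cuts
myomap3d slices --input volume.nrrd --index 64,64,64 --outdir runs/slices
```

ROI config is YAML: `rois: {label: [lo0,lo1,lo2, hi0,hi1,hi2]}` (0-based,
half-open). Every run directory receives the resolved configuration and a
log; identical config + seed reproduce byte-identical CSV/JSON outputs.

Key flags: `--window-um` (physical integration window, default 123.5),
`--window-kind fwhm|sigma|box` (how the window size is interpreted),
`--radial-axis`/`--longitudinal-axis` (slab wall frame),
`--ia-convention elevation|to_radial`, `--voxel-size` (required for TIFF,
overrides NRRD metadata).

## Package layout

- `volume_io` — `Volume3D`/`ROIBox`, TIFF/NRRD read/write, orthogonal slices
- `structure_tensor` — tensor field, analytic symmetric-3×3 eigensolver
  (dense-solver fallback), FA, fiber directions
- `myomapping` — wall frames (slab axes or surface-normal), HA/IA,
  transmural profiles, regional mean FA
- `collagen_quant` — exact-count collagen percentages, regional reports,
  cubic sub-volume extraction
- `synthetic_data` — fiber/collagen phantoms, noise and ring artefacts
- `cli` — the `myomap3d` command
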