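# scleratopo

Artefact-free corneoscleral topography processing and scleral-asymmetry
analysis.

Corneoscleral profilometers measure the anterior eye surface out to
several millimetres beyond the limbus, but the periphery of each scan is
contaminated by edge-effect artefacts (eyelid lift-off, tear pooling,
lashes). `scleratopo` implements the full processing chain that makes
such scans usable for scleral-shape work:

1. **surface_io** — point-cloud readers/writers (MAT container and a
   neutral `x_mm,y_mm,z_mm` CSV), laterality-aware anatomical-frame
   conversion (0° = nasal for both eyes), and resampling onto 1°
   meridians with a fixed radial grid (monotone piecewise-cubic, never
   extrapolated).
2. **levelling** — per-meridian limbus detection from the turning point
   of the smoothed second radial derivative, a robust ring fit across
   meridians, a total-least-squares limbus plane, tilt angles
   `alpha = -pi/2 + arccos(N·axis)`, X-then-Y rotation (rotation about Z
   fixed at zero) and re-origin at the refined apex.
3. **edge_elimination** — a moving median (11 elements, ±0.1 mm) of the
   absolute meridian slope with a tripled-mean cut-off (strategy 1), a
   pre-edge elevation-minimum search (strategy 2), and the ultimate
   cutting edge = whichever candidate is closest to the apex.
4. **sphere_elevation** — best-fit sphere to the scleral annulus by
   minimising the squared algebraic residuals (Kåsa initialisation +
   nonlinear refinement), sphere height on the upper sheet, relative
   elevation `Zi − Zsi`, and per-quadrant correlation against an
   11.5 mm reference sphere.
5. **asymmetry** — per-meridian differences `v(θ) − v(θ−180°)` for
   θ ∈ [0°, 180°), missing-aware group aggregation, and per-meridian
   two-sample t-tests (Welch default) with the binary decision at 95%.
6. **synthetic_eye** — fully parameterised synthetic eyes (conicoid
   cornea + near-spherical sclera joined at the limbus, asymmetry
   harmonics, tilt, noise, planted artefacts) with queryable ground
   truth, so every stage is testable without clinical data.
7. **cli** — `simulate` / `process` / `group` subcommands with
   config-hash provenance on every output.

## CLI

```bash
# generate a 10-eye synthetic cohort with a planted asymmetry
cat > recipe.json <<'EOF'
{"noise_sd": 0.003, "tilt": [2.0, -1.0],
 "asymmetry_harmonics": [[1, 0.08, -38.0]]}
EOF
scleratopo simulate --recipe recipe.json --n-eyes 10 --seed 7 --out-dir eyes/

# level, de-artefact and map each eye
scleratopo process eyes/eye_*.csv --out-dir processed/

# aggregate one laterality into asymmetry reports and polar figures
scleratopo group processed/eye_* --out-dir report/
```

Per-eye outputs: levelled cloud, limbus CSV/JSON, edge report, trimmed
polar surface, sphere fit JSON (with quadrant correlations), relative
elevation map and the per-meridian profile at the sampling radius
(default 8 mm). Group outputs: per-angle mean/sd/t/p/decision tables for
raw and relative elevation, a summary JSON with the maximum-asymmetry
meridian, and polar SVG plots. Every file records the SHA-256 hash of
the configuration that produced it; runs are bitwise reproducible for a
fixed seed.

Pipeline defaults (window width, threshold factor, sampling radius,
t-test variant, ...) can be overridden with `--config config.yaml`; see
`scleratopo.config.PipelineConfig` for the schema.

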