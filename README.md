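# afm3d

3D nanomechanical characterization from AFM force-volume data.

`afm3d` turns a grid of force–indentation curves into a depth-resolved
mechanical picture of a soft sample: for every pixel it fits the
depth-dependent **average Young's modulus** over growing indentation
windows, assembles the per-depth values into a stack of modulus maps (one
map per indentation depth), condenses every depth slice into a Gaussian
(mu, sigma) summary and its dimensionless (mu, sigma, h) vector, and
classifies the sample's behavior across depth as softening / stiffening
and homogenizing / heterogenizing.

## What's inside

| module                  | purpose |
|-------------------------|---------|
| `afm3d.contact_models`  | Force laws for cylinder, cone, paraboloid and exact sphere tips (implicit contact radius solved by bracketed root finding); optional caller-parameterized series-corrected sphere law |
| `afm3d.curve_io`        | Text dialect for curves and force-volume grids (manifest + per-pixel files or one packed table), raw deflection conversion, contact-point detection |
| `afm3d.depth_profile`   | Windowed least-squares and pointwise modulus estimators; constrained power-law fit E(h) = a·h^b + c (a, c > 0, b < 0) |
| `afm3d.map_stack`       | Depth map stacks, explicit threshold masking (substrate removal), TSV/CSV/JSON export |
| `afm3d.distributions`   | Gaussian summaries (moments or histogram least squares), indicator mixtures, (mu, sigma, h) vectors, trend classification |
| `afm3d.synthetic_data`  | Seeded simulator: layered / continuous / power-law modulus structures pushed through the forward force model with optional force noise, ground truth retained |
| `afm3d.cli`             | `afm3d` command with `simulate`, `profile`, `maps`, `report` subcommands |

All internal quantities are strict SI (m, N, Pa); files, CLI flags and
reports speak nm / nN / kPa.

## CLI quick start

Generate a synthetic dataset with known ground truth, then process it:

```bash
cat > sim.yaml <<'EOF'
grid: {ny: 16, nx: 16, pixel_size_nm: 78}
geometry: {kind: cone, half_angle_deg: 25}
poisson_ratio: 0.5
curve: {h_max_nm: 900, n_samples: 64}
field:
  kind: uniform
  profile: {type: power_law, a_kPa: 50, b: -0.5, c_kPa: 5}
noise: {multiplicative: 0.01}
seed: 1
EOF

afm3d simulate --config sim.yaml --out dataset/
afm3d maps --manifest dataset/manifest.json \
    --geometry cone --half-angle-deg 25 \
    --depths-nm 100,200,300,400,500,600,700,800 \
    --out run/
afm3d report --in run/
```

`maps` writes one TSV matrix per depth (masked pixels as `NA`), a long-form
`stack_long.csv`, `summaries.csv` / `vectors.csv` with the per-depth
(mu, sigma, h) data, and a `run.json` sidecar holding the full
configuration, its hash and the classification. Substrate-affected regions
are removed with an explicit, always-declared threshold
(`--mask-max-kpa`, `--mask-min-kpa` or `--mask-quantile`); there is no
silent default cut.

A single curve can be profiled directly:

```bash
afm3d profile --input curve.txt --geometry cone --half-angle-deg 25 \
    --depths-nm 100,200,300,400 --fit-power-law
```

## File dialect

Curve files are UTF-8 text: `#`-prefixed `key: value` headers with a
mandatory `units:` line, then two numeric columns (`h F` by default, or
`z d` raw data plus a `spring_constant_N_per_m` header). Grids are
described by a JSON/YAML manifest (`nx`, `ny`, optional `pixel_size_nm`,
and `paths` or `packed_table`). Pixel coordinates are 0-based (row, col),
row-major, top-left origin.
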