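# wavetrace

Quantitative analysis of traveling fluorescence waves in plant tissue:
geometric scanning of image stacks into distance–time profiles, traveling
peak/front tracking, kinematic summarization across replicates, and
transport-model inference (free power law, diffusion front, bulk flow with
Taylor dispersion, Gaussian-process distance–time regression). A synthetic
data module generates wave image stacks and distance–time tables with
analytic ground truth for validation.

## Modules

| module | purpose |
| --- | --- |
| `wavetrace.synthetic` | wave/ridge generators with closed-form front and peak laws |
| `wavetrace.scan` | radial / arc / transect scanning of stacks into distance profiles |
| `wavetrace.tracking` | baseline + noise bands, LOESS smoothing, peak and front tracking |
| `wavetrace.kinematics` | degree-6 origin polynomials, velocities, vascular speeds, group tests |
| `wavetrace.transport` | power-law, diffusion, Taylor-dispersion and GP fits; paired sign test |
| `wavetrace.cfwidth` | vein-unloading peak widths along grid scan lines |
| `wavetrace.cli` | `wavetrace` command-line pipeline |

## Command line

```sh
# simulate a local (radial) wave stack with ground truth
wavetrace simulate --kind local --seed 1 --out data/

# scan + track it (geometry JSON holds the anchor point in pixels)
wavetrace track-local --stack data/stack.tif --geometry geom.json \
    --span 0.06 --out tracked/

# vascular speeds and transport-model fit
wavetrace simulate --kind vascular --seed 1 --out vasc/
wavetrace vascular-speed vasc/tracer.csv --out speeds.csv
wavetrace fit-transport --tracer vasc/tracer.csv --calcium vasc/calcium.csv \
    --out fit/

# vein-unloading peak widths
wavetrace simulate --kind cf --seed 1 --out cf/
wavetrace cf-width --image cf/image.tif --out widths.csv
```

Geometry files look like
`{"mode": "radial_point", "points": [[128, 128]], "n_lines": 100,
"line_length_um": 1500}`; modes are `radial_point`, `arc_circle`
(three edge points) and `vein_transects` (segment endpoints). A YAML config
(`--config`) can override the tracking block (`span`, `window`,
`noise_multiplier`, `sd_floor`, `min_run`) and the transport block
(`u`, `Dm`, `radius`, `t_limit`); defaults mirror the published constants
(noise band ±1.96·SD̄, front threshold +SD̄, u = 500 μm/s,
Dm = 100 μm²/s, radius = 10 μm, t ≤ 10 s).

Exit codes: 0 ok, 2 configuration error, 3 data error.

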