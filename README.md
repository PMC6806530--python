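# phytoprobe

A desk-scale toolkit that reproduces the computational pipeline of a
sensor-to-plant phenotyping facility: a robotic arm carries depth
sensors, a hyperspectral line-scan camera, a thermal camera and a
fluorometer probe to plants growing in controlled chambers. Everything
runs on synthetic inputs — no hardware or external datasets required.

## Modules

| Module | Purpose |
| --- | --- |
| `phytoprobe.scene` | Synthetic chamber scenes, parametric leaves (flat round disks vs. elongated twisted ribbons), labeled point clouds at two sensor fidelities, spectral/thermal fixture images with ground-truth masks |
| `phytoprobe.geometry` | k-NN search (deterministic tie rule), PCA surface normals and curvature, principal axes of segments |
| `phytoprobe.segmentation` | Region growing with smoothness constraint; precision/recall scoring against labeled clouds |
| `phytoprobe.planner` | Probe-site selection, probe poses (8 mm standoff, 60° incidence by default), reach/collision feasibility, 5 mm leaf slicing, line-scan poses at 0.25 m, top-view pose for a 0.5 m footprint |
| `phytoprobe.measurements` | YII = (F′M − F)/F′M, white/dark reflectance calibration, circle/line region sampling, red-edge first derivative, CSV/JSON/PNG export |
| `phytoprobe.chamber` | Discrete-time chamber control simulator: PID temperature (10–44 °C), dual-actuator CO2 (150–5000 PPM, solenoid/scrubber exclusion), additive-only irrigation, curtain/damper interlock, photoperiod-offset schedules |
| `phytoprobe.design` | Split-plot randomization (chambers × genotypes), replication bookkeeping, per-genotype quadratic response-surface fits with clipped optima |
| `phytoprobe.io` / `phytoprobe.cli` | ASCII PLY/PCD I/O, workflow config, the end-to-end per-plant acquisition pipeline, CLI |

## CLI

All commands are under a single entry point:

```bash
phytoprobe simulate-scene --spec scene.yaml --seed 3 --out cloud.ply
phytoprobe segment --in cloud.ply --theta 10 --cmax 0.05 --min-size 100 --out seg.json
phytoprobe plan --cloud cloud.ply --seg seg.json --sites 4 --out plan.json
phytoprobe measure --spec scene.yaml --circle 100 100 30 --out-dir meas/
phytoprobe acquire --spec scene.yaml --seed 5 --out-dir run1/
phytoprobe chamber-sim --horizon 24 --out trace.csv
phytoprobe design --chambers 8 --genotypes 14 --out layout.csv
```

A scene spec is a small YAML file:

```yaml
pot_positions: [[0.5, 0.5], [1.2, 0.6]]
species_style: flat_round        # or elongated_twisted
leaves_per_plant: 3
stem_height_m: 0.3
```

## Conventions

Meters internally, millimeters at config boundaries; right-handed
frame, z-up, chamber floor at z = 0. All randomized operations take
explicit seeds and are bit-reproducible.
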