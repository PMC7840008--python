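# cuelearn

Analysis pipeline for short-term motor learning in an embodied-VR billiards
task: shot-level performance statistics, robust intertrial variability,
full-body kinematic learning metrics (generalized variance, PCA
dimensionality, manipulative complexity, Velocity Profile Error) and
learning-curve fits — together with a synthetic cohort generator and a 2D
shot-physics simulator so every stage is testable without external data.

## Modules

| module | purpose |
| --- | --- |
| `cuelearn.synthetic` | synthetic sessions: exponentially decaying directional error with configurable motor noise, full-body joint-angle kinematics (17 segments × 3 DoF at 60 Hz) with shoulder-to-elbow amplitude shift, and paired real/virtual validation angles |
| `cuelearn.physics` | cue-strike estimation (10-frame componentwise median), uniform-friction ball dynamics, line-of-centers collision, pocket test, and landmark-based similarity calibration between capture and virtual frames |
| `cuelearn.kinematics` | joint angles → angular velocity (central differences), trial peak from the right shoulder+elbow DoFs, 1-s peak-centred analysis window |
| `cuelearn.performance` | directional error, 25-trial blocks, success rate, t-distribution intertrial variability and its trend-corrected variant |
| `cuelearn.bodymetrics` | per-trial covariance, generalized variance, PC spectrum, DoF count (>1 % variance rule), manipulative complexity, VPE and its block variability |
| `cuelearn.learning` | exponential / double-exponential learning-curve fits (multi-start), first-to-last-block learning delta with paired t-test |
| `cuelearn.io` / `cuelearn.cli` | CSV/JSON readers and writers, run configuration, pipeline orchestration, CLI |

Numeric defaults in `CohortConfig` and `PhysicsParams` (noise SDs, success
tolerance, friction, stop threshold, table dimensions, …) are artifact
defaults chosen to produce the documented qualitative structure; they are not
measured values.

## CLI

```sh
cuelearn simulate --preset evr --seed 1 --out scratch/sim      # cohort CSVs
cuelearn analyze  --preset evr --seed 1 --out scratch/run      # full pipeline
cuelearn analyze  --config my_run.yaml                         # from YAML
cuelearn validate --n-shots 100 --discrepancy-sd 2.85 --seed 1 # angle twin
cuelearn shoot    --n-shots 10 --out scratch/shots             # physics batch
cuelearn report   scratch/run                                  # summary tables
```

`analyze` writes `outcomes.csv`, `block_stats.csv`, `block_summary.csv`,
`trial_metrics.csv`, `fits.json` and a `manifest.json` (config + seed +
version) from which every output is reproducible.

Presets: `evr` (constant intertrial motor noise) and `real_world` (noise
decaying over the session).

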