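# restifit

Trajectory-to-insight analysis of epithelial restitution in gastric
organoids: piecewise hybrid ODE models, per-organoid feature fitting,
treatment-vs-control chord analysis, and machine-learning follow-up.

## The problem

When a single cell in a gastric organoid is killed by laser
photodamage, its neighbors repair the wound within minutes
(*restitution*).  Time-lapse two-photon microscopy yields three
trajectories per organoid: GFP-actin intensity in the neighboring cells
(RLU), the damaged area (μm²), and the dead cell's distance from the
damage site (μm).  Comparing whole trajectories across heterogeneous
organoids and drug treatments is awkward; `restifit` instead compresses
each organoid into 13 interpretable model parameters — *static
features* — and analyzes those.

Each channel follows a small hybrid ODE whose rate terms switch at
discrete timing events:

- **actin**: dAct/dt = −Act_depoly1·(Act − Act_min) before T_min,
  Act_poly·(Act_max − Act) between T_min and T_max, and
  −Act_depoly2·(Act − Act_SS) afterwards — degradation, polymerization,
  relaxation to steady state;
- **damaged area**: dDA/dt = −k_repair·DA (single exponential repair);
- **dead cell distance**: dDCD/dt = k_stay + k_run·(DCD_max − DCD),
  with k_run switching on at the detachment time T_detach.

Timing and level features (T_min, T_max, T_detach, Act_min, Act_SS) are
read directly from each trajectory; rate constants and the theoretical
Act_max are fitted by evolutionary least squares (differential
evolution) on the regime-separated closed-form solutions.  Downstream,
percent changes of group means feed chord-plot edge lists
(strongest activation/inhibition per drug and per parameter), and the
pooled feature table feeds PCA and random-forest regression with scaled
Gini variable importance (which actin features predict the cellular
behaviors k_repair, T_detach, k_stay, k_run, DCD_max).

Because the underlying microscopy data are not publicly deposited, the
package includes a first-class synthetic-cohort generator that draws
per-cell parameters around the control cohort's published mean ± SD
summary, applies treatment multipliers and optional actin-timing
couplings, adds observation noise, and retains ground truth — so every
stage of the pipeline is testable offline.  See `docs/methods.md` for
models, estimators, defaults and limitations.

## Worked example

Generate a planted-signal cohort (behavior parameters linear in T_max,
3:1 signal-to-noise, noiseless observations), fit every organoid, and
ask the forest which actin feature carries the signal:

```python
from restifit import TimeGrid, fit_cohort
from restifit.io import frame_to_trajectories
from restifit.ml import SplitConfig, importance_report
from restifit.synthetic import generate_cohort, planted_signal_config

config = planted_signal_config(n_per_group=100, seed=1)
config.grid = TimeGrid(0.0, 20.0, 0.1)
config.noise_sd = {"actin": 0.0, "damaged_area": 0.0, "dead_cell_distance": 0.0}
dataset = generate_cohort(config)

cohort = fit_cohort(frame_to_trajectories(dataset.trajectories))
print(cohort[["organoid_id", "k_repair", "t_max", "t_detach"]].head(3).round(3))

truth = dataset.truth.set_index("organoid_id")
fit = cohort.set_index("organoid_id")
err = (fit["k_repair"] - truth["k_repair"]).abs() / truth["k_repair"]
print(f"median k_repair recovery error: {100 * err.median():.3f}%")

report = importance_report(cohort, SplitConfig(seed=1))
for res in report:
    print(f"{res.response:9s} r2_train={res.r2_train:.2f} "
          f"r2_val={res.r2_validation:+.2f} "
          f"t_max importance={res.importances['t_max']:.0f}")
```

Output (about a minute on one CPU):

```
   organoid_id  k_repair  t_max  t_detach
0  control_000     0.237    6.2       3.2
1  control_001     0.314    NaN       2.3
2  control_002     0.301    4.6       2.4
median k_repair recovery error: 0.000%
k_repair  r2_train=0.99 r2_val=+0.46 t_max importance=100
t_detach  r2_train=0.96 r2_val=+0.63 t_max importance=100
k_stay    r2_train=0.98 r2_val=+0.55 t_max importance=100
k_run     r2_train=0.98 r2_val=+0.70 t_max importance=100
dcd_max   r2_train=0.97 r2_val=+0.33 t_max importance=100
```

Each cohort row is one organoid's fitted feature vector (the `NaN`
marks a cell whose actin trace could not be fully featurized — it is
flagged, not silently dropped).  The repair rate of every cell is
recovered to optimizer precision from noiseless data, and the forest
correctly identifies the actin peak time `t_max` as the dominant
predictor (scaled importance 100) of every behavior parameter, with
positive validation R² throughout.

The same stages are available from a shell:

```sh
restifit pipeline --seed 0 --out results/demo          # all stages
restifit simulate --seed 0 --out data/                 # or one at a time
restifit fit --input data/trajectories.csv --out results/
restifit chord --features results/features.csv --out results/
restifit ml --features results/features.csv --out results/
```

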