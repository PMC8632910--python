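# omtrack

Quantification of **ommatidial rotation and tissue fluidity** from live-imaged,
tracked epithelial movies — with a synthetic-data generator so the entire
pipeline runs, and is tested, without any microscopy data.

During *Drosophila* eye development each ommatidium — a cluster of eight
photoreceptors (R1–R8) plus accessory cells — rotates 90° through a field of
interommatidial cells (ICs) while constricting its apical surface. How freely
it can rotate depends on the fluidity of the surrounding IC tissue: how often
ICs exchange neighbors (T1 transitions), how far they move, and how elongated
they are. `omtrack` turns tracked, segmented movies of this process (label
images + tracking table + ommatidium annotation) into the quantities used to
characterize it:

- **Rotation kinetics** — the angle R(t) of the R2→R5 centroid line relative
  to the morphogenetic furrow, fitted with a logistic
  R(t) = R₁/(1 + e^−(t−t₀)/τ) whose maximum slope gives the angular velocity
  **Ω = 60·R₁/(4τ)** [°/h].
- **Apical constriction** — the summed R-cell area
  A(t) = A₀ − A₁/(1 + e^−(t−t₀)/τ), with constriction rate
  **C = 60·A₁/(4τ)** [µm²/h], plus pulse/anti-pulse segmentation of dR/dt and
  constriction/expansion totals.
- **IC events and motility** — division/delamination detection from lineage
  and area collapse, neighbor-exchange counting from adjacency changes
  (lineage-remapped, so divisions never masquerade as exchanges), 90-min
  binned statistics, and displacement/speed fields on a 1.25 µm grid around
  the cluster.
- **Shape & jamming metrics** — the cell shape index **p₀ = L/√A**, whose
  regular-pentagon value 3.81 is the proposed jamming threshold; mean/SD of
  p₀ over the first- and second-level IC neighborhood; polygon-class
  distributions.
- **Junction kinetics** — FRAP normalization
  I_N(t) = (I − I_min)/(I_max − I_min) with reference-junction bleach
  correction and the single-exponential fit I_N(t) = A(1 − e^−kt)
  (mobile fraction A, recovery rate A·k, half time T½ = ln 2/k); and
  laser-ablation recoil fits L = l_f(1 − e^−t/T) (amplitude l_f, initial
  speed l_f/T), with viscoelastic (resorbing) recoils flagged as unfittable.

The `omtrack.synthetic` subpackage generates Voronoi-tessellated label-image
movies of a rotating, constricting 8-cell cluster in a motile IC field,
abstract cell-graph event ledgers with exactly known planted events, and
FRAP/recoil traces — each returning its ground truth, under three genotype
presets (`wild_type`, low-fluidity `lof`, high-fluidity `gof`).

## Worked example

```python
import numpy as np
from omtrack import WILD_TYPE
from omtrack.synthetic import generate_tissue_movie, generate_area_series
from omtrack.rotation import measure_rotation, fit_logistic

# render a tracked movie and check the measured rotation against ground truth
movie, annotation, truth = generate_tissue_movie(WILD_TYPE, n_frames=21, seed=42)
rotation = measure_rotation(movie, annotation)
print("max rotation error vs ground truth [deg]:",
      round(np.abs(rotation.angle_deg - truth.rotation_deg).max(), 3))

# fit the constriction logistic on a full-length (500 min) noisy trajectory
series, _ = generate_area_series(WILD_TYPE, n_frames=51, seed=1, noise_sd_um2=0.5)
fit = fit_logistic(series, "area")
print("constriction rate C [um^2/h]:", round(fit.rate, 3))
print("plateau apical area [um^2]:", round(fit.plateau, 2))
```

prints

```
max rotation error vs ground truth [deg]: 0.069
constriction rate C [um^2/h]: 2.46
plateau apical area [um^2]: 7.92
```

The measured rotation tracks the generator's schedule to well under a degree,
and the area fit recovers the wild-type preset's derived kinetics —
C = 2.5 µm²/h and an 8 µm² plateau (60% constriction) — from a single noisy
trajectory. Fits on noiseless trajectories recover the generating parameters
to four significant figures (see the test suite). Note that a movie covering
only the first ~200 min (before the sigmoid's inflection) does not constrain
the logistic; use full-length series for rate estimates.

The same operations are exposed on the command line:

```bash
omtrack simulate movie --preset wild_type --seed 42 --frames 21 --out demo/
omtrack measure rotation demo/ --out demo/rotation.csv
omtrack measure shape demo/ --out demo/shape.csv
omtrack frap fit --trace my_frap.csv
omtrack ablation fit --trace my_recoil.csv
```

## Data formats

- **Movie**: multi-page uint16 TIFF of label images (0 = background),
  tracking CSV (`frame,label,cell_id,parent_id`), metadata JSON
  (`pixel_size_um`, `frame_interval_min`), annotation JSON (R1–R8 roles,
  furrow axis, R7 recruitment frame, chirality, first-level IC set).
- **Event ledgers**: per-frame cell-graph JSON (nodes with areas, edges =
  adjacency) plus lineage.
- **Traces**: CSV with units in the headers (`time_s,roi_intensity,ref_*`
  for FRAP; `time_s,vertex_distance_um` for recoil).

See `docs/methods.md` for the models, parameter derivations, estimator
choices, and known limitations.
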