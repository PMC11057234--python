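# monoshape

Monocular reconstruction of 3D mirror-symmetric shapes from single
orthographic or perspective images.

A 2D orthographic image of a mirror-symmetric 3D object determines the
object only up to a one-parameter family of symmetric interpretations,
indexed by the slant of the symmetry plane. This package implements a
computational observer that picks one member of that family by combining
four slant estimators:

* **θ_v2s3** — maximize compactness `V²/S³` of the convex hull of the
  reconstruction;
* **θ_s3v** — maximize modified compactness `V/S³` (correlated with
  minimizing the reconstruction's depth range);
* **θ_sym2** — make the object's parts maximally symmetric about *two*
  mirror planes (primary + secondary, found by RANSAC), by minimizing a
  depth-consistency loss over a slant-pair grid;
* **θ_persp** — the slant implied by the vanishing point of the symmetry
  line segments in a perspective image (exactly 90° when the segments
  are parallel, i.e. for orthographic images).

The estimates are combined as `θ̂ = λ·θ_persp + (1−λ)·(β₀ + β₁θ_v2s3 +
β₂θ_s3v + β₃θ_sym2)`, where λ grows monotonically with the angular size
of the image and β is fitted per object type / subject by least squares
against per-trial response slants.

The package also contains the synthetic stimulus generator (random and
rectangular mirror-symmetric two-box polyhedra with seeded, constraint-
checked sampling), the projection/noise/image-correction chain, and an
evaluation harness based on the tan-ratio shape-dissimilarity metric
`log₂(tan σ_ref / tan σ_rec)`.

## Library overview

| module | contents |
| --- | --- |
| `monoshape.mesh` | `Mesh`, `RigidPose`, volume / surface area / convex hull / aspect ratio, OBJ/OFF/PLY I/O |
| `monoshape.stimuli` | seeded generators for the two polyhedral stimulus classes, trial views (slant/tilt sampling), condition sets |
| `monoshape.symmetry` | RANSAC mirror-plane detection, correspondence sets, primary/secondary plane selection, overlapping correspondences |
| `monoshape.imaging` | cameras, pair images, orientation noise, angular size, least-squares correction to a valid orthographic image |
| `monoshape.family` | one-parameter family reconstruction at a given slant, dissimilarity metric, slant grid |
| `monoshape.estimators` | the four slant estimators and the two-plane loss |
| `monoshape.combiner` | λ weighting, β fitting, simulated observers |
| `monoshape.evaluate`, `monoshape.pipeline` | per-trial results, summaries (medians, CDFs, correlations), end-to-end runner |

Minimal example:

```python
import numpy as np
from monoshape import *
from monoshape.stimuli import mirror_pairs, rotation_from_slant_tilt

mesh = generate_random_polyhedron(seed=1)
corr = CorrespondenceSet(SymmetryPlane(np.array([1.0, 0, 0]), 0.0),
                         mirror_pairs(mesh), 1e-9)
pose = RigidPose(rotation_from_slant_tilt(45, 30, 60), [0, 0, 50.8])
image = project(mesh, corr, pose, Camera("orthographic"))
family = FamilyGrid(correct_to_orthographic(image))
print(select_slant_compactness(family, "c1").value_deg)
```

## Command line

`monoshape` exposes the pipeline stages as subcommands:

```bash
monoshape generate --type random --n-per-slant 20 --seed 0 --out-dir stim/
monoshape detect --mesh stim/random_0000.obj --out corr.json
monoshape project --mesh stim/random_0000.obj --correspondences corr.json \
    --slant 45 --tilt 30 --projection perspective --out img.json
monoshape estimate --image img.json --out est.csv
monoshape simulate-observer --estimates est.csv --out resp.csv
monoshape fit --responses resp.csv --out model.json
monoshape predict --estimates resp.csv --model model.json --out pred.csv
monoshape evaluate --predictions pred.csv --out summary.json
monoshape run --config config.yaml --out-dir out/   # everything at once
```

`monoshape run` accepts a YAML config (seeds, stimulus parameters,
camera, noise SD, observer β/t, fitting options) and writes the
manifest, estimates, responses, predictions and summary tables.

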