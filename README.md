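# morphomap

Tissue motion and deformation mapping for fragmented 3D+t live imaging
of organogenesis.

Live microscopy of a developing organ — the motivating case is the early
mouse heart, where the cardiac crescent closes and elongates into the
primitive heart tube — never captures the whole process in one movie:
acquisitions span a few hours, tissue parts (the inflow and outflow
tracts) are routinely missing, and every embryo sits in its own
orientation. `morphomap` integrates such fragments into a single
spatiotemporal reference and measures tissue deformation on it:

1. **Motion estimation** — consecutive frames of each movie are aligned
   by cubic B-spline free-form deformation, minimizing
   `SSD + λ·E_reg` over a control lattice (λ = 0.01, ~10 µm spacing,
   four-level coarse-to-fine). Fields are anchored at the midpoint frame
   and chained outward, which halves the worst-case accumulated tracking
   error versus first-frame anchoring. A mesh of the segmented tissue
   ("Live-Shape") rides on these fields: fixed topology, per-frame node
   positions.
2. **Staging and mapping** — each frame is assigned to a reference-Atlas
   group by a Gaussian mixture over the landmark ratio h/w (posterior
   cutoff 0.75 at the acquisition boundary); the staged mesh is then
   projected into its Atlas group by Student's-t mixture rigid
   alignment, removal of unmatched Atlas regions ("AtlasCut"), and a
   mask-based non-rigid morph ("SurfaceMap").
3. **Deformation mechanics** — per triangle, the deformation gradient
   `F = T R⁻¹` between rest and deformed edge frames gives the growth
   rate `J = det F` (area ratio), the strain `ε = ½(FᵀF − I)`, and the
   anisotropy `θ = σ_max/σ_min` of the principal stretches with its 3D
   stretch axis; fields are smoothed over a 20-voxel geodesic radius.
4. **Concatenation and fate map** — anatomical correspondences are
   chained across stages through hook specimens; cumulative growth and
   anisotropy are per-point products of mean stepwise values,
   `J̄(i) = Π_gr mean_embryos J(i)_gr` (likewise θ̄), and carrying one
   reference cloud through a single specimen path yields a Dynamic Atlas
   for pseudo-cell tracking and zone-growth validation.

A first-class synthetic-data module generates the entire study design
with closed-form ground truth — a crescent-to-tube surface flow rendered
as membrane-shell images with labelled cells, a staged synthetic Atlas,
and fragmented, posed, cap-cut cohorts — so every pipeline stage is
testable without external data.

## Worked example

Deformation between two developmental times of a synthetic tube, plus
staging of a full sequence against a synthetic Atlas:

```python
import numpy as np
from morphomap.synthetic import SceneParams, SyntheticScene, make_synthetic_atlas
from morphomap.mechanics import deformation_map
from morphomap.staging import compute_features, fit_staging_model, stage_sequence

scene = SyntheticScene(SceneParams(), seed=7)
rest, deformed = scene.mesh_at(0.3), scene.mesh_at(0.5)
dm = deformation_map(rest, deformed, smoothing_radius=10.0)
print(f"mean growth J:        {np.nanmean(dm.J):.3f}")
print(f"mean anisotropy theta: {np.nanmean(dm.theta_aniso):.3f}")

shapes, calibration, _ = make_synthetic_atlas(n_stages=8, seed=7)
model = fit_staging_model(calibration)
hw = [compute_features(scene.landmarks_at(t)).h_over_w
      for t in scene.frame_times]
for k, (v, g) in enumerate(zip(hw, stage_sequence(hw, model).labels)):
    print(f"  frame {k}: h/w = {v:.3f} -> {g}")
```

prints

```
mean growth J:        1.292
mean anisotropy theta: 1.100
  frame 0: h/w = 0.973 -> Gr2
  frame 1: h/w = 1.027 -> Gr3
  frame 2: h/w = 1.116 -> Gr4
  frame 3: h/w = 1.255 -> Gr5
  frame 4: h/w = 1.475 -> Gr6
  frame 5: h/w = 1.844 -> Gr7
  frame 6: h/w = 2.545 -> Gr8
  frame 7: h/w = 4.287 -> Gr9
```

The mean J of 1.292 says the tissue grew ~29% in area between the two
times; θ of 1.10 says the growth is mildly directional. On this
synthetic flow the per-face J agrees with the closed-form value to
better than 5e-3, and the monotone h/w trajectory stages each frame into
its generating Atlas group.

The same stages are available from the shell:

```bash
morphomap simulate cohort --n 6 --seed 7 --out cohort/
morphomap preprocess --in cohort/s00/stack.tif --voxel 1,1,1 --out iso.tif
morphomap register --in iso.tif --grid 3 --out tset.mmr
morphomap run --config pipeline.yaml        # config-driven, resumable
```

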