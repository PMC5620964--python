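# kinelift

Monocular 3-D articulated-motion recovery for motion-capture and
biomechanics workflows: given the 2-D image tracks of a body's joints over a
sequence (or per-joint detector heatmaps in marker-less mode) and the known
orthographic camera rotations, `kinelift` reconstructs the per-frame 3-D
joint positions.

Recovering depth from a single camera is ill-posed; the solver resolves the
ambiguity with a *union-of-nonlinear-subspaces* prior on the motion. With
`X ∈ R^{3NP×NF}` the motion matrix (columns = frames), `X#` its frame-wise
rearrangement, `R` the block-diagonal stack of 2×3 camera matrices and `W`
the 2-D tracks, the estimate minimizes

```
  ‖Z‖* + λ1‖X‖* + λ2‖E‖1 + λ3 trace((I−Z)ᵀ K(X) (I−Z)) + λ4 R(X, l)
  s.t.  W = R X# + E
```

where

* `Z` (NF×NF) is a self-expressive coefficient matrix over frames — its
  nuclear norm pushes the feature-mapped shapes onto a few subspaces, and
  spectral clustering of `Z` recovers which "primitive action" each frame
  belongs to;
* `K(X)` is an RBF kernel Gram matrix on frame columns (median-heuristic
  bandwidth), so the subspaces are nonlinear shape manifolds;
* `E` absorbs gross tracking errors under an L1 penalty;
* `R(X, l) = Σ_f Σ_{(p,q)} (‖x_{f,p} − x_{f,q}‖ − l_{p,q})²` softly enforces
  constant bone lengths, with the lengths `l` estimated jointly.

The problem is solved by an inexact augmented-Lagrangian method: closed-form
singular-value / element-wise soft-thresholding steps for `Z`, the low-rank
proxy of `X`, and `E`; linear solves for the kernel coefficients and bone
lengths; and a bounded quasi-Newton inner loop with analytic gradients for
the motion itself. A DCT trajectory-basis fit (robust, damped least squares)
provides the initialization. Camera rotations are always an input, never
estimated.

A synthetic-data module generates articulated stick figures performing
concatenations of primitive actions via forward kinematics (bone lengths
exact to machine precision), an orbiting orthographic camera, Gaussian track
noise, sparse gross outliers, and synthetic detector heightmaps — so the
entire pipeline is testable offline.

## Worked example

```python
import numpy as np
import kinelift as kl

# a 13-joint figure performing two actions, seen by an orbiting camera
scene = kl.benchmark_scene(seed=7)

# recover 3-D motion from 2-D tracks and known rotations
result = kl.reconstruct(scene.W_clean, scene.cams, scene.skeleton)
print(f"converged={result.converged} after {result.iterations} iterations")
print("final residuals: %.2e %.2e %.2e" % result.residual_history[-1])

report = kl.emean(result.X_est, scene.X_gt)
print(f"e_mean={report.e_mean:.4f}  e_med={report.e_med:.4f}  flip={report.flip_used}")

labels = kl.affinity_to_clusters(result.Z, 2, seed=0)
print(f"clustering accuracy={kl.clustering_accuracy(scene.action_labels, labels):.3f}")
```

prints

```
converged=True after 153 iterations
final residuals: 9.40e-07 3.14e-10 9.63e-07
e_mean=0.0590  e_med=0.0366  flip=1
clustering accuracy=0.992
```

The residual triple tracks the three constraints (reprojection, affinity
coupling, low-rank coupling), each normalized by the track magnitude.
`e_mean` is the mean 3-D joint error normalized by the ground-truth shape's
average coordinate standard deviation — 0.059 means the average joint lands
within ~6% of the body's spatial spread; `flip=1` says the depth-reflection
ambiguity was resolved without mirroring. The affinity matrix `Z` clusters
the frames back into their two source actions almost perfectly.

The same pipeline runs from the shell:

```
kinelift simulate --actions swing,reach --frames 60,60 --seed 7 --outdir scene/
kinelift reconstruct --tracks scene/tracks.csv --rotations scene/rotations.csv \
         --skeleton scene/skeleton.json --out est.csv --report report.json
kinelift evaluate --est est.csv --gt scene/motion_gt.csv --out metrics.json
kinelift cluster --affinity est_affinity.csv --k 2 --seed 0 --out labels.csv
```

Marker-less mode consumes heightmaps instead of tracks
(`kinelift reconstruct-markerless --heightmaps scene/heightmaps ...`).

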