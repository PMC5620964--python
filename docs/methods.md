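# Methods

## Model

`kinelift` treats monocular 3-D articulated-motion recovery as a regularized
matrix-recovery problem. The unknown motion matrix `X ∈ R^{3NP×NF}` stacks
the NP joint positions of frame f in column f; its frame-wise rearrangement
`X# ∈ R^{3NF×NP}` satisfies the orthographic projection constraint
`W = R X# + E`, with `R` the block-diagonal stack of the known per-frame 2×3
camera matrices (orthonormal rows) and `E` an error matrix. The objective

```
  ‖Z‖* + λ1‖X̂‖* + λ2‖E‖1 + λ3 trace(Cᵀ K(X) C) + λ4 R(X, l),
  W = R X# + E,   X̂ = X,   C = I − Z
```

combines four priors:

1. **Low-rank shape** (`λ1‖X̂‖*`): frames are linear combinations of a few
   basis shapes. The nuclear norm is taken on X (rank bounded by
   min(NF, 3NP)), not X#, so redundancy *across frames* is exploited.
2. **Union of nonlinear subspaces** (`‖Z‖*` + kernel term): each frame
   column, mapped through an implicit feature map, should be expressible as
   a combination of the other frames (`Φ(X) ≈ Φ(X) Z`), with a low-rank
   coefficient matrix. Realized entirely through the kernel Gram matrix
   `K(X)_ij = k(x_i, x_j)`. Frames from the same primitive action end up in
   the same subspace; spectral clustering of `(|Z|+|Zᵀ|)/2` recovers the
   action segmentation.
3. **Sparse gross errors** (`λ2‖E‖1`): tracking/detection failures are
   sparse and large; the L1 penalty absorbs them without distorting the fit
   elsewhere.
4. **Soft inextensibility** (`λ4 R(X, l)`): distances between connected
   joints stay constant. Bone lengths `l` are auxiliary unknowns with a
   closed-form update (per-bone mean length over frames), so no length
   measurements are needed.

Camera rotations are input, never estimated. Orthographic translation is
unobservable: tracks are centred per frame (median over joints — robust to
outliers) and the output motion is reported with zero per-frame 3-D
centroid.

### Kernel

The kernel is Gaussian RBF on frame columns with the median-heuristic
bandwidth (median pairwise distance between frames of the initial estimate),
frozen across iterations to keep the motion subproblem smooth. A `linear`
kernel (`K = XᵀX`) is available; it reduces the regularizer to the classical
linear self-expressiveness `‖XC‖_F²` and serves as an ablation. The
gradient of `trace(CᵀK(X)C)` with respect to X includes the chain rule
through `K(X)`; with `M = CCᵀ`, column i receives
`−(2/σ²) Σ_j M_ij K_ij (x_i − x_j)` (verified against finite differences).
When all frames coincide, the median distance is zero and the bandwidth
falls back to 1 with a logged warning.

## Optimization

An inexact augmented-Lagrangian scheme with multipliers Γ1 (reprojection),
Γ2 (C = I − Z), Γ3 (X̂ = X) and penalty μ growing geometrically
(μ ← min(ρμ, μmax)). One outer iteration updates, in order,

* `Z ← D_{1/μ}(I − C − Γ2/μ)` and `X̂ ← D_{λ1/μ}(X + Γ3/μ)` —
  singular-value soft-thresholding (the proximal operator of the nuclear
  norm), exact minimizers of their subproblems;
* `X` — the only non-convex block: λ3·kernel + λ4·bones + the two quadratic
  coupling terms, minimized by L-BFGS with analytic gradients, warm-started
  at the previous X and capped at `inner_iter` iterations (inexact ALM); the
  returned iterate never increases the subproblem objective;
* `E ← S_{λ2/μ}(W − R X# + Γ1/μ)` — element-wise soft-thresholding;
* `C ← (2λ3 K + μI)^{−1}(μ(I − Z) − Γ2)` — an SPD linear solve (least
  squares with a warning beyond condition number 1e12);
* `l` — per-bone mean length (exact minimizer);
* dual ascent on Γ1, Γ2, Γ3 and the μ step.

Convergence is declared when the largest of the three constraint residuals,
each normalized by max(1, ‖W‖F), falls below `tol`. Convergence of the
overall nonconvex multi-block scheme is not guaranteed in theory; it is
monitored empirically via the recorded residual history and holds on all
study conditions (the rigid fixture reaches 1e−6 in ~140 iterations).

### Initialization

A trajectory-basis fit: each joint's 3-D path is constrained to the span of
the first `n_basis` DCT basis vectors over frames (default NF/8, at least
3), and the coefficients minimize `‖W − R X#‖F` — linear because R is known.
Two safeguards matter in practice:

* **Tikhonov damping** (1e−4; the design matrix has unit top singular
  value). Motion components that track the instantaneous viewing direction
  are nearly unobservable; undamped least squares amplifies them
  catastrophically (observed: solution norms 50× the data scale). The
  damped fit leaves those components small for the solver's priors to fill
  in.
* **Tukey-biweight IRLS** (10 rounds, c = 4.685, robust scale floored at
  5% of the track RMS). Gross outliers otherwise poison the start badly
  enough that the L1 term cannot recover. The floor guarantees that
  basis-truncation mismatch on clean data is never rejected (measured
  rejection rate on clean scenes: <1%).

Bone lengths are initialized from this fit (`l0 = update_lengths(X0)`), and
the RBF bandwidth is resolved on it.

### Parameter defaults

All weights assume tracks normalized to unit RMS (done internally, undone on
output). Defaults, exposed in the config:

| parameter | default | role |
|---|---|---|
| λ1 | 1.0 | nuclear norm of the motion matrix |
| λ2 | 0.15 | L1 error penalty |
| λ3 | 1.0 | kernel self-expressiveness |
| λ4 | 1.0 | bone inextensibility |
| λ5 | 1.0 | heightmap likelihood (marker-less) |
| μ0, ρ, μmax | 1e−3, 1.1, 1e8 | penalty schedule |
| tol, max_iter, inner_iter | 1e−6, 300, 20 | stopping |

λ2 deserves explanation: at convergence the reprojection force any single
observation can exert on the motion is bounded by λ2 (the dual variable of
an active L1 entry saturates at ±λ2). Large λ2 therefore lets outliers
drag the solution; small λ2 caps the fit to *inliers* as well. λ2 = 0.15 —
the same order as the 1/√(max dim) rule customary for L1 terms in robust
matrix recovery — balances the two on the study conditions (clean error
0.059, +39% under 5% gross outliers, 95% outlier localization). The other
weights are unit by construction after RMS normalization.

### Degenerate inputs

Coincident connected joints make the bone gradient undefined; the solver
perturbs them by 1e−6 with a logged warning instead of failing. A
non-finite state raises a diagnostic error carrying the last finite state.

## Marker-less mode

Tracks are replaced by per-(frame, joint) detector *heightmaps* —
nonnegative grids scoring each image position. The observations become an
auxiliary matrix Ŵ re-estimated once per outer iteration (after the E step)
by minimizing, per cell independently,
`−λ5 h_{f,p}(ŵ) + (μ/2)‖ŵ − proj_{f,p}‖²`, where `proj` is the current
reprojection corrected by E and Γ1. Each 2-D subproblem is solved by
projected gradient descent on the bilinearly interpolated surface with
backtracking, seeded at both the anchor and the heightmap argmax; the
coupling W = Ŵ is enforced by substitution, leaving the multiplier
structure unchanged. Ŵ is initialized at the per-map argmax. As μ grows the
quadratic term dominates and Ŵ locks to the reprojection — the heightmaps
act early, the geometry takes over late. Pixel centres sit at integer
(row, col) coordinates, first axis vertical; a grid origin and isotropic
spacing map image coordinates to pixels, and the grid geometry is rescaled
internally to unit track RMS.

## Synthetic data

The generator emulates the structure the method assumes, and is the basis of
every quantitative check:

* **Skeletons**: 13- or 15-joint stick figures (tree connectivity), ~1.7 m.
* **Actions**: four primitives (swing, walk_cycle, reach, crouch) as
  sinusoidal joint-angle trajectories through forward kinematics. Each
  action has its own rotation axes, frequencies, phases *and baseline
  posture* (constant angle offsets — arm raised for reach, knees bent for
  crouch). The offsets are essential: actions oscillating around a shared
  rest pose produce overlapping shape manifolds that no clustering method
  separates, which would make the union-of-subspaces structure vacuous.
  Because offsets are only ever rotated, bone lengths are exact to machine
  precision in every frame. Transitions cross-fade in angle space
  (default 3 frames), preserving exact lengths; the position-space
  `concat_actions` utility is also provided but only approximately preserves
  lengths inside its fade window.
* **Camera**: orbit about the vertical axis at a constant rate, pointing at
  the body centre.
* **Corruption**: i.i.d. Gaussian noise on all track entries (default
  0.01 m ≈ marker-tracking jitter) plus a chosen fraction of (frame, joint)
  cells replaced by uniform gross errors.
* **Heightmaps**: unit Gaussian bumps (σ = 2 px) at the true joint
  locations on a 64×64 grid, optional smooth clutter bumps — a clean-room
  stand-in for a joint detector's output.

Two named configurations define the study conditions:

* `benchmark_scene`: swing + reach, 60 + 60 frames, 1.5°/frame (~180° of
  viewpoint coverage), noiseless — used for end-to-end recovery and the
  marker-less comparison.
* `complex_scene`: swing + reach + crouch, 40 frames each, full amplitude,
  0.5°/frame (~60° coverage), 1 cm noise — used for the clustering and
  ablation studies. The slow camera matters: with ~180° coverage the
  reprojection term alone pins the motion and the kernel prior is inert
  (its ablation changes the error by <1%, within seed noise). The
  union-of-subspaces prior earns its keep exactly when per-action viewpoint
  coverage is limited, which is also the regime typical of real monocular
  footage; the complex-motion experiments are therefore defined there.

What passing tests on this generator do **not** show: performance on real
marker or detector data (soft tissue, occlusion, correlated tracking noise,
non-sinusoidal dynamics), behaviour under missing observations (not
modelled), or accuracy with estimated rather than given camera rotations.

## Evaluation

The mean error `e_mean = (1/(σ NF NP)) Σ e_fp` normalizes per-joint
Euclidean errors by the ground-truth shape's average per-frame coordinate
standard deviation σ; the median error is reported on the same σ scale
(midpoint convention). Monocular orthographic recovery has a global
depth-reflection ambiguity, so the metric is computed for the estimate and
its whole-sequence z-flip and the better one is reported along with the flip
sign (per-frame flipping exists behind a flag, off by default). No
Procrustes alignment is applied; σ is computed from the ground truth only,
so the metric is not symmetric in its arguments.

## Known limitations

* Occlusion / missing tracks are unsupported; every joint must be observed
  (marker-based) or covered by a heightmap (marker-less).
* Rotations must be supplied; small-viewpoint-range sequences remain poorly
  reconstructable regardless of priors.
* The inner motion subproblem is nonconvex; different numerically-equivalent
  inputs (e.g. rescaled tracks) converge to solutions agreeing to ~1%, not
  bitwise (identical inputs are bitwise deterministic).
* Bandwidth is frozen at initialization; pathological initializations would
  propagate into the kernel geometry.
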