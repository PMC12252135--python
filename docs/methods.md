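# Methods

`orchardmot` links per-frame fruit detections from orchard video into
identity-consistent trajectories and derives fruit counts from them.  This
note documents the model, its parameters, the synthetic study conditions,
and the numerical and design choices that are not forced by the mathematics.

## Motion model: adaptive fading-memory Kalman filter

Each track carries an 8-dimensional state
`X = (x, y, w, h, vx, vy, vw, vh)` — box center, box size, and their
per-frame velocities in pixels — under a constant-velocity transition

    F = [[I4, Δt·I4], [0, I4]],   Δt = 1 frame,

and a linear observation `H = [I4, 0]` of the detected box.  A plain
Kalman filter is deliberately used instead of EKF/UKF variants: fruit
motion between consecutive frames is close to uniform, and the linear
filter is cheap and drop-in compatible with standard tracking-by-detection
pipelines.

Noise scales with apparent target size.  At initialization the standard
deviations are

    σ_px = 2·w_p·w,  σ_py = 2·w_p·h,  σ_vx = 10·w_v·w,  σ_vy = 10·w_v·h,

velocity carrying the larger multiplier because it is obtained by
differentiation.  The printed covariance is isotropic per block:
`C0 = diag(σ_p²·I4, σ_v²·I4)` with `σ_p² = σ_px² + σ_py²` and likewise for
velocity.  A config switch (`kalman.per_component_init`) instead places
the distinct per-component variances on the diagonal; the isotropic form
is the default because it is the form the initialization equations state,
even though the per-component sigmas are computed individually.

Defaults `w_p = 1/20`, `w_v = 1/160` follow the BoT-SORT convention from
which the 2/10 multipliers are taken.  The same convention supplies the
per-step process noise, rebuilt from the current box each predict:

    Q = diag((w_p·w)², (w_p·h)², (w_p·w)², (w_p·h)²,
             (w_v·w)², (w_v·h)², (w_v·w)², (w_v·h)²),

and the observation noise `S = σ_p²·I4` recomputed from the predicted box.

### The variable forgetting factor

After prediction, the measurement residual `δ = z − H·X⁻` drives a
fading-memory coefficient

    λ_t = λ_min + (λ_max − λ_min)·exp(−γ·‖δ‖²),     0 < λ_min ≤ λ_t ≤ λ_max ≤ 1,

and the covariance update becomes

    C⁺ = (I − K·H)·C⁻ / λ_t + (1 − 1/λ_t)·C_prev,

where `C_prev` is the previous *updated* covariance.  Small residuals give
`λ_t → λ_max` (the textbook update when `λ_max = 1`); large residuals
shrink `λ_t`, inflating the covariance so the filter re-converges quickly
after abrupt motion.  Defaults: `λ_min = 0.6`, `λ_max = 1.0`,
`γ = 0.01 px⁻²` — all exposed in config, since only the admissible range
is prescribed by the formulation.

Numerical notes:

- With `λ_t < 1` the second term is negative and the recursion can lose
  positive semi-definiteness.  The covariance is therefore symmetrized and
  its eigenvalues floored at `1e-6·trace(C⁻)/8` after every update.
  Without this the filter can diverge on adversarial residual sequences.
- Near steady state `(I − KH)·C⁻ ≈ C_prev`, so the two λ-terms largely
  cancel and the net inflation acts only on their difference.  The
  adaptive filter therefore improves on the fixed `λ = 1` filter
  consistently but mildly at the default `γ`; the benefit grows with the
  residual magnitude (i.e. with maneuver size relative to box size).
- `‖δ‖²` is the raw pixel-squared norm, which is scale-dependent: the same
  physical maneuver produces larger residuals on larger boxes.  The
  literal form is the default; `kalman.residual_normalized` divides by
  `trace(H·C⁻·Hᵀ + S)` for a scale-free variant.
- Box sides in the state are floored at 1 px after updates so IoU and the
  size-dependent noise models remain well defined.

## Camera-motion compensation

Global camera motion between consecutive frames is modeled as a 2×3
affine `A` fitted to matched image points `(p_i, q_i)` with `p_i` in the
current frame and `q_i` its match in the previous frame (`q ≈ A·[p; 1]`,
so `A` maps current→previous).  Estimation is RANSAC (defaults: 100
iterations, 3 px inlier tolerance, minimal 3-point samples, ≥50% consensus)
followed by a least-squares refit on the consensus set; degenerate or
insufficient input falls back to the identity transform rather than
raising.  Predicted boxes — which live in previous-frame coordinates — are
brought into the current frame by applying `A⁻¹` to their centers and
scaling width/height by the column norms `(s_x, s_y)` of the linear part.

Two deliberate literalisms, both flagged rather than silently corrected:

- Multiplying sizes by `(s_x, s_y)` is dimensionally inconsistent with
  applying the *inverse* to centers under zoom; `camera.inverse_scale`
  switches to dividing.  Under pure translation (the dominant orchard
  case) the two coincide.
- Correspondences are ingested, not computed: they come from a sidecar
  file, from a mutual-nearest-neighbour prematch of detection centers
  between consecutive frames, or (in tests) from the generator's true
  camera model (`camera.source`).  Pixel-level optical flow is out of
  scope since the library never consumes images.

Compensation is applied to predicted boxes after the predict step and
before association.

## Data association

Spatial affinity is IoU distance `d_IoU = 1 − |A∩B|/|A∪B|`; appearance
affinity is cosine distance `d_ReID = 1 − a·b/(‖a‖‖b‖)` between the
detection embedding and the track's exponentially smoothed embedding

    f̄_{t+1} = α·f̄_t + (1−α)·f_{t+1},   α = 0.9,

L2-renormalized after mixing (the bare average shrinks the norm whenever
the vectors disagree, which would mis-calibrate subsequent cosine
distances).  Fusion follows the minimum-value rule with two filters, in
this order:

1. spatial gate: pairs with `d_IoU > θ_iou` (default 0.7) are inadmissible;
2. Re-ID filter: pairs with `d_ReID > θ_reid` (default 0.25) are excluded
   from appearance fusion and keep their motion-only cost `d_IoU`
   (`assoc.strict_reid_filter` drops them entirely instead);
3. remaining pairs cost `min(d_IoU, d_ReID)`.

The fallback (rather than hard-drop) default keeps recall when embeddings
are noisy; the order gate → filter → min is a design choice of this
package.  The assignment is the minimum-total-cost bipartite matching
(Jonker–Volgenant via `scipy.optimize.linear_sum_assignment`); solved
pairs costing more than `assoc.match_gate` (default 0.8) are demoted to
unmatched.

## Track lifecycle and counting

A detection with no match spawns a *tentative* track; `tracker.n_init = 3`
consecutive hits confirm it; a tentative track dies on its first miss.
Confirmed tracks that miss become *lost* but keep being predicted,
compensated, and offered to the associator (the re-identification window)
until `tracker.max_age = 30` consecutive misses (3 s at 10 fps) remove
them.  Ids are assigned once and never reused.

Counting emits two per-frame curves: **cumulative** (distinct ids ever
confirmed — the quantity a final fruit count needs, and the default for
R²/RMSE evaluation) and **active** (confirmed ids currently matched or
coasting).  Fruits are counted at confirmation, not first detection: this
delays the count by `n_init − 1` frames but keeps clutter from ever being
counted.  Result files contain confirmed tracks in the frames they were
actually matched.

An optional ByteTrack-style second association stage on low-confidence
detections exists (`tracker.two_stage`) but is off by default; the
single-stage pipeline is the documented form.

## Evaluation metrics

GT↔result matching per frame follows the MOTChallenge convention:
bipartite minimum-IoU-distance assignment restricted to IoU ≥ 0.5
(threshold exposed), with continuation preference — an existing pair is
kept while it stays admissible — and identity switches counted against a
ground-truth id's last known partner across gaps.  MOTA and IDF1 are the
standard forms; the identity counts come from the optimal trajectory-level
bipartite matching.  The test suite checks both against an independent
from-scratch implementation of the published definitions.

HOTA is provided in two forms.  `hota_paper` is a single-threshold
simplification, `Σ_c A(c) / (TP + FN + FP)`, in which each true-positive
match scores the fraction of its identity pair's matched frames among all
matched frames involving either id — detection misses do not enter `A(c)`.
`hota_standard` is the usual multi-threshold `mean_α sqrt(DetA·AssA)` with
trajectory lengths in the association denominator.  The two differ by
construction; both are reported.

Counting agreement uses `R² = 1 − Σ(n_t−n̂_t)²/Σ(n_t−n̄)²` and RMSE on the
per-frame curves, an OLS regression line of estimate on truth, and the
discrete Fréchet distance computed on raw `(frame_index, count)` points
with no normalization.

## Synthetic study conditions

The generator emulates a fruit-counting fly-by: 250 frames at 10 fps,
5 trees, 5 fruits per tree (25 identities), a 1280×720 image.  Fruits are
near-static in the world — apparent motion comes from a constant camera
pan of 4 px/frame, matching orchard videography where the camera moves
along the row (an optional wind mode adds per-fruit drift, and discrete
velocity jumps can be injected to exercise the fading filter).  Tree
placement keeps every fruit in view for at least 40 frames so each
identity is confirmable.  Detector imperfections: 5% missed detections,
2% clutter (sampled with realistic sizes so false positives genuinely
challenge the associator), 1 px Gaussian box noise, confidences uniform in
[0.6, 1].  Per-fruit occlusion gaps (probability 0.3, length 3–10 frames)
stay well below `max_age`.  Embeddings are fixed per-identity unit vectors
(dimension 16, enforced inter-identity cosine separation ≥ 0.3) plus
intra-identity noise σ = 0.05.  One global seed fans out to per-component
substreams, so toggling one disturbance leaves the others unchanged.

What the generator does **not** emulate: photorealistic appearance,
perspective and parallax (trees at different depths move differently under
pan), detector confidence correlated with occlusion, embedding drift with
viewpoint, and long-term re-entries.  Passing tests therefore demonstrate
the correctness and robustness of the tracking machinery under controlled
disturbances, not field performance with a real detector.

Problem sizes used by the shipped checks — 100 scenes of 250 frames for
counting, 50 tracks of 100 frames for the filter comparisons, 20 seeded
sequences for the metric oracles — were chosen to make the statistical
assertions stable while keeping a full run in the minutes range.

## Known limitations

- The fading-memory gain at default `γ = 0.01 px⁻²` is conservative (see
  above); applications with large, frequent maneuvers should raise `γ` or
  enable residual normalization.
- `hota_paper` is not comparable to values from standard HOTA tooling; use
  `hota_standard` for that.
- The affine model cannot represent parallax; strong depth structure in a
  scene degrades compensation to a best-fit average motion.
- Counting at confirmation undercounts fruits visible for fewer than
  `n_init` frames at the sequence boundary.
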