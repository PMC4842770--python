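# Methods

This note documents the models, defaults and numerical choices behind
`cortimap`, and what the synthetic generators do and do not emulate.

## Coordinate conventions and surfaces

All geometry is in millimetres, RAS-oriented (x left→right, y
posterior→anterior, z inferior→superior), matching MNI/Talairach-style
model spaces. No axis flips are ever applied implicitly; external
coordinates enter through an explicit affine (`import_coordinates`).

The brain surface is a plain triangle mesh. Surface extraction is out of
scope: meshes come from MRI reconstructions exported by other software
(OFF/PLY/STL/GIfTI importers are provided) and are stored in a documented
little-endian binary container — 8-byte magic `CORTIMOF`, `uint32` vertex
and face counts, a `float32` V×3 vertex block and a `uint32` F×3 face
block with 0-based indices. Vertices therefore round-trip at `float32`
precision; faces exactly. Validation drops degenerate faces (repeated
index or area < 1e-12 mm²) and rejects out-of-range indices and meshes
with fewer than 4 vertices.

**Fineness control.** Decimation uses quadric edge collapse (Garland–
Heckbert vertex quadrics, optimal collapse point from the 3×3 quadric
system with endpoint/midpoint fallback when ill-conditioned,
condition-number cut 1e7). Boundary vertices are frozen; collapses that
would flip a surviving face normal are skipped. The heap order is fully
deterministic given the input vertex/face order, which also makes the
face count monotone in the target fraction (two runs follow the same
collapse sequence and merely stop at different points). Each interior
collapse removes exactly two faces, so the result lands within two faces
of the requested count.

## Camera and ray casting

The camera is a perspective pinhole with a vertical field of view
(default 30°), a roll angle about the view axis, and the view distance
derived from position and focal point. Pixel coordinates are continuous
with origin at the top-left and the viewport centre mapping exactly onto
the view axis; directions are normalized by half the viewport *height*,
so scaling viewport and pixel coordinates together yields the same ray
(resolution covariance). An orthographic mode is deliberately not the
default — interactive mapping tools render perspective views.

Ray/mesh intersection is vectorized Möller–Trumbore over every face with
barycentric slack 1e-12 and minimum ray parameter 1e-9 mm; the nearest
positive hit wins and exact parameter ties (a ray grazing a shared edge)
resolve to the lowest face index for determinism. The test suite and the
acceptance script check this against an independent scalar loop-based
reference.

Electrode tuning snaps the requested offset to integer multiples of the
step (default 0.1 mm, any positive step allowed) and intentionally does
**not** re-project onto the surface: post-implantation brain deformation
is corrected by moving contacts off the nominal surface.

Default ball style: radius 2 mm, red (1, 0, 0).

## Surface mapping

Both interpolants use Euclidean 3D distance, not geodesic distance —
this matches what renderer-side interpolation does and is exact for the
convex fixture surfaces; geodesic support would only matter across sulci
on folded cortex and is a known limitation.

* Gaussian: normalized kernel weights `exp(-d²/2σ²)`; the "extend"
  parameter is σ in mm, default 10 mm (on the order of inter-contact
  spacing). Weights are shifted by the per-vertex nearest-contact
  distance before exponentiation, so the map is numerically stable down
  to σ → 0 (where it degenerates to the Voronoi/nearest-contact
  labeling) and up to σ → ∞ (the global mean). Normalization makes every
  vertex a convex combination of the inputs; an additive (unnormalized)
  kernel variant would not bound the field by the data range, which is
  why the normalized form was chosen.
* Linear: hat weights `max(0, 1 - d/R)`, default R = 15 mm (≈1.5× a
  typical 10 mm contact spacing); vertices outside every support are
  flagged uncovered, rendered in the base surface color and excluded
  from range computation.

Color ranges are auto (data min/max of the plotted row, degenerate
all-equal ranges widened by ±1e-9) or manual with clamping. The default
colormap is the blue→red diverging `coolwarm`; any named matplotlib
colormap may be substituted.

## Networks

Edges are pairs with correlation **strictly** above τ (so a τ at the
matrix maximum, e.g. ≥1 for PLV, hides everything). Automatic
thresholding at sparsity *s* returns the ⌈s·n(n−1)/2⌉-th largest
off-diagonal value nudged down by one ulp, so the strict comparison
keeps exactly that many edges; tied values at the cut all survive (and
are logged). Default sparsity is 0.1 — no canonical value exists, so it
is exposed and logged wherever used. Signed matrices are compared as
signed values by default with an `use_abs` option. Node strength is the
sum of incident surviving edge weights (degree in binary mode); the
"replot nodes" coloring uses the *thresholded* (displayed) network,
since that is what the viewer shows — the unthresholded alternative is a
one-liner via `threshold_edges(C, -inf)`.

Input matrices are symmetrized by (C+Cᵀ)/2; asymmetry above 1e-6
triggers a warning first. The diagonal is never consumed.

## Signal pipeline

Defaults reproduce a standard clinical language-mapping parameterization
and are all overridable:

| step | default | note |
|---|---|---|
| band-pass | 0.5–250 Hz | 4th-order Butterworth, `sosfiltfilt` (zero phase) |
| epoch window | −800 … +3500 ms | 4300 ms, half-open in samples |
| rejection | 6 robust SDs | see below |
| bands | Δ 1–4, θ 4–8, α 8–16, β 16–30, low γ 30–80, high γ 80–250 Hz | |
| PLV edge trim | 10 % per segment edge | filter transients |
| display threshold | 0.6 | strict `>` |

**Rejection.** "Apparent noise" is operationalized deterministically: an
epoch is dropped iff, on any channel, its peak-to-peak amplitude exceeds
the channel's *median* per-epoch peak-to-peak by more than
`amp_thresh_sd` × 1.4826 × MAD of those peak-to-peak values. A rule
comparing peak-to-peak against a multiple of the raw sample SD would
reject every epoch of clean Gaussian data once epochs reach a few
thousand samples (expected white-noise peak-to-peak is ≈6.6 σ), so the
deviation-from-median form is used; identical clean epochs are never
dropped and an injected artifact epoch always is. Below 8 epochs the MAD
spread estimate is too unstable, so rejection keeps everything and warns.

**PLV.** Phases come from the analytic signal (Hilbert transform) of the
band-passed data; for epoched input the per-trial phases are trimmed and
concatenated before averaging (a per-trial-then-average mode is a
straightforward variant but concatenation is the default and is what the
tests pin down). The estimator itself,
`PLV_ij = |mean exp(i(φ_i − φ_j))|`, is exposed separately as
`plv_from_phases`.

**Closed-form validation.** The coupled-pair generator draws the
per-sample phase difference i.i.d. from von Mises(0, κ), so the
population PLV is exactly `I₁(κ)/I₀(κ)`. The recovery check applies
`plv_from_phases` to the generator's ground-truth phases
(`return_phases=True`): a narrow-band filter smooths i.i.d. per-sample
phase jitter and would bias any phase-*estimation* route upward, so
estimator and phase-extraction are validated separately — the
filter+Hilbert pipeline on its own contracts (exact copies and
constant-lag sinusoids give PLV 1 − 10⁻³; independent wide-band noise at
~10⁴ effective samples stays under the Rayleigh-null 0.05 line).

## Rendering

The renderer is a deterministic software painter on the matplotlib Agg
canvas: faces, electrode balls and connection sticks are projected
through the same pinhole model as `cast_ray`, depth-sorted (far→near by
mean view depth, insertion order as tie-break) and drawn in that order.
Faces are Lambert-shaded against the view direction; at full opacity
each face is also stroked with its own color to close anti-aliasing
seams between adjacent triangles. Translucent surfaces (opacity < 1)
let interior electrodes show through, opaque ones hide them — matching
interactive viewers. Identical scenes produce byte-identical buffers;
PNG is the default output, BMP is kept for legacy workflows. The
colorbar is a fixed right-side vertical bar; labels are billboard text
above each ball.

## Synthetic data: what it does and does not show

The generators exist so every operation is testable from scratch:

* `make_brain_mesh` — an icosphere (10·4ˢ+2 vertices) scaled to
  140×170×120 mm. It is smooth and convex; passing tests demonstrate
  geometric and numerical correctness, **not** behavior on folded
  cortical anatomy (e.g. Euclidean-vs-geodesic differences are invisible
  here).
* `make_strip` / `make_case_study_montage` — strips marched along the
  surface tangent with the chord length between consecutive contacts
  iterated to the nominal spacing (10 mm); the case montage is four
  16-contact strips on the left lateral aspect, channels 1–64 ordered
  superior→inferior.
* `make_erp_dataset` — a damped 8 Hz template starting 200 ms
  post-onset (peak 50 µV, 0.4 s decay) times a smooth two-bump channel
  gain profile, plus white noise; `snr` is template RMS (over its
  support, strongest channel) divided by noise SD. Sampling rate
  defaults to 600 Hz, the smallest rate whose Nyquist comfortably clears
  the 80–250 Hz band. Trial timing is drawn from a fixed stream so the
  seed changes only the noise. Real iEEG noise is neither white nor
  stationary; rejection and averaging results here show correctness of
  the rules, not clinical artifact sensitivity.
* `make_coupled_pair` — see the PLV section above.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
subdivision-3 meshes (1280 faces), 64-contact montages, 100-ray oracle
sweeps, 10⁵-sample PLV recovery, 100 random threshold matrices, and a
6-trial / 64-channel end-to-end demo rendered at 320×240. All sizes are
arguments, so heavier runs are one call away.
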