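# Methods

## Measurement model

`cellspin` treats a cell's in-plane self-rotation as an appearance
periodicity problem: if the cell's image differs at different rotation
angles, then the normalized correlation between a fixed reference patch
and the best-matching patch in each frame is a periodic function of time
whose peaks mark whole revolutions.  The measurement therefore assumes

* the cell rotates in the image plane (out-of-plane tumbling is not
  modeled);
* the cell's appearance is not rotationally symmetric — a featureless
  disk has no measurable periodicity;
* the camera and stage are static, so a temporal mean of the first `N`
  frames is a valid background image;
* `N` exceeds the number of frames in one revolution (caller's
  responsibility; with the defaults, 40 frames at 15 fps covers any speed
  above ~22.5 rpm, and slower cells need a proportionally larger `N`).

Pixel coordinates are `(u, v) = (row, column)`, 0-based; frame indices are
1-based throughout the public API.  Color input is converted to grayscale
with ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded half-up; sources
deeper than 8 bits are rescaled linearly to 0–255.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `n_background` | 40 frames | frames averaged into the background and searched for the reference frame |
| `struct_radius` | 3 px | radius of the flat disk structuring element used for opening/closing the binarized difference image |
| `roi` (W, H) | user | template half extents; the rectangle should cover the cell as tightly as possible |
| `lbound` | 0.5 (or `"auto"`) | correlation threshold above which local maxima of the trace count as revolutions |

Details fixed by this implementation where the procedure leaves room:

* **Otsu threshold.** Computed on a 256-bin histogram (intensities binned
  by integer part); the smallest maximizing level wins ties; binarization
  is strictly greater-than, so a constant image yields an empty
  foreground.  Rounding of component centroids and radii is half-up.
* **Connectivity** for component labeling is 8-connected; nearest-component
  ties go to the smaller label (raster order).
* **Moving region vs. search window.**  Candidate template centers are the
  tracked moving region `Rect[(uᵢ, vᵢ), 2rᵢ+1, 2rᵢ+1]`; the stored search
  window `Rect[(uᵢ, vᵢ), 2rᵢ+2W+1, 2rᵢ+2H+1]` is exactly that candidate
  set dilated by the template half extents, i.e. the pixel support any
  candidate placement can touch.  Searching centers over the full window
  instead lets the matcher lock onto background patches mid-cycle
  (measured ~0.5 correlation floor), which produces spurious peaks.
* **A washed-out frame** (no components) inherits the previous frame's
  center and radius with a logged warning; an empty first frame is a hard
  error because tracking has nowhere to start.
* **Zero-variance patches** define a correlation of 0: a blank patch
  carries no rotational information and must never outrank a textured
  match.  Argmax ties resolve to the first candidate in raster order.
* **Peak rule.** A peak is a strict interior local maximum; plateaus
  collapse to their first frame; endpoint frames are dropped (no parabola
  support).  The fitted vertex of a strict local maximum always lies
  within ±0.5 frames of the integer peak.
* **best_match** evaluates the correlation surface with FFT correlation
  plus integral-image patch variances and then re-evaluates near-maximal
  placements with the literal coefficient, preserving exact raster-order
  tie-breaks; the literal double-sum form remains the public `ncc` and
  the oracle in the tests.

### Automatic threshold selection

The peak threshold must separate once-per-revolution peaks from smaller
spurious local maxima, and in practice it is adjusted per video.
`lbound="auto"` codifies that adjustment: every threshold on a grid
(0.30–0.90, step 0.025) is scored by the peak train it produces, and a
train is accepted only if its intervals are regular (coefficient of
variation ≤ 0.10), physically plausible (no interval under 4 frames,
i.e. 225 rpm at 15 fps) and not height-alternating (a threshold that
admits one spurious bump per revolution produces peaks of alternating
height).  The longest accepted train wins, ties going to the higher
threshold.  If no threshold yields a regular train the function returns a
threshold above every local maximum, so the fit comes back with *no
complete cycle* — an explicitly flagged outcome, preferable to a silently
wrong number.  The procedure sees only the trace, never any ground truth.

Residual failure modes, observed at roughly a 3% rate per run in the
synthetic study conditions: a two-peak doubled train cannot be screened by
the alternation test (too few peaks), and when genuine peaks are missing
the regular every-second-revolution subharmonic can win.  Both produce a
plausible-looking but wrong speed; both are rare and seed-specific.

## Dielectric model

`cellspin.electrokinetics` is deliberately decoupled from the imaging
pipeline (predicting a steady-state rotation rate would additionally
require a rotational drag model).  It provides:

* `cm_real(params, ω)` — real part of the single-shell Clausius–Mossotti
  factor, written in terms of the relaxation times τ_c = ε_c/σ_c,
  τ₁ = ε_m/σ_m, τ₂ = C_mem·R/σ_c, τ₂′ = C_mem·R/σ_m and evaluated with
  genuine complex arithmetic.  The DC limit is exactly ½ for any physical
  parameters; the function is bounded in [−1, 1.5] and pole-free for
  positive parameters.
* `dep_force_magnitude` — the time-averaged dielectrophoretic force
  2πR³ε_m Re[K] ∇|E_rms|²; negative values mean repulsion from the
  high-field region.
* `rotation_torque(params, X, X₀)` — the self-rotation torque of a
  shelled particle in a linearly polarized field, with X = ωτ,
  X₀ = ω₀τ, τ = (ε_p + 2ε_m)/(σ_p + 2σ_m).  The field-energy
  permittivity ε₁ is taken as the medium permittivity ε_m, the reading
  most consistent with the surrounding definitions; X and X₀ are plain
  inputs since the relation between the cellular-motion frequency ω₀ and
  the measured rotation rate is not part of this model.  The torque is
  odd in X when X₀ = 0 and vanishes when ε_r = σ_r.

## Synthetic scenes: what they emulate, and what they do not

The generator renders ~12 µm cells as 15 px-radius disks at 15 fps with
additive Gaussian camera noise (σ = 3 gray levels, 8-bit quantized) over a
static, weakly speckled background — the study conditions of the OEK
chip recordings the pipeline targets.  Rotation is in-plane, by bilinear
resampling of a cell-fixed texture; angles are accumulated modulo 360°,
so integer-frame periods repeat bit-exactly in the noise-free case, and
identical seeds reproduce identical videos.

The cell texture is a two-zone "dartboard": an outer annulus of four wide
uniform sectors and an inner disk of eight narrow ones, with
independently placed boundaries, bright membrane-like ridges along the
boundaries, and multiplicative plus additive speckle.  The design is
driven by three measurable properties that real rotating cells exhibit
and the algorithm relies on:

1. *Solid difference blobs.*  Sector levels keep |I − background| large
   everywhere inside the disk at every angle (ridges bridge the level
   transitions), so Otsu + opening/closing yields one component per cell.
2. *A single wide correlation lobe.*  The outer sectors give a
   correlation-vs-angle curve with one peak per turn that stays above the
   peak threshold out to ±30° — necessary at 149 rpm/15 fps, where frames
   sample every 59.6° — while the level patterns are chosen with
   non-positive circular autocorrelation at every whole-sector shift, so
   no other angle re-aligns the pattern.
3. *No translation spoofing.*  The inner wheel's fine alternation makes
   rotated-plus-shifted placements decorrelate, keeping the off-angle
   maximum over all placements in the moving region below the peak
   threshold.

What the scenes do **not** model: out-of-plane tumbling, shape changes,
optics (PSF, shot noise, defocus drift), illumination flicker, and
crowded fields with touching cells.  Passing on these fixtures
demonstrates the algorithm's logic under its stated assumptions, not
robustness to every laboratory artifact.

Two real effects of the static-background model are worth knowing.  For a
*stationary* rotating cell, the background contains the cell's angular
average, so the difference components are texture lobes whose centroid
orbits the true center by a few pixels; the moving region still covers
the cell and downstream matching is unaffected.  For a *translating*
cell, the difference centroid is biased by the cell's own temporal smear
(median ~1 px, single frames up to ~10 px), and with sub-pixel per-frame
velocities the integer-grid template chaining accumulates a slow drift
along the motion (~0.2 px/frame); at integer velocities the chaining is
exact.

## Problem sizes

The shipped tests and the acceptance script use the study-scale problems
throughout: 150–175-frame videos at 128²–160² px (the reference video is
158 frames, matching the recorded sequence length the method was designed
around), 20 replicates for the sub-frame-fitting comparison, and
five-speed sweeps over 11.1–149 rpm.  A full pipeline run on one such
video takes about one second on a single CPU.  A 10-s video at 11.1 rpm
holds only 1.85 revolutions; when the reference frame lands such that
fewer than two interior peaks exist, the fit reports *no complete cycle*
and the harness records a fresh video with a derived seed (up to five
attempts), as an operator would.

## Known limitations

* Cells whose appearance is (nearly) rotationally symmetric cannot be
  measured — the correlation trace carries no periodicity.
* Speeds above ~225 rpm at 15 fps are rejected by the auto-threshold's
  minimum-period guard; near 150 rpm the method already samples fewer
  than three frames per revolution.
* One cell of interest per run; no occlusion handling or cell-division
  logic.
* The trajectory is reported at integer pixel resolution at the peak
  frames only, exactly as defined by the matching step.
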