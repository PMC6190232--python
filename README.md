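# cellspin

Automated measurement of the **self-rotational speed** and motion trajectory
of a single cell in a microscopy video, for optically-induced
electrokinetics (OEK) experiments in which cells spin about their own axis
in a linearly polarized AC electric field.

In such experiments a chip full of lymphoblast-sized cells (~12 µm) is
recorded at ~15 fps while individual cells self-rotate at 10–150 rpm.  The
rotation rate versus field frequency encodes the cell's dielectric
properties, so measuring it accurately — without a stopwatch and a patient
operator — is the bottleneck.  `cellspin` automates the whole measurement:
you mark the cell of interest with one rectangle in the first frame, and
the library returns per-revolution speeds with sub-frame timing accuracy
plus the cell's trajectory.

## Method

Given frames *f₁…f_N* and a rectangle Rect[(u_R, v_R), 2W+1, 2H+1] around
the cell in frame 1:

1. **Background subtraction & tracking.** A static background
   *f_B = (1/N) Σ fᵢ* is averaged from the first *N* frames (*N* must
   exceed one rotation period).  Each difference image |fᵢ − f_B| is
   binarized at Otsu's threshold (the level maximizing between-class
   variance), cleaned by morphological opening and closing with a flat disk
   (radius 3 px by default), and its connected components are labeled.  The
   component nearest the previous position is the cell's *moving region*
   (center (uᵢ, vᵢ), radius rᵢ).
2. **Reference frame selection.**  The region of interest is chained
   forward — in each frame it is the patch maximizing the normalized
   correlation coefficient

   R = Σ(a−ā)(b−b̄) / √(Σ(a−ā)² Σ(b−b̄)²)

   with the previous frame's patch, searched over the moving region.  The
   frame whose patch is least similar to *both* temporal neighbors (smallest
   sum of ascending-sort ranks of C_{i,i−1} and C_{i+1,i}) becomes the
   reference *f_T*: the template that is most distinctive per revolution.
3. **Speed extraction.**  Every frame is matched against the reference
   patch, giving the trace {C_iT}, which peaks once per revolution.  Local
   maxima above a threshold *lbound* are refined by fitting a parabola
   through each peak and its two neighbors; the per-cycle speed is

   n = 60 · f_fps / (Xᵢ − Xᵢ₋₁)  [rpm]

   with Xᵢ the fitted vertex abscissas in frames.  The trajectory is the
   matched patch centers at the peak frames.

The package also implements the electrokinetic side as standalone
utilities: the time-averaged DEP force ⟨F⟩ = 2πR³ε_m Re[K(ω)] ∇|E_rms|²,
the real part of the single-shell Clausius–Mossotti factor K(ω) (membrane
capacitance model, evaluated with complex arithmetic), and the
self-rotation torque T(X, X₀) of a shelled particle in a linearly polarized
field.  A ground-truth synthetic video generator
(`cellspin.synthetic`) renders rotating textured cells so every pipeline
stage is testable without laboratory recordings.

## Worked example

```python
from cellspin import SelfRotationModel, render, single_cell_scene

# a synthetic ground-truth video: one cell, 54.76 rpm, 15 fps, 158 frames
seq, manifest = render(single_cell_scene(rpm=54.76, n_frames=158, seed=1))

model = SelfRotationModel(seq, roi=(64, 64, 16, 16), lbound="auto")
res = model.fit()
print(res.summary())
```

```
Self-rotation speed measurement
==============================================
frames                                     158
frame rate (fps)                        15.000
reference frame                              2
peaks found                                 10
complete cycles                              9
mean speed (rpm)                         54.75
cycle speed std (rpm)                     0.54
speed range (rpm)               54.0 -    55.4
interval std, integer (fr)                0.53
interval std, parabola (fr)               0.16
lbound                                    0.85
n_background                                40
struct radius (px)                           3
==============================================
```

The cell was rendered at 54.76 rpm and the pipeline recovers a nine-cycle
mean of 54.75 rpm; per-cycle speeds span 54.0–55.4 rpm.  The two interval
standard deviations show the effect of the parabolic sub-frame fit: cycle
lengths measured from integer peak frames scatter by 0.53 frames (the true
16.43-frame period forces 16/17 alternation), while the fitted vertices
scatter by only 0.16 frames.  `res.trajectory_points` holds the matched
patch centers at the peak frames, and `res.plot_trace()` /
`res.plot_trajectory()` draw the correlation trace and the motion path.

The same pipeline is available from the shell:

```sh
cellspin simulate --out video/ --rpm 54.76 --frames 158 --seed 1
cellspin extract  --input video/ --fps 15 --roi 64,64,16,16 \
                  --lbound auto --out results/
cellspin sweep-lbound --input video/ --fps 15 --roi 64,64,16,16 --out sweep.csv
cellspin dielectric --out cm_factor.csv        # Re[K(ω)] and torque tables
```

`extract` writes `results.csv` (one row per cycle and per trajectory
point) and `summary.json` (mean rpm, cycle count, reference frame,
parameters).

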