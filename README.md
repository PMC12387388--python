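# planim

Decision support for **mitral stenosis** from transesophageal
echocardiogram videos, for cardiology researchers and engineers working
on automated valve assessment.

Mitral stenosis is the failure of the mitral valve to open fully.  Its
planimetric severity criterion is the **maximum mitral valve area
(MVA)** — the orifice area at peak diastolic opening, in cm²:

| MVA (cm²)        | grade        |
|------------------|--------------|
| a ≥ 4.0          | no stenosis  |
| 1.5 < a < 4.0    | mild         |
| 1.0 ≤ a ≤ 1.5    | moderate     |
| a < 1.0          | severe       |

`planim` measures the MVA directly from an AVI video by classical
digital image processing, and separately offers a CNN that screens
videos for the presence/absence of stenosis.

## The measurement algorithm

For each video frame *f(x, y)* in RGB:

1. **Luminance conversion** — `L = 0.2989·R + 0.5870·G + 0.1140·B`,
   rounded to the nearest integer.
2. **Single-band fixed threshold** — binary output `v_out = 1` iff
   `v_in > t`, with `0 < t < 255`.  Bright pixels are valve/heart
   tissue; dark pixels are the background or, when enclosed by tissue,
   the valve orifice.
3. **Orifice planimetry** — the largest 8-connected dark region not
   touching the image border is the orifice.  Its area is the interior
   pixel count times the physical pixel area; the pixel area comes from
   vendor calibration markers (Philips green-dot ruler or GE scale
   line) burnt into the frame.
4. **Threshold scan** — thresholds t = 10, 11, …, 30 are applied in
   turn; each keeps the frame with the largest orifice.  The scan stops
   at the first threshold whose contour perimeter differs from the
   previous one's by more than 1.0 cm (the contour has leaked into the
   background) and selects the *penultimate* threshold, or runs to the
   cap of 30.  The selected record's area is the MVA, which the grading
   table above converts into a severity call.

The CNN arm (four 3×3-kernel convolution blocks with 32/64/128/256
filters and max pooling, dense 512, softmax over two classes; Adam,
batch 100, ≤10 epochs, early stopping on test loss) classifies single
frames and aggregates a per-video verdict by majority vote.  Frame
datasets are expanded ×6 with random rotation (±40°), shifts (±20%),
shear, zoom and horizontal flips before a 70/30 train/test split; whole
videos can be held out so validation videos are genuinely unseen.
Note that the frame-level split alone would leak frames of one video
into both sides — the video-level holdout is the leakage-free check.

Because clinical recordings cannot be redistributed, the package ships
a **phantom generator**: synthetic echo-like AVI videos with a colored
tissue disk, a central orifice following a raised-cosine open–close
cycle with known diastolic maximum, calibration markers, speckle-like
noise, and (for stenotic phantoms) a thickened leaflet rim.  Every
stage is tested against phantom ground truth.

## Worked example

```sh
$ planim phantom --mva 2.7 --frames 16 --seed 5 --out ph.avi --truth truth.json
wrote ph.avi: max area 2.701 cm² at frame 8

$ planim measure ph.avi --save-frame sel.png
MVA 2.70 cm² (threshold 30, frame 8, threshold_cap) -> mild
```

The phantom was asked for a 2.7 cm² diastolic orifice; rasterization
delivered 2.701 cm², peaking at frame 8.  The measurement pipeline
re-read the video, calibrated from the green-dot ruler, scanned
thresholds 10–30 (no perimeter jump, so the cap of 30 was selected),
and recovered 2.70 cm² on the correct frame — mild stenosis, since
1.5 < 2.70 < 4.0.  `sel.png` shows the selected frame with the orifice
contour drawn as a solid white line.

Grading a cohort of MVA measurements (here the bundled 30-exam
reference cohort):

```sh
$ planim cohort
grade,count,percent
no_stenosis,8,26.7
mild,8,26.7
moderate,4,13.3
severe,10,33.3
```

Other subcommands: `grade` (one value), `augment`/`split` (dataset
preparation), `train`/`predict` (CNN screening), `compare` (planimetry
and CNN verdicts side by side, flagging disagreement).  Exit codes:
0 success, 2 validation error, 3 I/O error, 4 calibration failure.

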