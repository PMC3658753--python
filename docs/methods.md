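# Methods

## The model

`hscsaliency` implements a bottom-up visual-attention model in which an
image is treated as a single hypercomplex (quaternion) signal rather than a
stack of independent feature channels. Each pixel of an HSV image becomes a
pure quaternion

    q(x, y) = H·i + S·j + V·k,

and a video frame additionally carries a five-frame motion cue M_t on the
scalar part,

    q_t(x, y) = M_t + H_t·i + S_t·j + V_t·k.

Saliency is computed in the quaternion frequency domain. The symplectic
decomposition q = f1 + f2·j with f1 = w + x·i, f2 = y + z·i places both
halves in the complex subfield spanned by {1, i}, so the left-sided
quaternion Fourier transform with axis i reduces to two ordinary complex
2-D FFTs, Q = F1 + F2·j. We use the unitary normalization 1/√(MN) on both
directions; this is the only convention under which the forward/inverse
pair is actually mutually inverse, and it gives Parseval's identity
exactly (both properties are asserted to 1e-10 in the tests, against a
brute-force O((MN)²) quaternion DFT oracle).

Writing the spectrum in polar form Q = ‖Q‖·(Q/‖Q‖), the **spectral
contrast** between the image and a Gaussian-blurred version of itself
(σ = 3 px, the "average energy" reference) is

    CQ(u, v) = ln( (‖Q_raw‖² + ε) / (‖Q_blur‖² + ε) ) · phase_raw(u, v),

with ε = 1e-12 and a hard zero wherever the raw amplitude is at the
floor. The saliency map at one scale is the σ = 3 Gaussian blur of the
squared quaternion modulus of the inverse transform of CQ. Maps at scales
l ∈ {1, 0.5, 0.25} of the 320×240 working resolution are averaged, and the
final map divides by a logarithmic center-distance weight

    SM(x, y) = S(x, y) / (1 + ln(1 + r / r_half_diag)),

where r is the Euclidean distance to the grid center and r_half_diag half
the pixel diagonal, so the weight is 1 at the center and 1 + ln 2 at the
corners. Natural logarithms are used throughout; the D_log form above is
this package's choice (it is resolution-invariant and vanishes at the
center), as is the eigenaxis polar form — a literal fixed-axis-j polar
projection is available via `polar_decompose(..., axis="j")` but only
reconstructs spectra confined to the {1, j} subfield.

### What the contrast actually measures

Because blurring is (up to boundary handling) a convolution, the blurred
spectrum is approximately the raw spectrum times the Gaussian transfer
function, and the log amplitude ratio is then nearly content-independent —
a radially increasing weight ≈ 4π²σ²f². The content enters through the
retained quaternion *phase*: the reconstruction is in effect a
high-frequency-weighted phase-only reconstruction, which suppresses
repeated structure and highlights items that are unique in the joint
H/S/V (and motion) signal. This is why pop-out works without any per-
feature sub-maps, and why a strictly constant image yields an identically
zero map (only the DC term survives, and its contrast is ln 1 = 0).

## Temporal extension

The motion cue is a five-tap temporal filter on the video intensity
(V channel of HSV), coefficients (1, −4, −1, 4, −1)/8 for frames
t−2 … t+2, with edge replication at the sequence boundaries. As printed
the taps sum to −1, so a static scene carries a constant pseudo-motion of
−I/8; the `zero_sum` variant drops the center tap, making static content
produce exactly zero motion, in which case the spatio-temporal map is
pixel-identical to the static map of the same frame. Both variants are
exposed (`as_printed` is the default); neither dominates, and the
reduction property is only exact under `zero_sum`.

Video frames are processed at 128×128 (the motion field is computed at
that resolution so the frequency grids of the raw and blurred spectra
match), then the per-frame map is resized back to the frame size. The
motion channel keeps its natural range (within ±3/4 for V in [0, 1]); no
extra normalization is applied before encoding.

## Synthetic data

The package generates its own test stimuli; nothing is downloaded.

**Pop-out patterns** are rows×cols grids (default 5×7 at 320×240) of
identical bars (or dots, crosses, curve segments) with one deviant in
color or orientation, positions jittered ±3 px, rendered without
anti-aliasing so the recorded bounding boxes are pixel-exact. The default
background is neutral mid-gray: HSV assigns hue 0 to any achromatic
pixel, so a red target (hue 0) on a *white* background would be invisible
in the hue channel — an artifact of the encoding, not of attention. For
the same reason a red deviant among blue distractors on an achromatic
background is a known failure mode of the HSV encoding and is documented
rather than worked around. Psychophysical checks disable the center-bias
weight, since target position is randomized.

**Synthetic videos** (default 128×128, 30 frames) move a 16-px colored
square at 2 px/frame over either a fixed blurred-noise texture or a
drifting sum of two sinusoidal gratings (enough non-stationarity to defeat
naive frame differencing). Ground-truth boxes track the square exactly.
These fixtures probe the mechanism — joint appearance+motion contrast —
but are far simpler than natural surveillance footage: no camera motion,
occlusion, illumination change, or deformable objects. Passing them shows
the pipeline is implemented correctly, not that it matches human fixation
data.

## Evaluation protocols

Normalized maps (affine min-max to [0, 255]; a constant map maps to all
zeros) are swept over integer thresholds 0…255 with the strict rule
`foreground = saliency > τ`. Precision is defined as 1 when nothing is
predicted, recall as 1 when the ground truth is empty. The ROC area
integrates TPR over FPR by the trapezoid rule with the predict-everything
point (1, 1) appended, so a perfect map scores exactly 1 and any constant
map scores 0.5. Ties are handled by the sweep itself (no mid-rank
correction).

Moving-object extraction binarizes at a single global threshold (default
128), applies morphological opening then closing with a radius-2 disk,
and takes 8-connected component boxes. A ground-truth box counts as
detected when at least 30% of its pixels are foreground; precision
matches predicted boxes to detected ground-truth boxes by any overlap
(the matching rule is this package's choice).

## Numerical choices and defaults

| parameter | default | notes |
| --- | --- | --- |
| scales | 1, 0.5, 0.25 | of the working resolution |
| blur σ | 3 px | reference blur, reconstruction smoothing, display smoothing |
| base resolution | 320×240 | static pipeline working size |
| video resolution | 128×128 | spatio-temporal working size |
| log ε | 1e-12 | amplitude-ratio stabilizer; also the zero-amplitude floor |
| motion variant | as_printed | `zero_sum` for the DC-free filter |
| extraction threshold | 128 | on [0, 255] maps, after per-frame normalization |
| morphology radius | 2 px | disk structuring element |

Resizing is bilinear everywhere (no anti-aliasing filter, so the resize is
a pure interpolation); Gaussian filtering uses reflective boundaries; the
blurred reference is built per scale independently (resize first, then
blur), because the point-wise spectral ratio requires the raw and blurred
spectra on the same frequency grid. Zero-amplitude frequencies take the
identity quaternion as their phase and are excluded from the contrast.
Hue enters as a plain [0, 1] coordinate; its circular topology is not
modeled (see the fixture discussion above for the consequences).

## Problem sizes used in the checks

The automated checks run the transform exactness on 100 random 16×16
grids and all grid shapes 2×2…8×8 against the brute-force oracle; pop-out
localization on 100 arrays per stimulus class at 320×240; and the video
protocols on 30-frame 128×128 sequences, scoring the 26 interior frames.
These sizes exercise every code path at full default fidelity while
keeping a complete run in the tens of seconds on one CPU.

## Known limitations

- Hue wrap-around: deviants whose hue coordinate coincides with the
  background's (red on achromatic backgrounds) lose their color channel.
- The amplitude ratio is nearly content-free (see above): the model's
  discriminative power rests on the quaternion phase; scenes whose
  saliency is carried purely by amplitude statistics at fixed phase will
  not be distinguished.
- No camera-motion compensation or optical flow: the motion cue is a
  pixel-wise temporal derivative and responds to any temporal change,
  including global illumination shifts.
- Saliency maps are per-frame; no temporal smoothing of maps is applied.
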