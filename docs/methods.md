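# Methods

`glottkit` asks a single scientific question from two directions: is
very high-pitched ("whistle register") soprano phonation produced by an
aeroacoustic (AA) whistle, or by self-sustained vocal fold oscillation
(the myoelastic-aerodynamic, MEAD, principle)?  The package provides
(1) an impinging-jet whistle model to probe the AA hypothesis, (2) a
self-oscillating finite-difference vocal fold model to probe the MEAD
hypothesis, (3) an analysis pipeline for super-high-speed
videolaryngoscopy and paired acoustic/electroglottographic (EGG)
signals, and (4) a synthetic data generator that stands in for human
recordings, with exact ground truth.

## 1. Impinging-jet whistle model (`glottkit.jet`)

A glottal air jet striking a wall at distance `x_wall` can lock into a
feedback whistle at

    f_n = n * u / x_wall,    u = V / A_gl,

with `V` the volumetric airflow, `A_gl` the glottal constriction area
and `n` the mode number.  Stability requires a Strouhal number
`St = f d / u` inside `d/x < St < 1` (strict inequalities; boundary
values are flagged unstable).

For mode 1 the identity `St = f d / u = d / x` holds whenever the same
diameter is used on both sides of the criterion, which would make
strict mode-1 stability unsatisfiable.  We therefore evaluate the
lower bound with the circular-equivalent *orifice* diameter
`2 sqrt(A_gl / pi)` and the Strouhal number with the *effective jet*
diameter (a supplied value wins over the derived one): impinging jets
entrain air and widen toward the wall, so the jet diameter at the wall
exceeds the orifice diameter.  The feasibility scan
(`whistle_range_feasible`) supplies a jet 1.15x the orifice diameter
to probe strict interior stability.  With the purely derived diameter,
mode 1 sits exactly on the lower bound and is reported unstable — the
conservative reading.

Units are SI internally; the CLI accepts ml/s, mm² and mm.

## 2. Self-oscillating vocal fold model (`glottkit.simulator`)

### Structure

A rectangular parallelepiped of tissue (length `L = 0.945 cm`,
vertical thickness `T = 0.3 cm`, lateral depth `D = 0.45 cm`) is
discretised into 5 (antero-posterior, AP) x 3 (inferior-superior) x 6
(medio-lateral) = 90 lumped masses, each with one medio-lateral degree
of freedom: 180 first-order state equations, integrated with classical
RK4.

Each AP row of masses is a discrete string under tensile fiber stress
with fixed phantom end nodes, so the node spacing is `dy = L/(n_ap+1)`
and each lumped mass is `rho * dy * (T/3) * (D/6)` (total mass
`5/6 rho L T D`; the two phantom half-cells at the fixed ends carry no
mass).  This is the discretisation whose 5-mass fundamental (1569 Hz)
approaches the continuous string prediction
`sqrt(sigma/rho)/(2L) = 1587 Hz` from below by ~1%; lumping `L/5` of
tissue per mass onto an `L/6` spacing instead would detune the
fundamental by ~10%, an avoidable discretisation artifact.

Tissue parameters: cover fiber stress 0.9 MPa on the two medial depth
layers (mucosa, ligament), muscle fiber stress 5 kPa on layers 3–6,
gel shear modulus 1 kPa coupling vertical and lateral neighbours (the
lateral chain ends at a fixed wall, letting vibration dissipate into
the body of the fold), tissue density 1000 kg/m³ (chosen so the string
formula at 0.9 MPa and 0.945 cm gives exactly 1587 Hz; the model makes
this choice explicit rather than implicit).

### Damping

The damping ratio is `zeta = 0.04`.  We reference it to the vibration
mode of each mass's own fiber: `c = 2 zeta m omega_0`, with `omega_0`
the string fundamental at that layer's stress.  Referencing `zeta` to
the much stiffer *local* inter-node stiffness (~7.4x the modal
stiffness `m omega_0^2` for the cover) would silently raise the
effective modal damping ratio to ~0.11 — and a damping ratio of ~0.1
is precisely what suppresses self-oscillation at these frequencies.
This choice is load-bearing and was verified by linear stability
analysis (below).

### Adduction and pre-phonatory shape

One parameter controls adduction: the posterior glottal width between
the vocal processes (0.1 mm for tight, 0.6 mm for weak adduction),
tapering linearly to zero at the anterior commissure.  There is no
vertical taper: the pre-phonatory glottis is rectangular, neither
convergent nor divergent.

### Aerodynamics

Quasi-steady Bernoulli flow with separation at the minimal section,
per AP segment: the flow-controlling area is the minimal vertical
cross-section of each segment, summed over segments
(`a_min = sum_i min_j a_ij`), and
`U = a_min sqrt(2 (P_L - P_supra) / rho_air)`.  Within a segment,
cells upstream of the minimal level carry the graded Bernoulli
pressure `P_supra + (P_L - P_supra)(1 - (a_min/a)^2)`, cells at or
downstream of it carry the supraglottal pressure, and closed segments
carry the full subglottal pressure below the closure.  The graded
upstream pressure matters: a binary P_L/0 rule has zero gradient with
respect to the neighbouring levels' positions almost everywhere, and
the model then falls into stable static (pushed-open) equilibria.

### Why the vocal tract is part of the default configuration

With the bare Bernoulli source the model is *linearly stable* at the
default tissue parameters.  We verified this by computing the static
equilibrium and the eigenvalues of the numerically differentiated
180-state Jacobian: all oscillatory modes decay.  The physical reason:
at 1.6 kHz a mucosal (gel shear) wave with speed `sqrt(G/rho) = 1 m/s`
has a 0.64 mm wavelength, below the 1 mm vertical node spacing, and
the fiber tension grounds each vertical level at the same resonance —
the vertical transfer that powers the convergent/divergent "push-pull"
is only ~13% in amplitude per layer, leaving the pump at about 2/3 of
the damping threshold.

The missing energy comes from the supraglottal load.  The default
configuration therefore couples the glottis to a one-dimensional
wave-reflection (Kelly-Lochbaum) vocal tract: 44 uniform sections over
17.5 cm with a stylised [a:] area function (0.5 cm² pharynx opening to
~7 cm² mouth), lip reflection coefficient −0.9, and a per-section
propagation attenuation of 0.997 standing in for viscous and wall
losses.  At soprano fundamentals (above the second formant of this
area function) the tract input reactance is inertive, supplying the
velocity-phase pressure that carries the oscillation over threshold —
consistent with the general result that quasi-steady flow without a
mucosal wave needs an inertive load to destabilise tissue.  The
attenuation value matters at both ends: a lossless line overdrives its
resonances until the supraglottal pressure transiently exceeds lung
pressure and chokes the transglottal flow (unphysical flow
interruptions), while attenuation at or below ~0.995 absorbs the pump
and the weak-adduction limit cycle dies.  `tract="none"` remains
available and documents the subthreshold behaviour.

### Contact

Collision with the contralateral fold (the model simulates one fold
and mirrors it; glottal width = 2 x (pre-phonatory half-width +
displacement), floored at zero) is a linear penalty of 3x the modal
grounding stiffness `m omega_0^2` — the classic convention of tripling
the spring rate during contact — plus, in the default `clamp` mode,
zeroing of any remaining inward velocity after the step.  The emergent
f_o is insensitive to the penalty constant (1715 vs 1723 Hz between
3x modal and 3x inter-node stiffness in a sensitivity run).

### Integration and outputs

`dt = 2 µs` (>= 300 integration points per cycle at 1.6 kHz; RK4
stability margin ~10x even during contact), duration 0.5 s with the
first 0.1 s discarded as onset transient.  Runs start from the
pre-phonatory rest position with a ~1 µm/s random velocity
perturbation; the limit cycle is independent of this seed.  f_o is
estimated by normalized autocorrelation (with parabolic sub-sample
peak interpolation) of the post-transient glottal area; harmonic
levels come from a Hann-windowed spectrum of the glottal flow
normalized to its strongest harmonic.

At these defaults the model self-oscillates at ~1586 Hz (tight) and
~1542 Hz (weak); tight closes fully (zero minimum flow), weak keeps a
posterior leak and a larger area oscillation with a relatively weaker
second harmonic — the full qualitative contrast between the two
adduction regimes emerges from a single changed parameter.

## 3. High-speed video pipeline (`glottkit.preprocess`, `glottkit.kinematics`)

**Honeycomb removal.**  Fiber-optic image guides imprint a periodic
lattice whose spectrum shows a dominant conjugate-symmetric peak pair.
Per frame: 2-D FFT, binarize the log magnitude at `mean + 4 sd`
outside a protected 8 px low-frequency disc, enforce conjugate
symmetry, keep the two strongest peak regions, dilate by 2 px
("slightly increase"), zero, inverse transform, clip to the input
range.  Frames without two off-center peaks pass through unchanged
with a logged notice.

**Rotation alignment.**  The glottis is the fastest-moving object:
absolute difference images at a 5-frame offset are binarized (Otsu),
opened, and the largest connected component's ellipse major-axis
orientation gives the glottal angle (degrees, CCW from vertical).
The keyframe track is median-filtered (window 5) and linearly
interpolated; frames are rotated back with bilinear interpolation.
Angles recover to within ±2° on synthetic truth.

**Cropping.**  Keyframed bounding boxes, centers and sizes linearly
interpolated, output padded to the largest box.

**Segmentation.**  A per-pixel threshold halfway between the stack
minimum (the gap intensity) and each pixel's background — its 95th
temporal percentile, since the folds cover every normally vibrating
pixel for part of the cycle, floored at the stack Otsu level for
pixels inside a permanent posterior gap.  Anchoring at the stack
minimum keeps the threshold between gap and tissue even when
open-glottis pixels are a small minority (a plain Otsu then splits
tissue-shading modes instead), and the halfway point makes the edge
criterion "gap covers more than half the pixel" independent of local
shading.  All connected components >= 1 px are retained —
local vocal fold contact genuinely splits the glottal opening into
several parts along the AP axis, and near closure a real opening can
shrink to a single pixel.  Empty masks are legitimate full-closure
frames.  The threshold scales with the data, making all downstream
quantities invariant to uniform intensity rescaling.

**GVG, CQ, configuration.**  The glottovibrogram is the per-row pixel
width over time, restricted to the declared visible-fold row span
(`ap_axis`, from the user ROI) — necessary because permanently closed
rows (configuration IIa) never appear in any mask yet belong to the
fold length.  The glottal area waveform equals the GVG column sums by
construction.  Closed quotients use a closure threshold of 0.5 px
(sub-pixel widths count as closed) over an integer number of cycles
anchored at a glottal-area minimum, with guards for < 3 cycles and
< 6 frames per cycle.  Cohort summaries pool all row-wise CQ values
of all subjects before taking the median and 5th/95th percentiles
(linear interpolation).  Configuration rules: closed-phase contact
fraction < 0.95 -> I; otherwise open-phase opening fraction <= 0.70 ->
IIa, else IIb; the cut-offs separate the reported in-vivo ranges
(contact along 44–75% of the visible length for I, partial opening
along 40–50% for IIa) with margin on both sides.

## 4. Voice signals (`glottkit.signals`)

f_o: normalized autocorrelation over a 100 ms window at the signal
midpoint, search band 800–2200 Hz, highest peak refined by parabolic
interpolation (at ~12.8 samples per period for G6 at 20 kHz, sub-sample
resolution is mandatory); correlation below 0.3 raises an unvoiced
error.  H1-H2: Hann-windowed spectrum, each harmonic the refined peak
within ±3% of `k f_o`; analysis is restricted below a 4 kHz aliasing
guard because uncontrolled clinical recordings commonly alias above
that band, and all levels are relative dB (no SPL calibration).
Pitch conversion is 12-tone equal temperament, A4 = 440 Hz.  The
EGG-vs-area phase is the difference of the two signals' complex
Fourier components at f_o, in cycles; vocal fold contact peaking at
the area minimum (the MEAD signature) reads ±0.5.

## 5. Synthetic data (`glottkit.synth`)

The generator emulates the acquisition conditions of super-high-speed
laryngoscopy: 20,000 fps at 386 x 320 px, 20 kHz audio/EGG, pitches
C6–G6.  Glottal width per row:
`w(u, t) = max(0, g(u) + a(u) sin(2 pi f_o t))`, with the offset
`g = 0.5 - a sin(pi (CQ - 1/2))` solving exactly for a target closed
quotient at the 0.5 px closure threshold used downstream.  The gap is
centered on a pixel center so the rendered closure threshold coincides
with the analytic one.  Configuration I adds a posterior gap that
never closes; IIa freezes the fold portions outside a central opening
span in permanent contact; IIb oscillates everywhere.  The honeycomb
overlay is three plane waves 60° apart (hexagonal-lattice
approximation) with one dominant pair, the background is a smooth
shaded texture symmetric about the glottal midline (the folds are
mirror images), and rotation and Gaussian noise are applied last;
truth (masks, GVG, per-row CQ, configuration, angle, f_o, H1-H2, EGG
phase) is computed from the generating waveforms, never re-measured
from pixels.  Audio is a 2–7 harmonic series (capped by Nyquist at the
pitch) with a prescribed `H1-H2 = 20 log10(A1/A2)`; the EGG is a
raised-cosine contact pulse with duty equal to the mean CQ, peaking at
the area minimum.  The 9-subject cohort allocates configurations
4 x I, 3 x IIa, 2 x IIb, draws row CQs uniformly from the empirical
span [0.30, 0.73], draws configuration fractions with >= 0.1 margin
from the classifier cut-offs (labels unambiguous by construction), and
H1-H2 targets from 17.2 ± 4.5 dB clipped to [6, 30] dB.

**What the generator does not emulate:** photorealistic tissue
texture, specular reflections, mucus bridges, endoscope motion beyond
a constant in-plane rotation, left-right asymmetric vibration,
vertical (convergent/divergent) dynamics in the image, or EGG
electrode artifacts.  Passing recovery tests on this data shows the
pipeline is correct *given its model of the scene*; it does not
certify performance on clinical footage.

## Problem sizes and numerical choices

Default analysis problem sizes: cohort recovery runs 9 subjects at
0.05 s (1000 frames, ~70–78 cycles) on 192 x 160 px frames; the
simulator runs 0.5 s at 2 µs steps (250,000 RK4 steps, 180 states).
Degenerate inputs are guarded explicitly: empty grids, inverted
bounds, non-positive physical quantities, static image sequences,
fewer than 3 cycles, closure thresholds on empty masks.  Percentiles
use linear interpolation; ties in the separation-level argmin resolve
to the most inferior level, which at exact vertical symmetry yields
zero driving pressure (the symmetric state is force-free by
symmetry).

## Known limitations

- The simulator's oscillation depends on the supraglottal load;
  threshold behaviour near the printed damping ratio means moderate
  parameter changes (e.g. halving lung pressure) can fail to phonate.
- One degree of freedom per mass: no vertical or longitudinal tissue
  motion, no mucosal-wave phase metrics.
- The fold geometry pipeline assumes an approximately vertical,
  midline-centered glottis after alignment; severe off-axis endoscopy
  is out of scope.
- The AA whistle model is kinematic: it predicts candidate frequencies
  and stability bands, not amplitudes or radiated sound.
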