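"""Synthetic laryngoscopy, audio and EGG generator with ground truth.

Every input the analysis pipeline consumes can be generated here with
exact, analytically computed ground truth attached: oscillating-glottis
image sequences (stereotypical glottal configurations I / IIa / IIb,
fiber-optic honeycomb overlay, in-plane rotation, sensor noise),
harmonic audio with a prescribed H1-H2, and an EGG contact signal in
antiphase with the glottal area.

The glottal width at normalized antero-posterior position ``u`` and
time ``t`` is

    w(u, t) = max(0, g(u) + a(u) * sin(2 pi f_o t))      [px]

with ``a`` an amplitude envelope and ``g`` an offset chosen per row so
that the closed fraction of the cycle (width <= 0.5 px, the closure
threshold used downstream) equals the target CQ:
``g = 0.5 - a * sin(pi (CQ - 1/2))``.  Configuration I keeps a
posterior gap open through the whole cycle; IIa freezes an anterior and
posterior portion of the folds in contact (``a = 0``, always closed);
IIb oscillates along the full visible length.  Ground truth (masks,
glottovibrogram, per-row CQ, configuration, rotation angle, f_o, H1-H2,
EGG phase) is computed from these generating waveforms, never
re-measured from the rendered images.

Fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinematics import Glottovibrogram
from .preprocess import HSVSequence
from .signals import VoiceSignal

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "CohortMember",
    "gen_hsv",
    "gen_audio_egg",
    "gen_cohort",
]

#: empirical per-row closed-quotient span used for cohort draws
CQ_RANGE = (0.30, 0.73)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    The defaults emulate the acquisition conditions of super-high-speed
    laryngoscopy of operatic soprano singing: 20,000 fps video at
    386 x 320 px and 20 kHz audio/EGG, at the pitch G6 (~1568 Hz).
    """

    f_o: float = 1568.0  # [Hz]
    fps: float = 20000.0
    duration: float = 0.05  # [s]
    image_dims: tuple[int, int] = (386, 320)  # (height, width)
    configuration: str = "I"  # "I", "IIa" or "IIb"
    posterior_gap_px: float = 5.0  # extra persistent gap width, config I
    contact_fraction_target: float = 0.60  # config I: closed-phase contact
    opening_fraction_target: float = 0.45  # config IIa: open-phase opening
    cq_target: tuple[float, ...] | float | None = None  # per open row
    amplitude_px: float = 14.0  # peak width oscillation amplitude
    rotation_angle: float = 0.0  # [deg] CCW from vertical
    honeycomb_freq: float = 0.25  # [cycles/px]
    honeycomb_amplitude: float = 0.0
    noise_sigma: float = 0.0
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.1)
    audio_fs: float = 20000.0
    audio_noise: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.configuration not in ("I", "IIa", "IIb"):
            raise ValueError("configuration must be 'I', 'IIa' or 'IIb'")
        if self.fps < 6.0 * self.f_o:
            raise ValueError(
                f"fps must be >= 6*f_o for meaningful cycle sampling "
                f"(got fps={self.fps}, f_o={self.f_o})"
            )
        for name in ("contact_fraction_target", "opening_fraction_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_harm = len(self.harmonic_amplitudes)
        if not 2 <= n_harm <= 7:
            raise ValueError(
                f"need between 2 and 7 harmonics, got {n_harm}"
            )
        if n_harm * self.f_o >= self.audio_fs / 2.0:
            raise ValueError("highest harmonic above Nyquist")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def h1_h2_true(self) -> float:
        a1, a2 = self.harmonic_amplitudes[0], self.harmonic_amplitudes[1]
        return 20.0 * math.log10(a1 / a2)


@dataclass
class SyntheticTruth:
    """Analytic ground truth attached to a generated dataset."""

    masks: np.ndarray  # (n_frames, H, W) bool, unrotated/clean geometry
    gvg: Glottovibrogram  # analytic width map, posterior row first
    cq: np.ndarray  # per glottis row, closure threshold 0.5 px
    configuration: str
    rotation_angle: float  # [deg]
    f_o: float
    h1_h2: float  # [dB]
    egg_phase: float  # EGG vs glottal area, cycles (antiphase = 0.5)
    glottis_rows: tuple[int, int]  # (first, last+1) image rows of glottis


def _width_profiles(spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row offset g(u) and amplitude a(u) of the width waveform."""
    height, _ = spec.image_dims
    r0, r1 = int(0.20 * height), int(0.80 * height)
    n_rows = r1 - r0
    u = np.linspace(0.0, 1.0, n_rows)  # 0 = posterior

    def cq_of_rows(n: int) -> np.ndarray:
        if spec.cq_target is None:
            return rng.uniform(*CQ_RANGE, size=n)
        if np.isscalar(spec.cq_target):
            return np.full(n, float(spec.cq_target))
        arr = np.asarray(spec.cq_target, dtype=float)
        if arr.size != n:
            # resample a supplied profile onto the row grid
            arr = np.interp(np.linspace(0, 1, n),
                            np.linspace(0, 1, arr.size), arr)
        return arr

    # amplitude envelope: broad arch with a floor so every oscillating
    # row has enough swing for sub-frame CQ resolution
    def arch(v: np.ndarray) -> np.ndarray:
        return spec.amplitude_px * (0.35 + 0.65 * np.sin(np.pi * v))

    a = np.zeros(n_rows)
    g = np.zeros(n_rows)
    if spec.configuration == "I":
        gap_frac = 1.0 - spec.contact_fraction_target
        gap = u < gap_frac
        osc = ~gap
        v = (u[osc] - gap_frac) / max(1e-9, 1.0 - gap_frac)
        a[osc] = arch(v)
        g[osc] = 0.5 - a[osc] * np.sin(np.pi * (cq_of_rows(osc.sum()) - 0.5))
        # posterior rows: oscillate but never reach closure
        v_gap = 1.0 - u[gap] / max(1e-9, gap_frac)  # 1 at posterior end
        a[gap] = 0.5 * arch(np.full(gap.sum(), 0.5))
        g[gap] = 0.5 + a[gap] + spec.posterior_gap_px * (0.2 + 0.8 * v_gap)
    elif spec.configuration == "IIa":
        span = spec.opening_fraction_target
        lo, hi = 0.5 - span / 2.0, 0.5 + span / 2.0
        osc = (u >= lo) & (u < hi)
        v = (u[osc] - lo) / max(1e-9, span)
        a[osc] = arch(v)
        g[osc] = 0.5 - a[osc] * np.sin(np.pi * (cq_of_rows(osc.sum()) - 0.5))
        g[~osc] = -1.0  # permanent contact
    else:  # IIb
        a[:] = arch(u)
        g[:] = 0.5 - a * np.sin(np.pi * (cq_of_rows(n_rows) - 0.5))
    return g, a


def _analytic_cq(g: np.ndarray, a: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Closed fraction of the cycle for w = max(0, g + a sin)."""
    cq = np.empty_like(g)
    still = a <= 0
    cq[still] = np.where(g[still] <= threshold, 1.0, 0.0)
    osc = ~still
    r = np.clip((threshold - g[osc]) / a[osc], -1.0, 1.0)
    cq[osc] = 0.5 + np.arcsin(r) / np.pi
    return cq


def _render_coverage(width_px: np.ndarray, n_cols: int,
                     center: int) -> np.ndarray:
    """Per-pixel gap coverage for widths centered on a pixel center.

    ``width_px`` has shape (..., ) and broadcasting adds a trailing
    column axis; coverage of column ``c`` is the overlap of the gap
    interval [center - w/2, center + w/2] with [c - 0.5, c + 0.5).
    """
    cols = np.arange(n_cols, dtype=float)
    lo = center - width_px[..., None] / 2.0
    hi = center + width_px[..., None] / 2.0
    return np.clip(np.minimum(hi, cols + 0.5) - np.maximum(lo, cols - 0.5),
                   0.0, 1.0)


def gen_hsv(spec: SyntheticSpec) -> tuple[HSVSequence, SyntheticTruth]:
    """Render a synthetic laryngoscopy sequence and its ground truth.

    The glottal gap is painted as a dark slit on a textured background
    (smooth gradient plus fold-edge shading, so segmentation is not a
    trivial constant threshold); the honeycomb overlay, the in-plane
    rotation and the Gaussian sensor noise are applied in that order.
    Truth is recorded for the clean, unrotated geometry.
    """
    rng = np.random.default_rng(spec.seed)
    height, width_im = spec.image_dims
    n_frames = spec.n_frames
    g, a = _width_profiles(spec, rng)
    r0 = int(0.20 * height)
    n_rows = g.size
    center = width_im // 2

    t = np.arange(n_frames) / spec.fps
    osc = np.sin(2.0 * np.pi * spec.f_o * t)  # (n_frames,)
    w = np.maximum(0.0, g[None, :] + a[None, :] * osc[:, None])  # (T, rows)

    # analytic truth
    gvg = Glottovibrogram(w.T.copy(), spec.fps,
                          np.linspace(0, 1, n_rows) if n_rows > 1 else np.zeros(1))
    cq = _analytic_cq(g, a)

    cov = _render_coverage(w, width_im, center)  # (T, rows, W)
    masks = np.zeros((n_frames, height, width_im), dtype=bool)
    masks[:, r0 : r0 + n_rows, :] = cov >= 0.5

    # background: bright tissue, darker shading toward the fold edges
    rr, cc = np.mgrid[0:height, 0:width_im]
    background = (
        0.72
        - 0.18 * np.exp(-((cc - center) ** 2) / (2.0 * (0.18 * width_im) ** 2))
        + 0.06 * rr / height
        + 0.04 * np.cos(2.0 * np.pi * (cc - center) / width_im)
    )  # symmetric about the glottal midline: the folds are mirror images
    frames = np.broadcast_to(background, (n_frames, height, width_im)).copy()
    gap_value = 0.08
    region = frames[:, r0 : r0 + n_rows, :]
    frames[:, r0 : r0 + n_rows, :] = region * (1.0 - cov) + gap_value * cov

    if spec.honeycomb_amplitude > 0:
        # hexagonal-lattice approximation: three plane waves 60 deg apart,
        # one pair dominant so its two spectral peaks stand out
        weights = (1.0, 0.3, 0.3)
        overlay = np.zeros((height, width_im))
        for theta_deg, wt in zip((0.0, 60.0, 120.0), weights):
            th = math.radians(theta_deg)
            phase = 2.0 * np.pi * spec.honeycomb_freq * (
                cc * math.cos(th) + rr * math.sin(th))
            overlay += wt * np.cos(phase)
        frames += spec.honeycomb_amplitude * overlay

    if spec.rotation_angle != 0.0:
        for i in range(n_frames):
            # ndimage rotates CCW in (row, col) axes, which is clockwise
            # in display coordinates; negate so positive rotation_angle
            # means CCW from vertical as estimated downstream
            frames[i] = ndimage.rotate(
                frames[i], -spec.rotation_angle, reshape=False, order=1,
                mode="nearest",
            )

    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)

    seq = HSVSequence(frames, spec.fps, {
        "synthetic": True,
        "configuration": spec.configuration,
        "f_o": spec.f_o,
    })
    truth = SyntheticTruth(
        masks=masks,
        gvg=gvg,
        cq=cq,
        configuration=spec.configuration,
        rotation_angle=spec.rotation_angle,
        f_o=spec.f_o,
        h1_h2=spec.h1_h2_true,
        egg_phase=0.5,
        glottis_rows=(r0, r0 + n_rows),
    )
    return seq, truth


def gen_audio_egg(
    spec: SyntheticSpec,
) -> tuple[VoiceSignal, VoiceSignal, SyntheticTruth]:
    """Generate paired audio and EGG signals plus ground truth.

    The audio is a harmonic series ``sum_k A_k sin(2 pi k f_o t)`` with
    a small Gaussian noise floor; its true H1-H2 is
    ``20 log10(A_1/A_2)``.  The EGG is a raised-cosine vocal fold
    contact pulse whose maximum coincides with the glottal-area minimum
    of the paired video geometry (antiphase, offset 0.5 cycles) and
    whose duty cycle equals the mean target CQ.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = int(round(spec.duration * spec.audio_fs))
    t = np.arange(n) / spec.audio_fs
    audio = np.zeros(n)
    for k, amp in enumerate(spec.harmonic_amplitudes, start=1):
        audio += amp * np.sin(2.0 * np.pi * k * spec.f_o * t)
    audio += spec.audio_noise * rng.standard_normal(n)

    g, a = _width_profiles(spec, np.random.default_rng(spec.seed))
    duty = float(np.clip(_analytic_cq(g, a).mean(), 0.15, 0.85))
    # area ~ sin(2 pi f t): minimum at phase 0.75, where contact peaks
    phase = (spec.f_o * t) % 1.0
    d = phase - 0.75
    d -= np.round(d)  # wrap to [-0.5, 0.5)
    egg = np.where(np.abs(d) < duty / 2.0,
                   0.5 * (1.0 + np.cos(2.0 * np.pi * d / duty)), 0.0)
    egg = egg + 0.01 * spec.audio_noise * rng.standard_normal(n)

    audio_sig = VoiceSignal(audio, spec.audio_fs, kind="audio")
    egg_sig = VoiceSignal(egg, spec.audio_fs, kind="egg")
    truth = SyntheticTruth(
        masks=np.zeros((0, 0, 0), dtype=bool),
        gvg=Glottovibrogram(np.zeros((1, 1)), spec.fps, np.zeros(1)),
        cq=_analytic_cq(g, a),
        configuration=spec.configuration,
        rotation_angle=spec.rotation_angle,
        f_o=spec.f_o,
        h1_h2=spec.h1_h2_true,
        egg_phase=0.5,
        glottis_rows=(0, 0),
    )
    return audio_sig, egg_sig, truth


#: configuration allocation pattern of a 9-subject cohort (4 x I,
#: 3 x IIa, 2 x IIb), cycled for other cohort sizes
_COHORT_PATTERN = ("I", "I", "I", "I", "IIa", "IIa", "IIa", "IIb", "IIb")
#: task pitches: top of the sung scale, G6 for most subjects, F6 for the
#: two who do not reach G6 in a 9-subject cohort
_PITCH_HZ = {"C6": 1046.50, "D6": 1174.66, "E6": 1318.51, "F6": 1396.91,
             "G6": 1567.98}


@dataclass(frozen=True)
class CohortMember:
    """One synthetic subject: identifier, pitch and generator spec.

    Image and signal data are produced on demand by :meth:`generate`
    (a full-cohort render held in memory at once would be needlessly
    large).
    """

    subject_id: str
    pitch: str
    spec: SyntheticSpec

    def generate(self) -> tuple[
        HSVSequence, SyntheticTruth, VoiceSignal, VoiceSignal
    ]:
        seq, truth = gen_hsv(self.spec)
        audio, egg, _ = gen_audio_egg(self.spec)
        return seq, truth, audio, egg


def gen_cohort(
    n_subjects: int = 9,
    seed: int = 0,
    duration: float = 0.05,
    fps: float = 20000.0,
    image_dims: tuple[int, int] = (386, 320),
) -> list[CohortMember]:
    """Draw a synthetic cohort spanning configurations I / IIa / IIb.

    With ``n_subjects = 9`` the configuration counts are (4, 3, 2) for
    (I, IIa, IIb); other sizes cycle the same pattern.  Per subject,
    row-wise CQ targets are drawn uniformly from the empirical span
    [0.30, 0.73], configuration-specific fractions are drawn with a
    margin of at least 0.1 from the classifier cut-offs (so labels are
    unambiguous by construction), and H1-H2 targets are drawn from the
    reported top-pitch distribution (17.2 +/- 4.5 dB, clipped to
    [6, 30] dB).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    members = []
    for i in range(n_subjects):
        rng = np.random.default_rng(children[i])
        config = _COHORT_PATTERN[i % len(_COHORT_PATTERN)]
        pitch = "F6" if n_subjects >= 9 and i % len(_COHORT_PATTERN) in (5, 8) \
            else "G6"
        f_o = _PITCH_HZ[pitch]
        h1h2 = float(np.clip(rng.normal(17.20, 4.48), 6.0, 30.0))
        # 2-7 noteworthy harmonics, capped by Nyquist at this pitch
        n_fit = int((fps / 2.0 - 1.0) / f_o)
        n_harm = int(min(rng.integers(2, 8), max(2, n_fit)))
        amps = [1.0, 10.0 ** (-h1h2 / 20.0)]
        for k in range(2, n_harm):
            amps.append(amps[-1] * 10.0 ** (-8.0 / 20.0))
        height = image_dims[0]
        n_rows = int(0.80 * height) - int(0.20 * height)
        config_kw: dict = {}
        if config == "I":
            contact = float(rng.uniform(0.45, 0.75))
            config_kw["contact_fraction_target"] = contact
            n_osc = int(np.ceil(contact * n_rows))
        elif config == "IIa":
            span = float(rng.uniform(0.40, 0.50))
            config_kw["opening_fraction_target"] = span
            u = np.linspace(0, 1, n_rows)
            lo, hi = 0.5 - span / 2, 0.5 + span / 2
            n_osc = int(((u >= lo) & (u < hi)).sum())
        else:
            n_osc = n_rows
        cq_rows = tuple(rng.uniform(*CQ_RANGE, size=n_osc))
        spec = SyntheticSpec(
            f_o=f_o,
            fps=fps,
            duration=duration,
            image_dims=image_dims,
            configuration=config,
            cq_target=cq_rows,
            harmonic_amplitudes=tuple(amps),
            seed=int(rng.integers(0, 2**31 - 1)),
            **config_kw,
        )
        members.append(CohortMember(subject_id=f"S{i + 1}", pitch=pitch,
                                    spec=spec))
    return members
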