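"""Self-oscillating finite-difference vocal fold model.

A rectangular parallelepiped of vocal fold tissue is discretised into a
grid of lumped masses (default 5 antero-posterior x 3 inferior-superior
x 6 medio-lateral = 90 masses), each with a single medio-lateral degree
of freedom, giving 180 first-order state equations integrated with a
classical 4th-order Runge-Kutta scheme.

Restoring forces are string-like: each antero-posterior fiber row is a
discrete string under tensile stress with fixed (phantom) end nodes, so
the cover layers (mucosa + ligament, fiber stress 0.9 MPa) behave like
strings tuned near ``sqrt(sigma/rho)/(2L)`` ~ 1.6 kHz, while the deeper
muscle layers (5 kPa) are slack.  Adjacent fibers are coupled by a soft
gel shear modulus, vertically (enabling the ribbon-like flexing of the
medial surface that phase-shifts the three vertical mass rows) and
laterally (a 6-deep chain terminating at a fixed wall, letting vibration
dissipate into the body of the fold).

The aerodynamic drive is quasi-steady Bernoulli flow with separation at
the minimal vertical cross-section: medial-surface masses upstream of
the minimal (or blocked) level carry the Bernoulli-graded intraglottal
pressure, those at or downstream of it carry only the supraglottal
load.  Alternating convergent/divergent
glottal shapes therefore push during opening and release during closing,
which is the energy-transfer mechanism of myoelastic-aerodynamic (MEAD)
self-sustained oscillation.  Adduction is controlled by one number: the
pre-phonatory posterior glottal width, tapering linearly to zero at the
anterior commissure, with no vertical (convergent/divergent) taper.

By default the glottal source is coupled to a one-dimensional
wave-reflection vocal tract (a 44-section stylised [a:] area function,
17.5 cm long) whose inertive input reactance at soprano fundamentals
supplies the velocity-phase supraglottal pressure that carries the
oscillation over threshold; with ``tract="none"`` the bare Bernoulli
source is used, for which the model is linearly stable at the default
tissue parameters (a property worth knowing: the tract load, not just
the tissue, decides whether phonation starts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signals import UnvoicedError, VoiceSignal, estimate_f0_autocorr

__all__ = [
    "VFModelParams",
    "SimState",
    "SimOutput",
    "GridTables",
    "build_grid",
    "string_natural_frequency",
    "derivatives",
    "step_rk4",
    "glottal_flow",
    "simulate",
    "flow_spectrum",
    "POSTERIOR_WIDTH_TIGHT",
    "POSTERIOR_WIDTH_WEAK",
]

POSTERIOR_WIDTH_TIGHT = 1e-4  # [m] 0.1 mm between the vocal processes
POSTERIOR_WIDTH_WEAK = 6e-4  # [m] 0.6 mm


@dataclass(frozen=True)
class VFModelParams:
    """Geometry, tissue properties and integration settings.

    Defaults reproduce a high-pitched soprano configuration: a
    0.945 cm x 0.3 cm x 0.45 cm fold, cover fiber stress 0.9 MPa,
    muscle fiber stress 5 kPa, gel shear modulus 1 kPa, damping ratio
    0.04 and lung pressure 4 kPa.
    """

    length_L: float = 0.00945  # antero-posterior [m]
    thickness_T: float = 0.003  # inferior-superior [m]
    depth_D: float = 0.0045  # medio-lateral [m]
    grid: tuple[int, int, int] = (5, 3, 6)  # (n_ap, n_thick, n_depth)
    fiber_stress_cover: float = 0.9e6  # [Pa], depth layers 1-2
    fiber_stress_muscle: float = 5e3  # [Pa], depth layers 3-6
    n_cover_layers: int = 2
    shear_modulus: float = 1.0e3  # [Pa]
    damping_ratio: float = 0.04
    lung_pressure: float = 4e3  # [Pa]
    posterior_width: float = POSTERIOR_WIDTH_TIGHT  # [m]
    tissue_density: float = 1000.0  # [kg/m^3]
    air_density: float = 1.14  # [kg/m^3]
    dt: float = 2e-6  # [s]
    duration: float = 0.5  # [s]
    transient_discard: float = 0.1  # [s]
    collision_mode: str = "clamp"  # "clamp" or "penalty"
    tract: str = "aa"  # "aa" (wave-reflection [a:] tract) or "none"

    def __post_init__(self) -> None:
        n_ap, n_thick, n_depth = self.grid
        if min(n_ap, n_thick, n_depth) < 1:
            raise ValueError("grid dimensions must be >= 1")
        for name in ("length_L", "thickness_T", "depth_D", "tissue_density",
                     "air_density", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("fiber_stress_cover", "fiber_stress_muscle",
                     "shear_modulus", "lung_pressure", "posterior_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.damping_ratio < 1:
            raise ValueError("damping_ratio must lie in [0, 1)")
        if self.collision_mode not in ("clamp", "penalty"):
            raise ValueError("collision_mode must be 'clamp' or 'penalty'")
        if self.tract not in ("none", "aa"):
            raise ValueError("tract must be 'none' or 'aa'")

    @property
    def n_masses(self) -> int:
        n_ap, n_thick, n_depth = self.grid
        return n_ap * n_thick * n_depth

    @property
    def n_state(self) -> int:
        return 2 * self.n_masses


@dataclass
class SimState:
    """Medio-lateral displacement/velocity of every mass at one instant.

    Displacements are measured from the pre-phonatory rest position;
    positive is lateral (opening).
    """

    displacement: np.ndarray  # [m], shape (n_masses,)
    velocity: np.ndarray  # [m/s], shape (n_masses,)
    time: float = 0.0

    def copy(self) -> "SimState":
        return SimState(self.displacement.copy(), self.velocity.copy(), self.time)


@dataclass
class SimOutput:
    """Time series and summary metrics of one simulation run."""

    time: np.ndarray  # [s]
    glottal_area: np.ndarray  # [m^2], projected area, >= 0
    glottal_flow: np.ndarray  # [m^3/s], >= 0
    sustained: bool
    f_o: float | None  # [Hz], None if oscillation died out
    spectrum_freqs: np.ndarray | None  # [Hz]
    spectrum_db: np.ndarray | None  # dB re strongest harmonic
    h1_level: float | None  # dB re strongest harmonic
    h2_level: float | None
    amplitude: float  # steady-state peak-to-peak area oscillation [m^2]


@dataclass
class GridTables:
    """Precomputed per-mass constants of the discretised fold."""

    mass: float  # lumped mass, identical for all cells [kg]
    stiffness: np.ndarray  # (n, n) linear stiffness matrix [N/m]
    damping: np.ndarray  # (n,) viscous coefficients [N s/m]
    prephonatory_half_width: np.ndarray  # (n_ap,) [m]
    collision_stiffness: float  # penalty constant on medial masses [N/m]
    dy: float  # antero-posterior node spacing [m]
    dz: float  # vertical cell height [m]
    medial_index: np.ndarray  # flat indices of the k=0 medial surface


def string_natural_frequency(fiber_stress: float, density: float,
                             length: float) -> float:
    """Fundamental of an ideal string: ``sqrt(sigma/rho) / (2 L)`` [Hz].

    With ligament stress 0.9 MPa, tissue density 1000 kg/m^3 and length
    0.945 cm this predicts 1587 Hz, the ballpark of the high-pitched
    soprano range.
    """
    if fiber_stress <= 0 or density <= 0 or length <= 0:
        raise ValueError("fiber_stress, density and length must be positive")
    return math.sqrt(fiber_stress / density) / (2.0 * length)


def _layer_stress(params: VFModelParams, k: int) -> float:
    return (params.fiber_stress_cover if k < params.n_cover_layers
            else params.fiber_stress_muscle)


def build_grid(params: VFModelParams) -> tuple[SimState, GridTables]:
    """Assemble the initial state and the per-mass constant tables.

    The ``n_ap`` masses per fiber are interior nodes of a fixed-end
    discrete string, so the node spacing is ``L / (n_ap + 1)`` and each
    lumped mass is the tissue density times its ``dy * dz * dx`` cell.
    The pre-phonatory glottal half-width tapers linearly from
    ``posterior_width / 2`` at the posterior fixed node to zero at the
    anterior commissure, with no vertical variation (rectangular glottis).
    """
    n_ap, n_thick, n_depth = params.grid
    dy = params.length_L / (n_ap + 1)
    dz = params.thickness_T / n_thick
    dx = params.depth_D / n_depth
    n = params.n_masses
    m = params.tissue_density * dy * dz * dx

    def flat(i: int, j: int, k: int) -> int:
        return (i * n_thick + j) * n_depth + k

    K = np.zeros((n, n))
    # string (antero-posterior) tension per fiber, fixed phantom ends
    for j in range(n_thick):
        for k in range(n_depth):
            sigma = _layer_stress(params, k)
            k_str = sigma * dz * dx / dy
            for i in range(n_ap):
                a = flat(i, j, k)
                K[a, a] += 2.0 * k_str
                if i > 0:
                    K[a, flat(i - 1, j, k)] -= k_str
                if i < n_ap - 1:
                    K[a, flat(i + 1, j, k)] -= k_str
    # gel shear: vertical neighbours (free surfaces at top/bottom)
    k_sh_v = params.shear_modulus * dy * dx / dz
    for i in range(n_ap):
        for k in range(n_depth):
            for j in range(n_thick - 1):
                a, b = flat(i, j, k), flat(i, j + 1, k)
                K[a, a] += k_sh_v
                K[b, b] += k_sh_v
                K[a, b] -= k_sh_v
                K[b, a] -= k_sh_v
    # gel shear: lateral (depth) chain, deepest layer anchored to the wall
    k_sh_l = params.shear_modulus * dy * dz / dx
    for i in range(n_ap):
        for j in range(n_thick):
            for k in range(n_depth - 1):
                a, b = flat(i, j, k), flat(i, j, k + 1)
                K[a, a] += k_sh_l
                K[b, b] += k_sh_l
                K[a, b] -= k_sh_l
                K[b, a] -= k_sh_l
            wall = flat(i, j, n_depth - 1)
            K[wall, wall] += k_sh_l  # fixed wall beyond the deepest layer

    # damping: c = 2 zeta m omega with omega the fundamental angular
    # frequency of the mass's own fiber (string formula at its layer
    # stress).  Referencing zeta to the vibration mode keeps the modal
    # damping ratio at its nominal value; referencing it to the much
    # stiffer local (inter-node) stiffness would overdamp the fundamental
    # by a factor ~sqrt(k_local / (m omega^2)) ~ 2.7 and suppress
    # self-oscillation entirely.
    c = np.empty(n)
    for j in range(n_thick):
        for k in range(n_depth):
            sigma = _layer_stress(params, k)
            omega = (2.0 * math.pi * string_natural_frequency(
                sigma, params.tissue_density, params.length_L)
                if sigma > 0 else 0.0)
            for i in range(n_ap):
                c[flat(i, j, k)] = 2.0 * params.damping_ratio * m * omega

    # pre-phonatory half-width at interior node positions y_i = (i+1) dy,
    # linear taper, posterior end (y=0) at posterior_width/2
    y = (np.arange(n_ap) + 1) * dy
    half_width = 0.5 * params.posterior_width * (1.0 - y / params.length_L)

    k_col = 3.0 * params.fiber_stress_cover * dz * dx / dy

    medial = np.array(
        [flat(i, j, 0) for i in range(n_ap) for j in range(n_thick)]
    )
    tables = GridTables(
        mass=m,
        stiffness=K,
        damping=c,
        prephonatory_half_width=half_width,
        collision_stiffness=k_col,
        dy=dy,
        dz=dz,
        medial_index=medial,
    )
    state = SimState(np.zeros(n), np.zeros(n), 0.0)
    return state, tables


def glottal_flow(
    area_profile: np.ndarray,
    params: VFModelParams,
    supraglottal_pressure: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Quasi-steady Bernoulli flow with separation at the minimal section.

    Parameters
    ----------
    area_profile
        Array of shape ``(n_ap, n_thick)``: open cross-section area of
        each antero-posterior segment at each vertical level, inferior
        (subglottal) level first.
    supraglottal_pressure
        Load pressure above the glottis (0 without a tract).

    Returns
    -------
    flow, pressure
        Volumetric flow [m^3/s] and the driving pressure on each medial
        cell, shape ``(n_ap, n_thick)``.  The flow-controlling area is
        the minimal vertical cross-section of each antero-posterior
        segment, summed along the antero-posterior axis:
        ``a_min = sum_i min_j area[i, j]``, and
        ``U = a_min * sqrt(2 (P_L - P_supra) / rho_air)``.  Within each
        segment the flow separates at the minimal vertical level: cells
        upstream of it carry the Bernoulli pressure
        ``P_supra + (P_L - P_supra) * (1 - (a_seg_min / a)^2)``, cells at
        or downstream of it carry the supraglottal pressure, and closed
        segments carry the full subglottal pressure on the
        subglottal-facing cells below the closure.
    """
    a = np.asarray(area_profile, dtype=float)
    if a.ndim != 2:
        raise ValueError("area_profile must be 2-D (n_ap, n_thick)")
    if np.any(a < 0):
        raise ValueError("negative area in area_profile")
    n_ap, n_thick = a.shape
    j_min = np.argmin(a, axis=1)  # per-segment separation level
    a_seg_min = a[np.arange(n_ap), j_min]
    a_min = float(a_seg_min.sum())
    p_trans = params.lung_pressure - supraglottal_pressure
    if a_min <= 0 or p_trans <= 0:
        flow = 0.0
    else:
        flow = a_min * math.sqrt(2.0 * p_trans / params.air_density)

    levels = np.arange(n_thick)
    upstream = levels[None, :] < j_min[:, None]
    open_seg = a_seg_min > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio2 = np.where(a > 0, (a_seg_min[:, None] / np.where(a > 0, a, 1.0)) ** 2, 0.0)
    bernoulli = supraglottal_pressure + max(p_trans, 0.0) * (1.0 - ratio2)
    pressure = np.where(
        upstream,
        np.where(open_seg[:, None], bernoulli, params.lung_pressure),
        supraglottal_pressure,
    )
    return flow, pressure


def _aero_force(
    x: np.ndarray, params: VFModelParams, tables: GridTables,
    supraglottal_pressure: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Aerodynamic + collision force on all masses; also returns the flow."""
    n_ap, n_thick, n_depth = params.grid
    f = np.zeros_like(x)
    x3 = x.reshape(n_ap, n_thick, n_depth)
    h = tables.prephonatory_half_width[:, None] + x3[:, :, 0]  # (n_ap, n_thick)
    width = 2.0 * np.maximum(h, 0.0)
    area = width * tables.dy
    flow, pressure = glottal_flow(area, params, supraglottal_pressure)
    f3 = f.reshape(n_ap, n_thick, n_depth)
    f3[:, :, 0] += pressure * tables.dy * tables.dz
    # collision penalty past the midplane
    pen = np.minimum(h, 0.0)
    f3[:, :, 0] += -tables.collision_stiffness * pen
    return f, flow


def derivatives(
    state: SimState,
    params: VFModelParams,
    tables: GridTables | None = None,
    supraglottal_pressure: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rates (velocity, acceleration) for the 2*n_masses state variables."""
    if tables is None:
        _, tables = build_grid(params)
    x, v = state.displacement, state.velocity
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise FloatingPointError(
            f"non-finite state at t = {state.time:.6g} s"
        )
    f_aero, _ = _aero_force(x, params, tables, supraglottal_pressure)
    accel = (-tables.stiffness @ x - tables.damping * v + f_aero) / tables.mass
    return v, accel


def step_rk4(
    state: SimState,
    params: VFModelParams,
    dt: float | None = None,
    tables: GridTables | None = None,
    supraglottal_pressure: float = 0.0,
) -> SimState:
    """One classical Runge-Kutta step, with post-step collision handling.

    In ``clamp`` collision mode, masses left past the midplane have any
    remaining inward velocity zeroed after the step (the penalty force
    still acts inside the step in both modes).
    """
    if dt is None:
        dt = params.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tables is None:
        _, tables = build_grid(params)
    x, v = state.displacement, state.velocity

    def rhs(xx: np.ndarray, vv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f_aero, _ = _aero_force(xx, params, tables, supraglottal_pressure)
        return vv, (-tables.stiffness @ xx - tables.damping * vv + f_aero) / tables.mass

    k1x, k1v = rhs(x, v)
    k2x, k2v = rhs(x + 0.5 * dt * k1x, v + 0.5 * dt * k1v)
    k3x, k3v = rhs(x + 0.5 * dt * k2x, v + 0.5 * dt * k2v)
    k4x, k4v = rhs(x + dt * k3x, v + dt * k3v)
    x_new = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)

    if np.max(np.abs(x_new)) > 10.0 * params.depth_D:
        raise FloatingPointError(
            f"integration unstable: |displacement| > 10*depth at "
            f"t = {state.time + dt:.6g} s"
        )

    if params.collision_mode == "clamp":
        n_ap, n_thick, n_depth = params.grid
        x3 = x_new.reshape(n_ap, n_thick, n_depth)
        v3 = v_new.reshape(n_ap, n_thick, n_depth)
        h = tables.prephonatory_half_width[:, None] + x3[:, :, 0]
        penetrating = (h < 0) & (v3[:, :, 0] < 0)
        v3[:, :, 0] = np.where(penetrating, 0.0, v3[:, :, 0])

    return SimState(x_new, v_new, state.time + dt)


class _WaveReflectionTract:
    """One-dimensional wave-reflection line on a stylised [a:] area function.

    A Kelly-Lochbaum scattering chain of ``n_sections`` uniform tubes; the
    glottal end is driven by the instantaneous glottal flow, the lip end
    radiates with a real reflection coefficient, and travelling waves are
    attenuated by a constant per-section factor standing in for viscous
    and wall losses (a lossless line overdrives its resonances until the
    supraglottal pressure chokes the transglottal flow).  Supplies the
    supraglottal load pressure seen by the glottis.  The section length
    fixes the internal update rate ``c / dl``; the caller holds the load
    constant between updates.
    """

    #: stylised [a:]: narrow pharynx opening to a wide oral cavity [m^2]
    def __init__(self, n_sections: int = 44, total_length: float = 0.175,
                 c: float = 350.0, rho: float = 1.14,
                 lip_reflection: float = -0.9, attenuation: float = 0.997):
        s = np.linspace(0.0, 1.0, n_sections)
        area_cm2 = 0.52 + 0.39 * s + 6.5 * np.clip((s - 0.45) / 0.55, 0, 1) ** 1.5
        self.area = area_cm2 * 1e-4
        self.attenuation = attenuation
        self.dl = total_length / n_sections
        self.c = c
        self.rho = rho
        self.dt = self.dl / c
        self.z = rho * c / self.area  # characteristic impedances
        za, zb = self.z[:-1], self.z[1:]
        self.r = (za - zb) / (za + zb)  # junction reflection coefficients
        self.lip_reflection = lip_reflection
        self.fwd = np.zeros(n_sections)
        self.bwd = np.zeros(n_sections)

    def step(self, flow: float) -> float:
        """Advance one internal sample; returns supraglottal pressure."""
        self.fwd *= self.attenuation
        self.bwd *= self.attenuation
        fwd, bwd, r = self.fwd, self.bwd, self.r
        new_fwd = np.empty_like(fwd)
        new_bwd = np.empty_like(bwd)
        # glottal end: flow source with high (rigid) source impedance
        new_fwd[0] = self.z[0] * flow + bwd[0]
        # interior scattering junctions
        new_fwd[1:] = (1 + r) * fwd[:-1] - r * bwd[1:]
        new_bwd[:-1] = r * fwd[:-1] + (1 - r) * bwd[1:]
        # lip end
        new_bwd[-1] = self.lip_reflection * fwd[-1]
        self.fwd, self.bwd = new_fwd, new_bwd
        return float(self.fwd[0] + self.bwd[0])


def simulate(params: VFModelParams, seed_amplitude: float = 1e-6,
             rng: np.random.Generator | None = None) -> SimOutput:
    """Integrate the model and extract f_o, flow and spectral metrics.

    The run starts from the pre-phonatory rest position with a small
    random velocity perturbation (so oscillation onset does not depend on
    a symmetric special state); with adequate lung pressure the MEAD
    instability grows into a limit cycle within a few tens of
    milliseconds.  f_o is estimated by autocorrelation of the
    post-transient glottal area waveform; if the post-transient area
    oscillation amplitude is negligible, the run is reported as not
    sustained and f_o is None.
    """
    if params.duration <= params.transient_discard:
        raise ValueError("duration must exceed transient_discard")
    if rng is None:
        rng = np.random.default_rng(0)
    state, tables = build_grid(params)
    state.velocity += seed_amplitude * rng.standard_normal(state.velocity.size)

    tract = _WaveReflectionTract(rho=params.air_density) \
        if params.tract == "aa" else None
    p_supra = 0.0
    tract_clock = 0.0

    n_steps = int(round(params.duration / params.dt))
    n_ap, n_thick, n_depth = params.grid
    times = np.empty(n_steps)
    areas = np.empty(n_steps)
    flows = np.empty(n_steps)

    for s in range(n_steps):
        x3 = state.displacement.reshape(n_ap, n_thick, n_depth)
        h = tables.prephonatory_half_width[:, None] + x3[:, :, 0]
        width = 2.0 * np.maximum(h, 0.0)
        # projected (visible) glottal area: vertical minimum per column
        areas[s] = float(width.min(axis=1).sum() * tables.dy)
        flow, _ = glottal_flow(width * tables.dy, params, p_supra)
        flows[s] = flow
        times[s] = state.time
        if tract is not None:
            tract_clock += params.dt
            while tract_clock >= tract.dt:
                p_supra = tract.step(flow)
                tract_clock -= tract.dt
        state = step_rk4(state, params, params.dt, tables, p_supra)

    post = times >= params.transient_discard
    area_post = areas[post]
    flow_post = flows[post]
    amplitude = float(np.max(area_post) - np.min(area_post))

    # sustained if the post-transient area swing is well above numerical dust
    rest_area = float(np.sum(2.0 * tables.prephonatory_half_width) * tables.dy)
    floor = max(1e-3 * max(rest_area, tables.dy * tables.dz), 1e-12)
    sustained = amplitude > floor

    f_o = None
    freqs = spec_db = None
    h1 = h2 = None
    if sustained:
        fs = 1.0 / params.dt
        gaw = VoiceSignal(area_post, fs, kind="gaw")
        try:
            f_o = estimate_f0_autocorr(gaw, window_len=min(0.1, 0.9 * gaw.duration))
        except UnvoicedError:
            sustained = False
        if f_o is not None:
            try:
                freqs, spec_db, h1, h2 = flow_spectrum(flow_post, fs, f_o)
            except ValueError:
                pass  # post-transient segment too short for a spectrum

    return SimOutput(
        time=times,
        glottal_area=areas,
        glottal_flow=flows,
        sustained=sustained,
        f_o=f_o,
        spectrum_freqs=freqs,
        spectrum_db=spec_db,
        h1_level=h1,
        h2_level=h2,
        amplitude=amplitude,
    )


def flow_spectrum(
    flow: np.ndarray,
    fs: float,
    f_o: float | None = None,
    max_freq: float = 20000.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized magnitude spectrum of a glottal flow segment.

    Returns ``(freqs, level_db, h1, h2)`` where ``level_db`` is the
    Hann-windowed magnitude spectrum in dB re its strongest harmonic
    (0 dB at the maximum) and h1/h2 are the levels at f_o and 2 f_o.
    ``f_o`` is estimated from the segment by autocorrelation when not
    supplied; at least 20 cycles must be present.
    """
    flow = np.asarray(flow, dtype=float)
    if f_o is None:
        f_o = estimate_f0_autocorr(
            VoiceSignal(flow, fs, kind="gaw"),
            window_len=min(0.1, 0.9 * flow.size / fs),
        )
    if flow.size * f_o / fs < 20:
        raise ValueError("need at least 20 cycles of f_o for the spectrum")
    seg = (flow - np.mean(flow)) * np.hanning(flow.size)
    mag = np.abs(np.fft.rfft(seg))
    freqs = np.fft.rfftfreq(flow.size, 1.0 / fs)
    keep = freqs <= max_freq
    freqs, mag = freqs[keep], mag[keep]

    df = fs / flow.size

    def level_at(f: float) -> float:
        lo = max(1, int(np.floor(0.97 * f / df)))
        hi = min(mag.size, int(np.ceil(1.03 * f / df)) + 1)
        return float(np.max(mag[lo:hi])) if hi > lo else 0.0

    a1 = level_at(f_o)
    a2 = level_at(2 * f_o)
    ref = max(a1, a2, np.max(mag[1:]) if mag.size > 1 else 1.0, 1e-300)
    level_db = 20.0 * np.log10(np.maximum(mag, 1e-300) / ref)
    h1 = 20.0 * math.log10(max(a1, 1e-300) / ref)
    h2 = 20.0 * math.log10(max(a2, 1e-300) / ref)
    return freqs, level_db, h1, h2


def params_for_adduction(adduction: str | float,
                         **overrides) -> VFModelParams:
    """Convenience constructor: 'tight' (0.1 mm), 'weak' (0.6 mm) or mm."""
    if adduction == "tight":
        w = POSTERIOR_WIDTH_TIGHT
    elif adduction == "weak":
        w = POSTERIOR_WIDTH_WEAK
    else:
        w = float(adduction) * 1e-3
    return VFModelParams(posterior_width=w, **overrides)
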