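"""Wall-impinging jet whistle model.

An aeroacoustic (AA) sound source needs no tissue vibration: a glottal air
jet striking an opposing wall can lock into a feedback loop between
downstream-travelling flow structures and upstream-travelling acoustic
waves.  The entrained frequencies are

    f_n = n * u / x_wall,        u = V / A_gl,

where ``n`` is the mode number, ``x_wall`` the impingement length (jet
origin to wall), ``V`` the volumetric airflow and ``A_gl`` the glottal
constriction area, so ``u`` is the mean convection speed of the coherent
flow structures.  A vortex whistle of this kind is only stable when the
Strouhal number ``St = f * d / u`` (``d`` = jet diameter) satisfies
``d/x < St < 1``.

This module evaluates that model over physiological parameter ranges to
ask whether an AA mechanism could in principle cover the soprano "whistle
register" (roughly 1000-1600 Hz).  All quantities are SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JetParams",
    "JetResult",
    "mode_frequency",
    "isofrequency_map",
    "whistle_range_feasible",
]


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class JetParams:
    """Inputs of the impinging-jet whistle model.

    Parameters
    ----------
    flow_rate
        Volumetric airflow V [m^3/s].
    glottal_area
        Glottal constriction area A_gl [m^2].
    impingement_length
        Jet length x_wall from glottis to the impinged wall [m].
    mode
        Whistle mode number n >= 1 (mode 1 is the lowest stable frequency).
    jet_diameter
        Jet diameter d [m].  If omitted it is derived from the glottal area
        as the circular-equivalent diameter d = 2*sqrt(A_gl/pi); a supplied
        value wins over the derived one.
    """

    flow_rate: float
    glottal_area: float
    impingement_length: float
    mode: int = 1
    jet_diameter: float | None = field(default=None)

    def __post_init__(self) -> None:
        _require_positive(
            flow_rate=self.flow_rate,
            glottal_area=self.glottal_area,
            impingement_length=self.impingement_length,
        )
        if int(self.mode) != self.mode or self.mode < 1:
            raise ValueError(f"mode must be a positive integer, got {self.mode!r}")
        if self.jet_diameter is not None:
            _require_positive(jet_diameter=self.jet_diameter)

    @property
    def effective_jet_diameter(self) -> float:
        """Jet diameter actually used: supplied d, else 2*sqrt(A_gl/pi)."""
        if self.jet_diameter is not None:
            return self.jet_diameter
        return 2.0 * math.sqrt(self.glottal_area / math.pi)


@dataclass(frozen=True)
class JetResult:
    """Outputs of the impinging-jet whistle model (SI units)."""

    convection_speed: float  # u = V/A_gl [m/s]
    frequency: float  # f_n = n*u/x_wall [Hz]
    strouhal: float  # St = f*d/u
    stable: bool  # d/x < St < 1 with strict inequalities


def mode_frequency(params: JetParams) -> JetResult:
    """Evaluate the whistle frequency of mode ``n`` for one parameter set.

    The convection speed is ``u = V/A_gl`` and the mode-n frequency
    ``f_n = n*u/x_wall``.  The stability flag applies the strict Strouhal
    criterion ``d/x < St < 1``; boundary values are flagged unstable.

    Notes
    -----
    The Strouhal number uses the effective jet diameter (supplied value
    wins), while the lower stability bound ``d/x`` uses the
    circular-equivalent orifice diameter ``2*sqrt(A_gl/pi)``.  For mode 1
    the identity ``St = f*d/u = d/x`` holds whenever both sides use the
    same diameter, so with a purely derived diameter mode 1 sits exactly on
    the lower bound and is flagged unstable; a separately supplied jet
    diameter (impinging jets entrain air and widen toward the wall) can
    place it strictly inside the stable band.
    """
    u = params.flow_rate / params.glottal_area
    f = params.mode * u / params.impingement_length
    d = params.effective_jet_diameter
    d_orifice = 2.0 * math.sqrt(params.glottal_area / math.pi)
    st = f * d / u
    stable = (d_orifice / params.impingement_length) < st < 1.0
    return JetResult(convection_speed=u, frequency=f, strouhal=st, stable=stable)


def isofrequency_map(
    flow_rate: float,
    area_grid: np.ndarray,
    length_grid: np.ndarray,
) -> np.ndarray:
    """Mode-1 frequency matrix over a (glottal area, impingement length) grid.

    Returns ``M[i, j]`` = mode-1 frequency at ``(area_grid[i],
    length_grid[j])`` for the given flow, i.e. the isoparametric frequency
    chart of the whistle model at fixed V.
    """
    area_grid = np.asarray(area_grid, dtype=float)
    length_grid = np.asarray(length_grid, dtype=float)
    if area_grid.size == 0 or length_grid.size == 0:
        raise ValueError("area_grid and length_grid must be non-empty")
    if np.any(area_grid <= 0) or np.any(length_grid <= 0):
        raise ValueError("grids must be strictly positive")
    if np.any(np.diff(area_grid) <= 0) or np.any(np.diff(length_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    _require_positive(flow_rate=flow_rate)
    u = flow_rate / area_grid  # per-area convection speed
    return u[:, None] / length_grid[None, :]


def whistle_range_feasible(
    flow_rate: float,
    f_lo: float,
    f_hi: float,
    area_bounds: tuple[float, float],
    length_bounds: tuple[float, float],
    n_grid: int = 200,
) -> tuple[bool, dict | None]:
    """Scan (A, x) bounds for a *stable* mode-1 whistle inside [f_lo, f_hi].

    Stability requires ``d/x < St < 1``; with the circular-equivalent jet
    diameter the mode-1 Strouhal number equals ``d/x`` exactly, so the scan
    supplies a slightly widened jet (d = 1.15 of circular-equivalent,
    standing in for downstream jet spreading) to probe strict interior
    stability.

    Returns ``(feasible, witness)`` where the witness dict holds one
    conforming parameter set (area, length, frequency, strouhal) or None.
    """
    if not f_lo < f_hi:
        raise ValueError(f"f_lo must be < f_hi, got {f_lo} >= {f_hi}")
    a_lo, a_hi = area_bounds
    x_lo, x_hi = length_bounds
    if not (0 < a_lo < a_hi and 0 < x_lo < x_hi):
        raise ValueError("area/length bounds must be positive and increasing")
    areas = np.linspace(a_lo, a_hi, n_grid)
    lengths = np.linspace(x_lo, x_hi, n_grid)
    for a in areas:
        d = 1.15 * 2.0 * math.sqrt(a / math.pi)
        for x in lengths:
            res = mode_frequency(
                JetParams(flow_rate, a, x, mode=1, jet_diameter=d)
            )
            if res.stable and f_lo <= res.frequency <= f_hi:
                witness = {
                    "glottal_area": float(a),
                    "impingement_length": float(x),
                    "frequency": float(res.frequency),
                    "strouhal": float(res.strouhal),
                }
                return True, witness
    return False, None
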