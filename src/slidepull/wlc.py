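"""Worm-like chain (WLC) entropic elasticity.

The interpolation formula for the tension of a semi-flexible polymer of
persistence length L_p and contour length L_c held at end-to-end
extension z:

    F(z) = (k_B T / L_p) * [ 1/4 * (1 - z/L_c)^-2 + z/L_c - 1/4 ]

F is strictly increasing in z, diverges as z -> L_c, and is linear in
1/L_p.  The latter property gives the exact parallel-composition rule:
n identical chains stretched in parallel respond like a single chain
with effective persistence length L_p/n and the same contour length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy

__all__ = [
    "WLCParams",
    "WLCFitResult",
    "wlc_force",
    "wlc_extension",
    "wlc_stiffness",
    "fit_wlc",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    Attributes
    ----------
    persistence_length : float
        Bending-stiffness length scale L_p, nm.
    contour_length : float
        Fully stretched length L_c, nm.
    temperature : float
        Absolute temperature, K.
    """

    persistence_length: float
    contour_length: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.contour_length <= 0:
            raise ValueError("contour_length must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy, pN*nm."""
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class WLCFitResult:
    """Result of least-squares WLC fitting of a stretch segment.

    ``effective_persistence_length`` / ``effective_contour_length`` are
    the parameters of the single WLC that best describes the data; when
    the data come from m parallel chains of persistence length L_p the
    effective persistence length approaches L_p/m.
    """

    params: WLCParams
    effective_persistence_length: float
    effective_contour_length: float
    residual_rms: float
    n_points: int
    converged: bool = True
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged


def wlc_force(extension, params: WLCParams):
    """WLC tension (pN) at a given extension (nm).

    Accepts a scalar or array extension in [0, L_c). Raises ValueError
    for negative extensions or extensions at/beyond the contour length,
    where the model diverges.
    """
    z = np.asarray(extension, dtype=float)
    if np.any(z < 0):
        raise ValueError("extension must be non-negative")
    if np.any(z >= params.contour_length):
        raise ValueError(
            "extension must be below the contour length "
            f"({params.contour_length} nm); WLC force diverges at full extension"
        )
    x = z / params.contour_length
    f = (params.kBT / params.persistence_length) * (0.25 * (1.0 - x) ** -2 + x - 0.25)
    return f if np.ndim(extension) else float(f)


def wlc_stiffness(extension, params: WLCParams):
    """Analytic slope dF/dz (pN/nm) of the WLC force law.

    This is the effective spring constant of the stretched chain; close
    to a rupture it sets the instantaneous loading rate r = k_eff * v.
    """
    z = np.asarray(extension, dtype=float)
    if np.any(z < 0):
        raise ValueError("extension must be non-negative")
    if np.any(z >= params.contour_length):
        raise ValueError("extension must be below the contour length")
    x = z / params.contour_length
    k = (params.kBT / (params.persistence_length * params.contour_length)) * (
        0.5 * (1.0 - x) ** -3 + 1.0
    )
    return k if np.ndim(extension) else float(k)


_BRACKET_EPS = 1e-9


def wlc_extension(force: float, params: WLCParams) -> float:
    """Numerical inverse of the WLC force law: extension (nm) at a tension (pN).

    Solved by bracketed root finding on [0, L_c*(1 - 1e-9)], which is
    robust against the divergence at z = L_c.
    """
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    hi = params.contour_length * (1.0 - _BRACKET_EPS)
    f_hi = wlc_force(hi, params)
    if force >= f_hi:
        return hi
    return float(brentq(lambda z: wlc_force(z, params) - force, 0.0, hi, xtol=1e-12, rtol=1e-14))


def fit_wlc(
    points: Sequence[Tuple[float, float]],
    temperature: float = DEFAULT_TEMPERATURE_K,
    fix_persistence: Optional[float] = None,
) -> WLCFitResult:
    """Least-squares fit of the WLC force law to (extension, force) points.

    Parameters
    ----------
    points
        Iterable of (extension nm, force pN) pairs; at least 5 points.
    temperature
        Absolute temperature in K used for k_B*T.
    fix_persistence
        If given, L_p is held at this value (nm) and only L_c is fitted.

    Returns
    -------
    WLCFitResult
        Fitted parameters; ``converged`` is False (with a message) for
        degenerate inputs or optimizer failure, never a silent success.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (extension, force) pairs")
    n_free = 1 if fix_persistence is not None else 2
    if pts.shape[0] < max(5, n_free + 1):
        raise ValueError(f"need at least 5 points, got {pts.shape[0]}")
    z, f = pts[:, 0], pts[:, 1]
    if np.any(z <= 0):
        raise ValueError("extensions must be positive")

    def _flagged(msg: str) -> WLCFitResult:
        p = WLCParams(fix_persistence or 1.0, float(np.max(z)) * 2.0, temperature)
        return WLCFitResult(p, p.persistence_length, p.contour_length,
                            float("nan"), len(z), converged=False, message=msg)

    if np.all(f <= 0) or np.ptp(f) == 0:
        return _flagged("degenerate force data (no stretch response)")

    kbt = thermal_energy(temperature)
    zmax = float(np.max(z))

    def model(lp: float, lc: float) -> np.ndarray:
        x = np.clip(z / lc, 0.0, 1.0 - _BRACKET_EPS)
        return (kbt / lp) * (0.25 * (1.0 - x) ** -2 + x - 0.25)

    # Initial guesses: generic single-chain L_p, contour just beyond the data.
    lp0 = fix_persistence if fix_persistence is not None else 4.0
    lc0 = 1.1 * zmax

    if fix_persistence is not None:
        def resid(theta):
            return model(fix_persistence, theta[0]) - f
        x0, lb, ub = [lc0], [zmax * (1 + 1e-6)], [np.inf]
    else:
        def resid(theta):
            return model(theta[0], theta[1]) - f
        x0, lb, ub = [lp0, lc0], [1e-6, zmax * (1 + 1e-6)], [np.inf, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        return _flagged(f"optimizer failed: {sol.message}")

    if fix_persistence is not None:
        lp_fit, lc_fit = float(fix_persistence), float(sol.x[0])
    else:
        lp_fit, lc_fit = float(sol.x[0]), float(sol.x[1])
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    params = WLCParams(lp_fit, lc_fit, temperature)
    return WLCFitResult(params, lp_fit, lc_fit, rms, len(z))
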