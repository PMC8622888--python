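"""Per-frame estimation of the Booth shape parameter B.

For each frame the size coefficient is pinned to half the measured maximum
horizontal length, ``a = L_max / 2``, and the single remaining parameter B is
found by derivative-free simplex descent (Nelder-Mead) on the polar radial
least-squares objective

    sum_i ( r_i - a * sqrt(cos^2 phi_i + B^2 sin^2 phi_i) )^2

over the centered contour points.  Contour points closer than 2 px to the
origin are excluded (their angle is numerically unstable).  Across a sequence
the previous frame's optimum warm-starts the next fit.

Because the silhouette is star-shaped about the centering origin, the polar
boundary at each angle is the outermost contour pixel along that ray.  The
objective therefore keeps the maximum-radius contour pixel per angular bin
(ray casting, 720 bins by default).  This matters for near-tangent shapes
(B below about 0.1): the concave notch between the two lobes is narrower
than one pixel there, and the rasterized notch walls otherwise alias into
spurious inner points that bias B toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .booth_geometry import B_MIN
from .image_pipeline import ContourPointSet

__all__ = ["FrameFit", "fit_shape", "fit_sequence", "polar_boundary", "R_EXCLUDE_PX", "N_PHI_BINS"]

#: Contour points with r below this radius (px) are excluded from the objective.
R_EXCLUDE_PX = 2.0

_XATOL = 1e-6
_FATOL = 1e-9
_MAXITER = 500

#: Angular bins for the ray-cast extraction of the outermost boundary pixel.
N_PHI_BINS = 720


def polar_boundary(r: np.ndarray, phi: np.ndarray, n_bins: int = N_PHI_BINS):
    """Outermost point per angular bin: the star-shaped boundary in polar form.

    Returns the filtered (r, phi) arrays, one point per occupied bin.
    Invariant to point order and duplication.
    """
    bins = np.floor((phi + np.pi) / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    order = np.argsort(r, kind="stable")  # ascending: last write per bin wins
    winner = np.full(n_bins, -1, dtype=int)
    winner[bins[order]] = order
    winner = winner[winner >= 0]
    return r[winner], phi[winner]


@dataclass
class FrameFit:
    """Result of fitting one frame: a (px), B, RMS radial misfit (px)."""

    a: float
    B: float
    residual_rms: float
    n_points: int
    converged: bool
    time_s: float = 0.0
    L_max: int = 0
    ok: bool = True
    status: str = "ok"

    @classmethod
    def failed(cls, reason: str, time_s: float = 0.0) -> "FrameFit":
        return cls(
            a=math.nan, B=math.nan, residual_rms=math.nan, n_points=0,
            converged=False, time_s=time_s, L_max=0, ok=False, status=reason,
        )


def _objective(r: np.ndarray, phi: np.ndarray, a: float):
    c2 = np.cos(phi) ** 2
    s2 = np.sin(phi) ** 2

    def f(bvec: np.ndarray) -> float:
        b = min(max(float(bvec[0]), B_MIN), 1.0)
        model = a * np.sqrt(c2 + b * b * s2)
        d = r - model
        return float(d @ d)

    return f


def fit_shape(contour: ContourPointSet, a_fixed: float, b_init: float = 0.5) -> FrameFit:
    """Fit B for one centered polar contour with the size coefficient fixed.

    Returns a :class:`FrameFit` with B clamped to (1e-6, 1]; ``converged`` is
    False if the simplex hit its iteration cap (the best B so far is still
    reported).
    """
    if len(contour) < 8:
        raise ValueError(f"need at least 8 contour points, got {len(contour)}")
    if not a_fixed > 0:
        raise ValueError(f"a_fixed must be positive, got {a_fixed}")
    keep = contour.r >= R_EXCLUDE_PX
    r, phi = contour.r[keep], contour.phi[keep]
    if len(r) == 0 or np.all(contour.r == 0):
        raise ValueError("degenerate contour: no usable points with r >= 2 px")
    r, phi = polar_boundary(r, phi)
    if contour.pixel_grid:
        # rasterized contours mark pixel centers; the physical boundary runs
        # through their outer edge, half a pixel further from the origin
        r = r + 0.5
    obj = _objective(r, phi, a_fixed)
    res = optimize.minimize(
        obj,
        x0=[float(np.clip(b_init, B_MIN, 1.0))],
        method="Nelder-Mead",
        options={"xatol": _XATOL, "fatol": _FATOL, "maxiter": _MAXITER},
    )
    b_opt = min(max(float(res.x[0]), B_MIN), 1.0)
    rms = math.sqrt(obj([b_opt]) / len(r))
    return FrameFit(
        a=float(a_fixed),
        B=b_opt,
        residual_rms=rms,
        n_points=int(len(r)),
        converged=bool(res.success),
        time_s=contour.time_s,
        L_max=contour.L_max,
    )


def fit_sequence(contours: list[ContourPointSet | None], b_init: float = 0.5) -> list[FrameFit]:
    """Fit every frame of a sequence, warm-starting each fit from the last.

    ``None`` entries (frames whose segmentation failed upstream) and frames
    that raise during fitting become flagged rows; neighbors are unaffected
    and keep the last good warm start.
    """
    if not contours:
        raise ValueError("empty sequence")
    fits: list[FrameFit] = []
    b_prev = b_init
    for contour in contours:
        if contour is None:
            fits.append(FrameFit.failed("no contour"))
            continue
        try:
            a_fixed = contour.L_max / 2.0
            fit = fit_shape(contour, a_fixed, b_init=b_prev)
        except ValueError as exc:
            fits.append(FrameFit.failed(str(exc), time_s=contour.time_s))
            continue
        fits.append(fit)
        b_prev = fit.B
    return fits
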