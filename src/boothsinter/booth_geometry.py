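"""Closed-form geometry of lemniscates of Booth and the equivalent Hopper shapes.

Two coalescing equal cylinders, viewed in cross-section, trace a one-parameter
family of "inverse ellipse" profiles.  Two equivalent parameterizations are
used throughout the package:

* the polar lemniscate of Booth, ``r(phi) = a * sqrt(cos^2 phi + B^2 sin^2 phi)``
  with size coefficient ``a > 0`` and shape parameter ``B`` (``B = 1`` is a
  circle, ``B -> 0`` two tangent circles);
* the Hopper parameterization with parameter ``m in [0, 1)`` and final
  equivalent radius ``R0`` (``R0 = sqrt(2) * R_i`` for initial filament radius
  ``R_i``, so that the total cross-section area ``pi * R0^2`` is conserved).

The two are linked by ``B = (1 - m) / (1 + m)``.

Conventions: the filament pair lies horizontally, the bonding-neck plane is
``x = 0`` and ``phi`` is measured from the positive x axis, so the long axis of
the silhouette is along x (``r(0) = a``) and the neck half-thickness is
``r(pi/2) = a * B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "B_MIN",
    "BoothLemniscate",
    "HopperShape",
    "NeckGeometry",
    "booth_radius",
    "b_from_m",
    "m_from_b",
    "a_constant_area",
    "booth_area",
    "sample_curve",
    "neck_length",
    "bonding_angle",
]

#: Lower clamp for the shape parameter B; avoids the degenerate zero-radius
#: rays of the exact B = 0 limit.
B_MIN = 1e-6


def _check_b(B: float) -> float:
    B = float(B)
    if not 0.0 < B <= 1.0:
        raise ValueError(f"shape parameter B must be in (0, 1], got {B}")
    return B


def _check_m(m: float) -> float:
    m = float(m)
    if not 0.0 <= m < 1.0:
        raise ValueError(f"Hopper parameter m must be in [0, 1), got {m}")
    return m


@dataclass(frozen=True)
class BoothLemniscate:
    """Polar Booth lemniscate with size coefficient ``a`` and shape ``B``."""

    a: float
    B: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"size coefficient a must be positive, got {self.a}")
        _check_b(self.B)

    def radius(self, phi):
        return booth_radius(self, phi)

    @property
    def area(self) -> float:
        return booth_area(self)


@dataclass(frozen=True)
class HopperShape:
    """Hopper parameterization: parameter ``m`` and equivalent radius ``R0``."""

    m: float
    R0: float

    def __post_init__(self) -> None:
        _check_m(self.m)
        if not self.R0 > 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")

    def to_booth(self) -> BoothLemniscate:
        B = b_from_m(self.m)
        return BoothLemniscate(a=a_constant_area(B, self.R0), B=B)


@dataclass(frozen=True)
class NeckGeometry:
    """Bonding neck of length ``x_neck`` between filaments of diameter ``d``.

    ``theta`` is the bonding angle ``arcsin(x_neck / d)``; it is only defined
    while the neck is shorter than the filament diameter and is NaN otherwise.
    """

    x_neck: float
    d: float
    theta: float


def booth_radius(shape: BoothLemniscate, phi):
    """Polar radius ``a * sqrt(cos^2 phi + B^2 sin^2 phi)`` of the lemniscate.

    Total in ``phi`` (any real angle, scalar or array), periodic with period pi.
    """
    phi = np.asarray(phi, dtype=float)
    c = np.cos(phi)
    s = np.sin(phi)
    r = shape.a * np.sqrt(c * c + (shape.B * shape.B) * (s * s))
    return float(r) if r.ndim == 0 else r


def b_from_m(m: float) -> float:
    """Shape parameter ``B = (1 - m) / (1 + m)`` from the Hopper parameter."""
    m = _check_m(m)
    return (1.0 - m) / (1.0 + m)


def m_from_b(B: float) -> float:
    """Hopper parameter ``m = (1 - B) / (1 + B)``; exact inverse of b_from_m."""
    B = _check_b(B)
    return (1.0 - B) / (1.0 + B)


def a_constant_area(B: float, R0: float) -> float:
    """Size coefficient of the Booth lemniscate enclosing area ``pi * R0^2``.

    Closed form ``a = R0 * sqrt(2 / (1 + B^2))``; ranges from ``sqrt(2) * R0``
    (two tangent circles, B -> 0) down to ``R0`` (final circle, B = 1).
    """
    B = _check_b(B)
    if not R0 > 0:
        raise ValueError(f"R0 must be positive, got {R0}")
    return R0 * math.sqrt(2.0 / (1.0 + B * B))


def booth_area(shape: BoothLemniscate) -> float:
    """Enclosed area ``pi * a^2 * (1 + B^2) / 2`` (closed form of 1/2 ∮ r² dphi)."""
    return math.pi * shape.a * shape.a * (1.0 + shape.B * shape.B) / 2.0


def sample_curve(shape: HopperShape, n_points: int) -> np.ndarray:
    """Sample the closed boundary of a Hopper shape as (x, y) points.

    Uses the bounded, area-consistent Cartesian parameterization::

        x(alpha) = R0 (1 - m^2)(1 - m) sin(alpha) / (sqrt(1 + m^2) D(alpha))
        y(alpha) = R0 (1 - m^2)(1 + m) cos(alpha) / (sqrt(1 + m^2) D(alpha))
        D(alpha) = 1 + 2 m cos(2 alpha) + m^2,   alpha in [0, 2 pi)

    which is exactly the polar Booth lemniscate with ``B = (1-m)/(1+m)`` and
    the constant-area size coefficient.  Returns an ``(n_points, 2)`` array.
    """
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    m, R0 = shape.m, shape.R0
    alpha = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    denom = (1.0 + 2.0 * m * np.cos(2.0 * alpha) + m * m) * math.sqrt(1.0 + m * m)
    pref = R0 * (1.0 - m * m)
    x = pref * (1.0 - m) * np.sin(alpha) / denom
    y = pref * (1.0 + m) * np.cos(alpha) / denom
    return np.column_stack([x, y])


def neck_length(shape: HopperShape) -> float:
    """Full bonding-neck thickness at the symmetry plane, ``2 a B``.

    Equals ``2 R0 (1 - m) / sqrt(1 + m^2)``; decreases from ``2 R0`` (fully
    coalesced circle) to 0 as ``m -> 1`` (tangent circles).
    """
    m, R0 = shape.m, shape.R0
    return 2.0 * R0 * (1.0 - m) / math.sqrt(1.0 + m * m)


def bonding_angle(x_neck: float, d: float) -> float:
    """Bonding angle ``theta = arcsin(x_neck / d)`` in radians.

    Returns NaN (out-of-domain marker) when ``x_neck > d``: in late-stage
    coalescence the neck outgrows the filament diameter and the bonding-angle
    description no longer applies.
    """
    if not d > 0:
        raise ValueError(f"filament diameter d must be positive, got {d}")
    if x_neck < 0:
        raise ValueError(f"neck length must be nonnegative, got {x_neck}")
    if x_neck > d:
        return math.nan
    return math.asin(x_neck / d)
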