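"""Sintering kinetics: from per-frame shape fits to the viscous sintering time.

The fitted shape parameter B of each frame is converted to the Hopper
parameter ``m = (1 - B) / (1 + B)`` and its square.  In the pure viscous
sintering window, m²(t) decreases roughly linearly; its ordinary
least-squares slope (dm²/dt)_experimental, combined with the theoretical
dimensionless rate of the master curve evaluated at a reference m²,
yields the characteristic viscous sintering time

    t_vs = (dm²/d(t/t_vs))_theoretical / (dm²/dt)_experimental

with ``t_vs = R_i * mu / Gamma`` linking it to the viscosity/surface-tension
ratio of the melt.

The master curve (dm²/d(t/t_vs) as a function of m², Hopper's abacus) is a
replaceable CSV table; the packaged default is a synthetic reconstruction
anchored at the published reference value f(0.3) = -0.4727 (see
``data/hopper_master_curve_synthetic.csv``).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .booth_geometry import bonding_angle, m_from_b
from .lemniscate_fit import FrameFit

__all__ = [
    "MasterCurve",
    "SinteringTrajectory",
    "KineticsResult",
    "load_default_master_curve",
    "build_trajectory",
    "experimental_slope",
    "master_coefficient",
    "characteristic_time",
    "capillary_ratio",
    "neck_angle_series",
    "analyze_kinetics",
    "DEFAULT_WINDOW_S",
    "DEFAULT_M2_REF",
]

#: Pure-sintering regression window (s): after the ~20 s warm-up lag, before
#: swelling/spreading sets in at about one minute.
DEFAULT_WINDOW_S = (20.0, 60.0)
#: Reference m² at which the theoretical master-curve coefficient is read.
DEFAULT_M2_REF = 0.3

_KNOT_RTOL = 0.01  # polynomial must reproduce every table knot within 1%


@dataclass
class MasterCurve:
    """Tabulated theoretical rate dm²/d(t/t_vs) vs m², with a polynomial fit.

    The rate is negative over the whole tabulated span (coalescence only
    drives m down).  The polynomial (default degree 3) is fitted to the knots
    at construction and must reproduce every knot within 1% relative.
    """

    m_squared: np.ndarray
    dm2_dtau: np.ndarray
    degree: int = 3
    coefficients: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        u = np.asarray(self.m_squared, dtype=float)
        f = np.asarray(self.dm2_dtau, dtype=float)
        if u.ndim != 1 or u.shape != f.shape or len(u) < self.degree + 1:
            raise ValueError("master curve needs matching 1-D columns with more knots than the fit degree")
        order = np.argsort(u)
        self.m_squared, self.dm2_dtau = u[order], f[order]
        if np.any(self.dm2_dtau >= 0):
            raise ValueError("master curve rate dm2/dtau must be negative everywhere")
        self.coefficients = np.polyfit(self.m_squared, self.dm2_dtau, self.degree)
        fitted = np.polyval(self.coefficients, self.m_squared)
        rel = np.abs(fitted - self.dm2_dtau) / np.abs(self.dm2_dtau)
        if np.any(rel > _KNOT_RTOL):
            raise ValueError(
                f"degree-{self.degree} polynomial misfits the master-curve table "
                f"(max relative error {rel.max():.3%} > 1%)"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.m_squared[0]), float(self.m_squared[-1])

    def rate(self, m2, extrapolate: bool = False):
        """Polynomial rate at m²; refuses extrapolation unless asked to."""
        m2 = np.asarray(m2, dtype=float)
        lo, hi = self.span
        if not extrapolate and (np.any(m2 < lo) or np.any(m2 > hi)):
            raise ValueError(f"m2={m2} outside the tabulated span [{lo}, {hi}]")
        out = np.polyval(self.coefficients, m2)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path: str | Path, degree: int = 3) -> "MasterCurve":
        table = pd.read_csv(path)
        return cls(table["m_squared"].to_numpy(), table["dm2_dtau"].to_numpy(), degree=degree)


def load_default_master_curve(degree: int = 3) -> MasterCurve:
    """Packaged master curve (synthetic reconstruction of Hopper's abacus)."""
    ref = importlib.resources.files("boothsinter") / "data" / "hopper_master_curve_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return MasterCurve.from_csv(path, degree=degree)


@dataclass
class SinteringTrajectory:
    """Per-frame table of (t, L_max, L_max ratio, a, B, m, m², residual)."""

    table: pd.DataFrame
    temperature_c: float | None = None
    pixel_scale: float = 1.0
    frame_interval_s: float = 1.0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ok(self) -> pd.Series:
        return self.table["status"] == "ok"


@dataclass
class KineticsResult:
    """Experimental slope, theoretical coefficient and the derived t_vs."""

    slope: float  # dm²/dt, s⁻¹
    slope_se: float
    window: tuple[float, float]
    theoretical_coefficient: float
    m2_ref: float
    t_vs: float  # s
    t_vs_uncertainty: float
    n_window: int = 0


def build_trajectory(
    fits: list[FrameFit],
    temperature_c: float | None = None,
    pixel_scale: float = 1.0,
    frame_interval_s: float = 1.0,
) -> SinteringTrajectory:
    """Tabulate per-frame fits: m = (1-B)/(1+B) row-wise, m², L_max ratio.

    The L_max ratio is relative to the first valid frame.  Flagged fits stay
    in the table with NaN values and their status string.
    """
    if not fits:
        raise ValueError("no fits to tabulate")
    rows = []
    for fit in fits:
        if fit.ok and math.isfinite(fit.B):
            m = m_from_b(fit.B)
            rows.append(
                dict(time_s=fit.time_s, L_max_px=2.0 * fit.a, a_px=fit.a, B=fit.B,
                     m=m, m_squared=m * m, residual_rms=fit.residual_rms, status=fit.status)
            )
        else:
            rows.append(
                dict(time_s=fit.time_s, L_max_px=math.nan, a_px=math.nan, B=math.nan,
                     m=math.nan, m_squared=math.nan, residual_rms=math.nan, status=fit.status)
            )
    table = pd.DataFrame(rows)
    valid = table["status"] == "ok"
    if not valid.any():
        raise ValueError("every frame in the sequence is flagged; nothing to tabulate")
    L0 = table.loc[valid, "L_max_px"].iloc[0]
    table.insert(2, "L_max_ratio", table["L_max_px"] / L0)
    return SinteringTrajectory(
        table=table, temperature_c=temperature_c,
        pixel_scale=pixel_scale, frame_interval_s=frame_interval_s,
    )


def experimental_slope(
    traj: SinteringTrajectory, window: tuple[float, float] = DEFAULT_WINDOW_S
) -> tuple[float, float]:
    """OLS slope of m² against time (s⁻¹) and its standard error, in-window."""
    t0, t1 = window
    tab = traj.table
    sel = traj.ok & (tab["time_s"] >= t0) & (tab["time_s"] <= t1)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"only {n} valid frames inside the window [{t0}, {t1}] s; need >= 3")
    res = stats.linregress(tab.loc[sel, "time_s"], tab.loc[sel, "m_squared"])
    return float(res.slope), float(res.stderr)


def master_coefficient(curve: MasterCurve, m2_ref: float = DEFAULT_M2_REF) -> float:
    """Theoretical coefficient f(m²_ref) from the master-curve polynomial."""
    return curve.rate(m2_ref)


def characteristic_time(
    slope_experimental: float, theoretical_coefficient: float, slope_se: float = 0.0
) -> tuple[float, float]:
    """t_vs = theoretical coefficient / experimental slope, with uncertainty.

    The uncertainty is first-order relative-error propagation from the slope
    alone: dt_vs = t_vs * (slope_se / |slope|); the theoretical coefficient is
    treated as exact.
    """
    if not slope_experimental < 0:
        raise ValueError(f"experimental slope must be negative (no coalescence signal): {slope_experimental}")
    if not theoretical_coefficient < 0:
        raise ValueError(f"theoretical coefficient must be negative: {theoretical_coefficient}")
    t_vs = theoretical_coefficient / slope_experimental
    return t_vs, t_vs * slope_se / abs(slope_experimental)


def capillary_ratio(t_vs: float, R_i: float) -> float:
    """Viscosity-to-surface-tension ratio mu/Gamma = t_vs / R_i (s/m)."""
    if not (t_vs > 0 and R_i > 0):
        raise ValueError(f"t_vs and R_i must be positive, got {t_vs}, {R_i}")
    return t_vs / R_i


def neck_angle_series(traj: SinteringTrajectory, R_i: float) -> pd.DataFrame:
    """Per-frame bonding neck length and bonding angle (d = 2 R_i, same units as a).

    The neck thickness is 2 a B; frames where it exceeds the filament diameter
    carry NaN for theta (late-stage coalescence, the angle is undefined).
    """
    if not traj.table["status"].eq("ok").any():
        raise ValueError("trajectory has no valid frames")
    d = 2.0 * R_i
    out = []
    for _, row in traj.table.iterrows():
        if row["status"] != "ok":
            out.append(dict(time_s=row["time_s"], x_neck=math.nan, theta=math.nan))
            continue
        x_neck = 2.0 * row["a_px"] * row["B"]
        theta = bonding_angle(x_neck, d)
        out.append(dict(time_s=row["time_s"], x_neck=x_neck, theta=theta))
    return pd.DataFrame(out)


def analyze_kinetics(
    traj: SinteringTrajectory,
    curve: MasterCurve,
    window: tuple[float, float] = DEFAULT_WINDOW_S,
    m2_ref: float = DEFAULT_M2_REF,
) -> KineticsResult:
    """Slope in the window + master coefficient at m²_ref -> t_vs."""
    slope, se = experimental_slope(traj, window)
    coeff = master_coefficient(curve, m2_ref)
    t_vs, dt_vs = characteristic_time(slope, coeff, se)
    t0, t1 = window
    tab = traj.table
    n = int((traj.ok & (tab["time_s"] >= t0) & (tab["time_s"] <= t1)).sum())
    return KineticsResult(
        slope=slope, slope_se=se, window=(t0, t1),
        theoretical_coefficient=coeff, m2_ref=m2_ref,
        t_vs=t_vs, t_vs_uncertainty=dt_vs, n_window=n,
    )
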