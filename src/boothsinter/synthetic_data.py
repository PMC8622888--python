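"""Forward simulator of backlit filament-coalescence image sequences.

Produces ground-truthed synthetic frames that emulate the acquisition the
package analyzes: a dark Booth-lemniscate silhouette on a bright background,
8-bit, 1 frame/s, with Gaussian blur, grey-level noise and an optional solid
"oven base" strip along the bottom edge.

The shape trajectory is driven by the master curve: after a warm-up lag with
a static near-tangent shape, m²(t) is integrated by fixed-step classical
Runge-Kutta from  dm²/dt = f(m²) / t_vs_true  and floored at zero (full
coalescence, a circle, after which the shape is static).  The size
coefficient follows the constant-area closed form; late-stage viscoelastic
swelling is emulated as an isotropic size ramp calibrated so the final
maximum-width ratio L_max/L_max_initial equals ``swell_ratio_final``
(the "stabilizes at 112%" observable), flat once the ramp ends.

All randomness flows from the single integer ``seed``; frame k uses the
child stream ``(seed, k)``, so any frame is bit-reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .booth_geometry import BoothLemniscate, a_constant_area, b_from_m, booth_radius
from .image_pipeline import FrameImage
from .sintering_kinetics import MasterCurve

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trajectory",
    "render_frame",
    "render_sequence",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic sintering sequence.

    Defaults mirror the analyzed acquisition: 1 frame/s at about 200 px/mm for
    filaments of radius ~1 mm (R0 = sqrt(2) * R_i ≈ 283 px), 8-bit frames, a
    ~20 s warm-up before the filament surface melts, a 2-minute sequence,
    characteristic time t_vs = 80 s, and a late swell of the maximum width to
    112% of its initial value between 60 s and 90 s.  The starting shape is
    m = 0.68 (B = 0.19): the first shape the camera resolves once sintering
    begins — nearer-tangent shapes have a concave notch narrower than one
    pixel at this resolution, which no contour analysis at the acquisition
    scale can capture.
    """

    t_vs_true: float = 80.0
    m_initial: float = 0.68
    warmup_s: float = 20.0
    frame_interval_s: float = 1.0
    n_frames: int = 120
    R0_px: float = 283.0
    image_size: tuple[int, int] = (960, 960)
    object_grey: int = 30
    background_grey: int = 220
    blur_sigma_px: float = 1.0
    noise_sigma_grey: float = 3.0
    swell_ratio_final: float | None = 1.12
    swell_start_s: float = 60.0
    swell_end_s: float = 90.0
    base_strip_rows: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.m_initial < 1.0:
            raise ValueError(f"m_initial must be in (0, 1), got {self.m_initial}")
        for g in (self.object_grey, self.background_grey):
            if not 0 <= g <= 255:
                raise ValueError(f"grey level {g} outside [0, 255]")
        if abs(self.object_grey - self.background_grey) < 50:
            raise ValueError("object and background grey must be separated by >= 50 levels")
        if self.t_vs_true <= 0 or self.frame_interval_s <= 0 or self.n_frames < 1:
            raise ValueError("t_vs_true, frame_interval_s and n_frames must be positive")


@dataclass
class GroundTruth:
    """Per-frame true (time, m, B, a, L_max) of a simulated sequence."""

    table: pd.DataFrame  # columns: time_s, m_true, B_true, a_true_px, L_max_true_px

    def __len__(self) -> int:
        return len(self.table)


def _swollen_size(times: np.ndarray, cfg: SimulationConfig, a_ca: np.ndarray) -> np.ndarray:
    """Size coefficient with the swelling/spreading emulation applied.

    Before ``swell_start_s`` the constant-area value holds.  During the ramp
    the width ratio a_true(t)/a_true(0) interpolates linearly from its value
    at swell onset up to ``swell_ratio_final`` at ``swell_end_s``, and stays
    flat afterwards — an isotropic size factor at fixed B that reproduces the
    observed stabilization of L_max/L_max_initial above unity.
    """
    if cfg.swell_ratio_final is None:
        return a_ca.copy()
    t0, t1 = cfg.swell_start_s, cfg.swell_end_s
    if t1 <= t0:
        t1 = t0 + cfg.frame_interval_s
    ratio_ca = a_ca / a_ca[0]
    onset = np.searchsorted(times, t0)
    r0 = ratio_ca[min(onset, len(times) - 1)]
    frac = np.clip((times - t0) / (t1 - t0), 0.0, 1.0)
    target = r0 + frac * (cfg.swell_ratio_final - r0)
    return np.where(times < t0, a_ca, a_ca[0] * target)


def simulate_trajectory(cfg: SimulationConfig, curve: MasterCurve) -> GroundTruth:
    """Integrate the master-curve dynamics into a ground-truth shape table.

    m² stays at m_initial² during the warm-up, then follows
    dm²/dt = f(m²)/t_vs_true under fixed-step classical Runge-Kutta (one step
    per frame interval), floored at zero.  B and the constant-area a follow
    from the closed forms; the swell ramp then scales a (and L_max = 2 a).
    """
    u0 = cfg.m_initial**2
    lo, hi = curve.span
    if u0 > hi:
        raise ValueError(
            f"master curve span [{lo}, {hi}] does not cover m_initial^2 = {u0:.4f}"
        )

    def f(u: float) -> float:
        if u <= 0.0:
            return 0.0
        return curve.rate(min(u, hi), extrapolate=True) / cfg.t_vs_true

    times = np.arange(cfg.n_frames, dtype=float) * cfg.frame_interval_s
    u = np.empty(cfg.n_frames)
    h = cfg.frame_interval_s
    cur = u0
    for k, t in enumerate(times):
        u[k] = cur
        if t + h <= cfg.warmup_s:
            continue
        # partial step if the warm-up ends mid-interval
        step = h if t >= cfg.warmup_s else t + h - cfg.warmup_s
        k1 = f(cur)
        k2 = f(max(cur + 0.5 * step * k1, 0.0))
        k3 = f(max(cur + 0.5 * step * k2, 0.0))
        k4 = f(max(cur + step * k3, 0.0))
        cur = cur + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        cur = max(cur, 0.0)

    m = np.sqrt(u)
    B = np.array([b_from_m(mi) for mi in m])
    a_ca = np.array([a_constant_area(Bi, cfg.R0_px) for Bi in B])
    a_true = _swollen_size(times, cfg, a_ca)
    table = pd.DataFrame(
        dict(time_s=times, m_true=m, B_true=B, a_true_px=a_true, L_max_true_px=2.0 * a_true)
    )
    return GroundTruth(table=table)


def render_frame(truth_row: pd.Series, cfg: SimulationConfig) -> FrameImage:
    """Render one 8-bit backlit frame from a ground-truth row.

    Pixels whose centered polar radius lies inside the Booth lemniscate
    (a_true, B_true) get ``object_grey``, the rest ``background_grey``; the
    optional base strip is drawn solid at object grey.  Gaussian blur, then
    additive Gaussian grey noise seeded from ``(seed, frame_index)``, clipping
    to [0, 255] and 8-bit quantization follow.
    """
    from scipy import ndimage  # local import keeps module import light

    nrows, ncols = cfg.image_size
    a, B = float(truth_row["a_true_px"]), float(truth_row["B_true"])
    cy = (nrows - cfg.base_strip_rows) // 2
    cx = ncols // 2
    margin = min(cx, ncols - 1 - cx, cy, nrows - 1 - cfg.base_strip_rows - cy)
    if a + 5 > margin:
        raise ValueError(f"shape with a = {a:.1f} px does not fit the frame with a 5 px margin")
    yy = cy - np.arange(nrows, dtype=float)[:, None]
    xx = np.arange(ncols, dtype=float)[None, :] - cx
    r = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx)
    inside = r <= booth_radius(BoothLemniscate(a=a, B=B), phi)
    img = np.where(inside, float(cfg.object_grey), float(cfg.background_grey))
    if cfg.base_strip_rows > 0:
        img[nrows - cfg.base_strip_rows :, :] = float(cfg.object_grey)
    if cfg.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.blur_sigma_px)
    if cfg.noise_sigma_grey > 0:
        frame_index = int(round(float(truth_row["time_s"]) / cfg.frame_interval_s))
        rng = np.random.default_rng([cfg.seed, frame_index])
        img = img + rng.normal(0.0, cfg.noise_sigma_grey, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameImage(pixels=img, time_s=float(truth_row["time_s"]), name=f"frame_{float(truth_row['time_s']):07.1f}s")


def render_sequence(cfg: SimulationConfig, curve: MasterCurve) -> tuple[list[FrameImage], GroundTruth]:
    """Simulate and render the whole sequence in memory."""
    truth = simulate_trajectory(cfg, curve)
    frames = [render_frame(row, cfg) for _, row in truth.table.iterrows()]
    return frames, truth


def generate_dataset(cfg: SimulationConfig, curve: MasterCurve, out_dir: str | Path):
    """Write PNG frames plus manifest and ground-truth CSVs to ``out_dir``.

    Re-running with the same config (same seed) reproduces identical bytes.
    Returns (list of frame paths, manifest path, ground-truth path).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    frames, truth = render_sequence(cfg, curve)
    paths = []
    manifest_rows = []
    for k, frame in enumerate(frames):
        name = f"frame_{k:04d}.png"
        path = out / name
        try:
            iio.imwrite(path, frame.pixels)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths.append(path)
        manifest_rows.append(dict(filename=name, time_s=frame.time_s))
    manifest_path = out / "manifest.csv"
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    truth.table.to_csv(truth_path, index=False)
    return paths, manifest_path, truth_path
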