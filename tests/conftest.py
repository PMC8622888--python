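"""Shared fixtures: master curve, small-scale simulated runs, rendered frames.

Synthetic sequences for tests use R0_px = 100 (objects well above the 60 px
validity floor of the fitting study) so the whole suite stays fast; the
physics and acquisition timing match the package defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import boothsinter as bs
from boothsinter.cli import AnalysisConfig, analyze_frames

TEST_R0_PX = 100.0
TEST_IMAGE = (380, 380)


@pytest.fixture(scope="session")
def curve() -> bs.MasterCurve:
    return bs.load_default_master_curve()


def make_sim_config(**overrides) -> bs.SimulationConfig:
    base = dict(R0_px=TEST_R0_PX, image_size=TEST_IMAGE, seed=7)
    base.update(overrides)
    return bs.SimulationConfig(**base)


def render_booth_frame(
    B: float,
    R0_px: float = TEST_R0_PX,
    blur: float = 1.0,
    noise: float = 3.0,
    seed: int = 1,
    a_px: float | None = None,
) -> bs.FrameImage:
    """One rendered frame of a constant-area Booth shape (or explicit a)."""
    a = a_px if a_px is not None else bs.a_constant_area(B, R0_px)
    cfg = make_sim_config(blur_sigma_px=blur, noise_sigma_grey=noise, seed=seed)
    row = pd.Series(dict(a_true_px=a, B_true=B, time_s=0.0))
    return bs.render_frame(row, cfg)


@pytest.fixture(scope="session")
def analyzed_runs(curve):
    """Cache of full simulate->render->analyze runs keyed by (t_vs, seed)."""
    cache: dict[tuple[float, int], tuple] = {}

    def run(t_vs: float = 80.0, seed: int = 7):
        key = (t_vs, seed)
        if key not in cache:
            cfg = make_sim_config(t_vs_true=t_vs, seed=seed)
            frames, truth = bs.render_sequence(cfg, curve)
            traj, kin, reason, contours = analyze_frames(frames, AnalysisConfig(), curve)
            cache[key] = (cfg, truth, traj, kin, reason)
        return cache[key]

    return run


def random_small_mask(rng: np.random.Generator) -> np.ndarray:
    """Random <=15x15 binary mask containing at least one 3x3 solid block."""
    nrows, ncols = rng.integers(7, 16, size=2)
    m = rng.random((nrows, ncols)) < 0.45
    r0 = rng.integers(0, nrows - 3)
    c0 = rng.integers(0, ncols - 3)
    m[r0 : r0 + 3, c0 : c0 + 3] = True
    return m


def brute_force_contour(mask: np.ndarray) -> np.ndarray:
    """Oracle: foreground pixels with any 8-neighbor outside the mask or on
    the image border (3x3-erosion semantics, border counted as background)."""
    nrows, ncols = mask.shape
    out = np.zeros_like(mask)
    for i in range(nrows):
        for j in range(ncols):
            if not mask[i, j]:
                continue
            on_border = i in (0, nrows - 1) or j in (0, ncols - 1)
            bg_neighbor = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrows and 0 <= jj < ncols and not mask[ii, jj]:
                        bg_neighbor = True
            out[i, j] = on_border or bg_neighbor
    return out
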