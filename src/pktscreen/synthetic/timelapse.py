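"""Synthetic GFP time-lapse movies with ground-truth trajectories.

Default acquisition mirrors the live-migration assay: one frame every
12 min for 12 h (61 frames).  Cells are rendered as Gaussian blobs that
follow persistent-random-walk paths; the ground truth records every cell
in every frame, so tracking fidelity can be scored exactly.

Paths reflect at the field border.  With ``confine_grid`` set, each cell
is instead confined to its own reflecting grid territory, which
guarantees non-contacting masks for any seed — the fixture used to test
identity-preserving tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import MotilityParams
from .motility import simulate_prw_path

__all__ = ["TimelapseConfig", "TimelapseMovie", "generate_timelapse"]

#: default pixel scale of the x20 live-imaging objective, um/px
DEFAULT_UM_PER_PX = 0.33


@dataclass(frozen=True)
class TimelapseConfig:
    n_cells: int = 20
    params: MotilityParams = MotilityParams(speed=0.8, persistence_time=120.0)
    n_frames: int = 61
    dt: float = 12.0                    # min
    image_shape: tuple[int, int] = (512, 512)
    um_per_px: float = DEFAULT_UM_PER_PX
    blob_sigma_px: float = 15.0
    blob_amplitude: float = 3000.0
    background: float = 100.0
    noise_sd: float = 20.0
    min_separation_px: float = 0.0      # minimum initial spacing (0 = random)
    confine_grid: tuple[int, int] | None = None   # (nx, ny) territories

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        h, w = self.image_shape
        if 8 * self.blob_sigma_px >= min(h, w):
            raise ValueError("cell radius must be smaller than the image extent")
        if self.confine_grid is not None:
            nx, ny = self.confine_grid
            if nx * ny < self.n_cells:
                raise ValueError("confine_grid too small for n_cells")
            if min(w // nx, h // ny) <= 2 * self._margin_px:
                raise ValueError("territories too small for the blob size")

    @property
    def _margin_px(self) -> float:
        return 4.0 * self.blob_sigma_px


@dataclass
class TimelapseMovie:
    stack: np.ndarray        # (n_frames, H, W) uint16
    truth: pd.DataFrame      # cell_id, frame, t_min, x/y in um and px
    config: TimelapseConfig

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.config.n_frames) * self.config.dt


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    z = np.mod(x - lo, 2 * span)
    return lo + np.where(z > span, 2 * span - z, z)


def _cell_bounds(cfg: TimelapseConfig, i: int) -> tuple[float, float, float, float]:
    """(x_lo, x_hi, y_lo, y_hi) reflection bounds of cell i, px."""
    h, w = cfg.image_shape
    m = cfg._margin_px
    if cfg.confine_grid is None:
        return m, w - m, m, h - m
    nx, ny = cfg.confine_grid
    tw, th = w / nx, h / ny
    gx, gy = i % nx, i // nx
    return gx * tw + m, (gx + 1) * tw - m, gy * th + m, (gy + 1) * th - m


def generate_timelapse(config: TimelapseConfig | None = None,
                       rng_seed: int = 0,
                       params_per_cell: list[MotilityParams] | None = None
                       ) -> TimelapseMovie:
    cfg = config or TimelapseConfig()
    if params_per_cell is not None and len(params_per_cell) != cfg.n_cells:
        raise ValueError("params_per_cell length must equal n_cells")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    h, w = cfg.image_shape

    # starting positions: territory centers (jittered) or random draws
    starts = []
    for i in range(cfg.n_cells):
        x_lo, x_hi, y_lo, y_hi = _cell_bounds(cfg, i)
        if cfg.confine_grid is not None:
            cx, cy = 0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi)
            jx = 0.1 * (x_hi - x_lo) * rng.uniform(-1, 1)
            jy = 0.1 * (y_hi - y_lo) * rng.uniform(-1, 1)
            starts.append((cx + jx, cy + jy))
        else:
            tries = 0
            while True:
                cand = (rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
                if cfg.min_separation_px > 0 and starts:
                    d = np.linalg.norm(np.asarray(starts) - cand, axis=1)
                    if d.min() < cfg.min_separation_px:
                        tries += 1
                        if tries > 10000:
                            raise RuntimeError(
                                "cannot place cells at requested separation")
                        continue
                starts.append(cand)
                break

    paths_px = np.empty((cfg.n_cells, cfg.n_frames, 2))
    for i in range(cfg.n_cells):
        p = params_per_cell[i] if params_per_cell is not None else cfg.params
        path_um = simulate_prw_path(p, cfg.n_frames - 1, cfg.dt, rng_seed=rng)
        path = path_um / cfg.um_per_px + np.asarray(starts[i])
        x_lo, x_hi, y_lo, y_hi = _cell_bounds(cfg, i)
        path[:, 0] = _reflect(path[:, 0], x_lo, x_hi)
        path[:, 1] = _reflect(path[:, 1], y_lo, y_hi)
        paths_px[i] = path

    # render blobs in local windows only (5 sigma)
    win = int(math.ceil(5 * cfg.blob_sigma_px))
    stack = np.empty((cfg.n_frames, h, w), dtype=np.uint16)
    for f in range(cfg.n_frames):
        img = np.full((h, w), cfg.background, dtype=float)
        for i in range(cfg.n_cells):
            cx, cy = paths_px[i, f]
            x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
            y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img[y0:y1, x0:x1] += cfg.blob_amplitude * np.exp(
                -r2 / (2 * cfg.blob_sigma_px ** 2))
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 65535).astype(np.uint16)

    rec = []
    t = np.arange(cfg.n_frames) * cfg.dt
    for i in range(cfg.n_cells):
        rec.append(pd.DataFrame({
            "cell_id": i, "frame": np.arange(cfg.n_frames), "t_min": t,
            "x_um": paths_px[i, :, 0] * cfg.um_per_px,
            "y_um": paths_px[i, :, 1] * cfg.um_per_px,
            "x_px": paths_px[i, :, 0], "y_px": paths_px[i, :, 1],
        }))
    truth = (pd.concat(rec, ignore_index=True) if rec else
             pd.DataFrame(columns=["cell_id", "frame", "t_min",
                                   "x_um", "y_um", "x_px", "y_px"]))
    return TimelapseMovie(stack=stack, truth=truth, config=cfg)
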