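"""Render synthetic phagokinetic-track montages.

A PKT well image is a bright field covered by a lawn of dark latex
beads.  A migrating cell phagocytoses the beads along its path, leaving a
bead-free swath (the track) with the cell body sitting at the path end.
The renderer reproduces exactly that geometry: a Poisson bead lawn,
per-path cleared stadium-shaped corridors of width ``track_width``, dark
elliptical cell bodies, additive Gaussian noise, and a ground-truth label
mask assigning each track's cleared pixels a unique id.  Whole-well
montages are conceptually 6 x 6 tile grids; the renderer produces the
assembled montage and records the tiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PKTRenderConfig", "PKTMontage", "render_pkt_montage"]

#: default pixel scale of the x10 transmitted-light montage, um/px
DEFAULT_UM_PER_PX = 0.65


@dataclass(frozen=True)
class PKTRenderConfig:
    """Rendering parameters; intensities are 16-bit counts."""

    image_shape: tuple[int, int] = (1200, 1200)
    um_per_px: float = DEFAULT_UM_PER_PX
    bead_density: float = 0.19          # beads / um^2
    bead_radius_px: float = 1.2
    background: float = 10000.0
    bead_intensity: float = 3500.0
    cell_intensity: float = 1500.0
    cell_axes_px: tuple[float, float] = (8.0, 6.0)
    noise_sd: float = 150.0
    montage_tiles: tuple[int, int] = (6, 6)

    def __post_init__(self) -> None:
        if self.bead_density <= 0:
            raise ValueError("bead_density must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PKTMontage:
    """Rendered montage plus its ground truth."""

    image: np.ndarray                 # uint16, (H, W)
    labels: np.ndarray                # uint16 label mask, 0 = lawn
    paths_px: list[np.ndarray]        # per-track path in pixel coords (x, y)
    cell_centers_px: list[tuple[float, float]]
    colliding_tracks: frozenset[int]  # 1-based track ids whose swaths overlap
    config: PKTRenderConfig

    @property
    def n_images(self) -> int:
        return int(np.prod(self.config.montage_tiles))


def _path_clear_mask(path_px: np.ndarray, radius_px: float,
                     shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels within ``radius_px`` of the polyline."""
    # densify the polyline so nearest-vertex distance ~ distance to curve
    pts = [path_px[:1]]
    for a, b in zip(path_px[:-1], path_px[1:]):
        seg = b - a
        n = max(1, int(math.ceil(np.hypot(*seg) / 0.25)))
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pts.append(a[None, :] + t * seg[None, :])
    dense = np.concatenate(pts, axis=0)

    h, w = shape
    x0 = max(0, int(np.floor(dense[:, 0].min() - radius_px - 1)))
    x1 = min(w, int(np.ceil(dense[:, 0].max() + radius_px + 2)))
    y0 = max(0, int(np.floor(dense[:, 1].min() - radius_px - 1)))
    y1 = min(h, int(np.ceil(dense[:, 1].max() + radius_px + 2)))
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    tree = cKDTree(dense)
    d, _ = tree.query(np.column_stack([xx.ravel(), yy.ravel()]),
                      distance_upper_bound=radius_px + 0.5)
    local = (d <= radius_px).reshape(yy.shape)
    mask[y0:y1, x0:x1] = local
    return mask


def _ellipse_mask(center: tuple[float, float], axes: tuple[float, float],
                  angle: float, shape: tuple[int, int]) -> np.ndarray:
    cx, cy = center
    a, b = axes
    h, w = shape
    r = max(a, b) + 1
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def render_pkt_montage(
    paths_um: list[np.ndarray],
    track_width_um: float | list[float] = 15.0,
    config: PKTRenderConfig | None = None,
    rng_seed=None,
    protrusiveness: float | list[float] = 0.0,
) -> PKTMontage:
    """Render a bead-lawn montage with one cleared track per path.

    Parameters
    ----------
    paths_um
        One (n_i, 2) array of (x, y) positions in um per cell; paths must
        lie within the field after scaling.
    track_width_um
        Full width of the cleared swath, scalar or per path (um).
    protrusiveness
        Adds sinusoidal jitter to each swath's local radius, roughening
        the track boundary (scalar or per path; 0 = smooth stadium).
    """
    cfg = config or PKTRenderConfig()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    h, w = cfg.image_shape
    scale = 1.0 / cfg.um_per_px

    widths = np.broadcast_to(np.asarray(track_width_um, dtype=float),
                             (len(paths_um),))
    protr = np.broadcast_to(np.asarray(protrusiveness, dtype=float),
                            (len(paths_um),))

    # per-track cleared masks
    paths_px, masks, centers = [], [], []
    for i, p_um in enumerate(paths_um):
        p_px = np.asarray(p_um, dtype=float) * scale
        if p_px[:, 0].min() < 0 or p_px[:, 1].min() < 0 \
                or p_px[:, 0].max() >= w or p_px[:, 1].max() >= h:
            raise ValueError(f"path {i} leaves the field after scaling")
        radius = 0.5 * widths[i] * scale
        mask = _path_clear_mask(p_px, radius, (h, w))
        if protr[i] > 0:
            # roughen: carve extra clearance lobes along the path
            n_lobes = max(3, int(protr[i] * len(p_px)))
            idx = rng.integers(0, len(p_px), size=n_lobes)
            for j in idx:
                lobe_r = radius * (0.4 + 0.6 * rng.random())
                ang = rng.uniform(0, 2 * math.pi)
                c = (p_px[j, 0] + radius * math.cos(ang),
                     p_px[j, 1] + radius * math.sin(ang))
                mask |= _ellipse_mask(c, (lobe_r, lobe_r), 0.0, (h, w))
        paths_px.append(p_px)
        masks.append(mask)
        centers.append((p_px[-1, 0], p_px[-1, 1]))

    # label mask, earlier tracks keep overlapping pixels; collisions flagged
    labels = np.zeros((h, w), dtype=np.uint16)
    colliding: set[int] = set()
    for i, mask in enumerate(masks):
        tid = i + 1
        if np.any(labels[mask]):
            hit = np.unique(labels[mask])
            colliding.update(int(t) for t in hit if t > 0)
            colliding.add(tid)
        labels[mask & (labels == 0)] = tid
    cleared = labels > 0

    # Poisson bead lawn outside cleared swaths
    area_um2 = h * w * cfg.um_per_px ** 2
    n_beads = int(rng.poisson(cfg.bead_density * area_um2))
    img = np.full((h, w), cfg.background, dtype=float)
    if n_beads:
        bx = rng.uniform(0, w, size=n_beads)
        by = rng.uniform(0, h, size=n_beads)
        keep = ~cleared[np.clip(by.astype(int), 0, h - 1),
                        np.clip(bx.astype(int), 0, w - 1)]
        bx, by = bx[keep], by[keep]
        bead = np.zeros((h, w), dtype=bool)
        r = cfg.bead_radius_px
        ri = int(math.ceil(r))
        dy, dx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
        stamp = (dx ** 2 + dy ** 2) <= r ** 2
        sy, sx = np.nonzero(stamp)
        sy, sx = sy - ri, sx - ri
        for x, y in zip(bx.astype(int), by.astype(int)):
            yy = y + sy
            xx = x + sx
            ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
            bead[yy[ok], xx[ok]] = True
        bead &= ~cleared
        img[bead] = cfg.bead_intensity

    # cell bodies at path ends (dark ellipses, oriented along last step)
    for i, (p_px, c) in enumerate(zip(paths_px, centers)):
        if len(p_px) >= 2:
            d = p_px[-1] - p_px[-2]
            ang = math.atan2(d[1], d[0]) if np.hypot(*d) > 0 else 0.0
        else:
            ang = 0.0
        body = _ellipse_mask(c, cfg.cell_axes_px, ang, (h, w))
        img[body] = cfg.cell_intensity

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    return PKTMontage(image=img, labels=labels, paths_px=paths_px,
                      cell_centers_px=centers,
                      colliding_tracks=frozenset(colliding), config=cfg)
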