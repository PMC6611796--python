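"""Synthetic cell/nucleus morphology scenes.

Generates label-mask pairs (nucleus mask, cell-body mask) emulating a
confocal actin/nuclei screen: each cell body contains exactly one
nucleus, except a configurable fraction of orphan nuclei rendered with
no body (to exercise the rejection rule).  Three archetypes control the
body shape: ``spread`` (large smooth ellipse), ``compact`` (small
ellipse) and ``spiky`` (disk with radial protrusions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon

__all__ = ["MorphologySceneConfig", "MorphologyScene", "generate_morphology_scene"]

ARCHETYPES = ("spread", "compact", "spiky")


@dataclass(frozen=True)
class MorphologySceneConfig:
    n_cells: int = 20
    archetype: str = "spread"
    n_protrusions: int = 6            # spiky archetype only
    orphan_fraction: float = 0.0      # fraction of nuclei without a body
    image_shape: tuple[int, int] = (1024, 1024)
    nucleus_radius_px: float = 7.0
    size_jitter: float = 0.0          # relative sd of per-cell size scaling

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 <= self.orphan_fraction <= 1):
            raise ValueError("orphan_fraction must be in [0, 1]")
        if self.n_protrusions < 1:
            raise ValueError("spiky archetype needs >= 1 protrusion")


@dataclass
class MorphologyScene:
    nucleus_mask: np.ndarray    # uint16 labels
    cell_mask: np.ndarray       # uint16 labels
    truth: pd.DataFrame         # cell_id, archetype, n_spikes, has_body

    @property
    def n_cells(self) -> int:
        return int(self.truth.shape[0])


def _body_polygon(archetype: str, scale: float, n_spikes: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Radial boundary polygon (x, y offsets) of one cell body."""
    theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    phase = rng.uniform(0, 2 * math.pi)
    if archetype == "spread":
        a, b = 45.0 * scale, 30.0 * scale
        r = a * b / np.sqrt((b * np.cos(theta - phase)) ** 2
                            + (a * np.sin(theta - phase)) ** 2)
    elif archetype == "compact":
        a, b = 18.0 * scale, 15.0 * scale
        r = a * b / np.sqrt((b * np.cos(theta - phase)) ** 2
                            + (a * np.sin(theta - phase)) ** 2)
    else:  # spiky: inner disk + narrow radial spikes
        r_in, r_out = 20.0 * scale, 40.0 * scale
        half_width = math.pi / n_spikes * 0.35
        r = np.full_like(theta, r_in)
        for k in range(n_spikes):
            c = phase + 2 * math.pi * k / n_spikes
            d = np.angle(np.exp(1j * (theta - c)))
            sel = np.abs(d) < half_width
            r[sel] = np.maximum(
                r[sel], r_in + (r_out - r_in) * np.cos(
                    0.5 * math.pi * d[sel] / half_width) ** 2)
    return r * np.cos(theta), r * np.sin(theta)


def generate_morphology_scene(config: MorphologySceneConfig | None = None,
                              rng_seed: int = 0) -> MorphologyScene:
    cfg = config or MorphologySceneConfig()
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    h, w = cfg.image_shape
    nuc = np.zeros((h, w), dtype=np.uint16)
    cell = np.zeros((h, w), dtype=np.uint16)

    n_orphans = int(round(cfg.orphan_fraction * cfg.n_cells))
    # place cells on a jittered grid so bodies never touch
    pitch = 100
    nx = max(1, w // pitch)
    slots = [( (i % nx) * pitch + pitch // 2,
               (i // nx) * pitch + pitch // 2) for i in range(cfg.n_cells)]
    if slots and (slots[-1][1] + pitch // 2) > h:
        raise ValueError("too many cells for the image size")

    records = []
    for cid, (cx, cy) in enumerate(slots, start=1):
        orphan = cid > cfg.n_cells - n_orphans
        scale = max(0.3, 1.0 + cfg.size_jitter * rng.normal()) \
            if cfg.size_jitter > 0 else 1.0
        if not orphan:
            ox, oy = _body_polygon(cfg.archetype, scale, cfg.n_protrusions, rng)
            rr, cc = polygon(cy + oy, cx + ox, shape=(h, w))
            cell[rr, cc] = cid
        else:
            rng.uniform(0, 2 * math.pi)  # keep the stream aligned
        yy, xx = np.mgrid[0:h, 0:w][:,
                 max(0, cy - 10):cy + 11, max(0, cx - 10):cx + 11]
        rr = (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.nucleus_radius_px ** 2
        sub = nuc[max(0, cy - 10):cy + 11, max(0, cx - 10):cx + 11]
        sub[rr] = cid
        records.append({
            "cell_id": cid, "archetype": cfg.archetype,
            "n_spikes": cfg.n_protrusions if cfg.archetype == "spiky" and not orphan else 0,
            "has_body": not orphan,
        })

    truth = pd.DataFrame(records, columns=["cell_id", "archetype",
                                           "n_spikes", "has_body"])
    return MorphologyScene(nucleus_mask=nuc, cell_mask=cell, truth=truth)
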