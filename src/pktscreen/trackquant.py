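"""Quantify migratory tracks from PKT montages.

Pipeline: segment bead-free regions -> count cell bodies per region ->
accept single-cell tracks -> measure eight morphometric parameters.
Tracks without a cell or with more than one cell are excluded, matching
the screen's acceptance rule.

Segmentation works on the bead texture: dark pixels (beads and cells)
are thresholded, their local area fraction is computed in a sliding
window, and near-zero-fraction cores mark bead-free clearings; cores are
dilated back to recover the track boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .datatypes import TrackFeatures, Treatment, WellRecord, FEATURE_COLUMNS

__all__ = [
    "SegmentationConfig", "segment_tracks", "detect_cell_bodies",
    "accept_tracks", "measure_track", "quantify_well", "well_record_to_frame",
]


@dataclass(frozen=True)
class SegmentationConfig:
    dark_rel_threshold: float = 0.6    # dark if below this fraction of the image median
    cell_rel_threshold: float = 0.25   # cell-body pixels are much darker than beads
    window_px: int = 15                # sliding window for the bead-fraction map
    clear_fraction: float = 0.05       # bead-free if local dark fraction below this
    dilation_px: int = 5               # boundary recovery after core detection
    min_area_px: int = 50              # region area floor (speckle suppression)
    min_cell_area_px: int = 60         # compact dark blob floor for a cell body
    exclude_border: bool = True
    min_dark_fraction: float = 1e-3    # below this the image is blank/saturated


def _disk(radius: int) -> np.ndarray:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (dx ** 2 + dy ** 2) <= radius ** 2


def _dark_mask(image: np.ndarray, rel: float) -> tuple[np.ndarray, float]:
    med = float(np.median(image))
    return image < rel * med, med


def segment_tracks(
    montage: np.ndarray,
    config: SegmentationConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Label bead-free track regions in a single-channel montage.

    Returns
    -------
    labels : int ndarray, 0 = bead lawn
    warnings : list of QC warning strings (blank/saturated input, etc.)
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(montage)
    if img.ndim != 2:
        raise ValueError("montage must be a single-channel 2-D image")
    warnings: list[str] = []

    dark, med = _dark_mask(img, cfg.dark_rel_threshold)
    if med <= 0 or dark.mean() < cfg.min_dark_fraction:
        warnings.append("blank-or-saturated-image")
        return np.zeros(img.shape, dtype=np.int32), warnings

    # cell bodies (far darker than the bead tone) sit inside cleared
    # tracks and must not count as bead texture
    cells = img < cfg.cell_rel_threshold * med
    beads = dark & ~ndimage.binary_dilation(cells, structure=_disk(2))

    frac = ndimage.uniform_filter(beads.astype(float), size=cfg.window_px,
                                  mode="reflect")
    core = frac < cfg.clear_fraction
    cleared = ndimage.binary_dilation(core, structure=_disk(cfg.dilation_px))
    cleared = ndimage.binary_fill_holes(cleared)

    labels, n = ndimage.label(cleared, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32), warnings

    # drop small regions and (by default) border-touching ones
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep[areas < cfg.min_area_px] = False
    if cfg.exclude_border:
        border = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        keep[border[border > 0]] = False
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, int(keep.sum()) + 1)
    return relabel[labels], warnings


def detect_cell_bodies(
    montage: np.ndarray,
    labels: np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Count dark compact blobs (cell bodies) inside each labeled region.

    A cell body is a connected component of very dark pixels (well below
    bead intensity) of at least ``min_cell_area_px`` whose pixels lie in
    the region's interior (3-px erosion keeps boundary bead clusters out).
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(montage)
    n_regions = int(labels.max())
    counts = np.zeros(n_regions, dtype=int)
    if n_regions == 0:
        return counts

    med = float(np.median(img))
    cells = img < cfg.cell_rel_threshold * med
    blob_labels, n_blobs = ndimage.label(cells, structure=np.ones((3, 3), dtype=int))
    if n_blobs == 0:
        return counts
    interior = ndimage.binary_erosion(labels > 0, structure=_disk(3))
    for b in range(1, n_blobs + 1):
        sel = blob_labels == b
        if sel.sum() < cfg.min_cell_area_px:
            continue
        inside = sel & interior
        if not inside.any():
            continue
        region_ids, freq = np.unique(labels[inside], return_counts=True)
        rid = int(region_ids[np.argmax(freq)])
        if rid > 0:
            counts[rid - 1] += 1
    return counts


def accept_tracks(labels: np.ndarray, cell_counts: np.ndarray
                  ) -> tuple[np.ndarray, int]:
    """Keep exactly the regions containing one cell; report n_rejected."""
    n_regions = int(labels.max())
    cell_counts = np.asarray(cell_counts)
    if cell_counts.shape[0] != n_regions:
        raise ValueError(
            f"cell_counts has {cell_counts.shape[0]} entries for "
            f"{n_regions} regions")
    keep = cell_counts == 1
    relabel = np.zeros(n_regions + 1, dtype=np.int32)
    relabel[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    return relabel[labels], int((~keep).sum())


def measure_track(mask: np.ndarray) -> TrackFeatures:
    """Measure the eight morphometric parameters of one track mask.

    net_area    cleared-pixel count
    gross_area  convex-hull area
    major/minor ellipse-equivalent axes from second central moments
    axial_ratio major / minor (minor floored at 1 px: a region is at
                least one pixel wide)
    roughness   perimeter^2 / (4 pi net_area), = 1 for a disc
    perimeter   Crofton estimate (4 directions)
    solidity    net_area / gross_area
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    net = float(props.area)
    gross = float(props.area_convex)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    minor = max(minor, 1.0)
    major = max(major, minor)
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    roughness = max(1.0, perimeter ** 2 / (4.0 * math.pi * net))
    return TrackFeatures(
        net_area=net,
        gross_area=max(gross, net),
        major_axis=major,
        minor_axis=minor,
        axial_ratio=major / minor,
        roughness=roughness,
        perimeter=perimeter,
        solidity=min(1.0, net / max(gross, net)),
    )


def quantify_well(
    montage: np.ndarray,
    plate_id: str = "",
    well_id: str = "",
    treatment: Treatment | None = None,
    n_images: int = 36,
    config: SegmentationConfig | None = None,
) -> WellRecord:
    """Full per-well pipeline: segment -> detect -> accept -> measure."""
    labels, warnings = segment_tracks(montage, config)
    counts = detect_cell_bodies(montage, labels, config)
    accepted, n_rejected = accept_tracks(labels, counts)
    tracks = []
    for rid in range(1, int(accepted.max()) + 1):
        tracks.append(measure_track(accepted == rid))
    return WellRecord(plate_id=plate_id, well_id=well_id, tracks=tracks,
                      n_rejected=n_rejected, n_images=n_images,
                      treatment=treatment, qc_warnings=warnings)


def well_record_to_frame(record: WellRecord) -> pd.DataFrame:
    """Track-level feature table of one well (CSV schema)."""
    rows = []
    for i, t in enumerate(record.tracks, start=1):
        row = {"plate_id": record.plate_id, "well_id": record.well_id,
               "track_id": i, **t.as_row(), "n_cells_in_track": 1}
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
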