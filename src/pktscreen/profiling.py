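"""Single-cell morphology quantification and knockdown-level clustering.

Per cell (nucleus + actin body masks) the module measures CellProfiler
style size/shape features plus a protrusion ("spike") count from
convexity defects.  Per knockdown, features are summarized as log2 fold
changes of the well median against the plate's two pooled mock wells,
and knockdown profiles are grouped by agglomerative clustering with
Euclidean distance and complete linkage.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy
from skimage import measure

from .datatypes import CellMorphology

__all__ = [
    "measure_cell_morphology", "count_spikes", "filter_images",
    "profile_knockdown", "cluster_profiles", "linkage_to_newick",
    "MORPHOLOGY_FEATURES",
]

#: default feature set entering the knockdown profiles
MORPHOLOGY_FEATURES = ["area", "perimeter", "form_factor",
                       "spike_count", "nucleus_area"]


def _disk(radius: int) -> np.ndarray:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (dx ** 2 + dy ** 2) <= radius ** 2


def count_spikes(mask: np.ndarray, depth_min: float = 5.0,
                 width_max: float = 30.0) -> int:
    """Count protrusions ("spikes") of a cell mask.

    The cell core is the morphological opening of the mask with a disk
    of diameter ``width_max``: anything thinner than that is a candidate
    protrusion.  Each connected residual component reaching at least
    ``depth_min`` pixels beyond the core counts as one spike.  A smooth
    convex body has no residuals and scores zero.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 8:
        return 0
    props = measure.regionprops(mask.astype(np.uint8))[0]
    r0, c0, r1, c1 = props.bbox
    pad = int(width_max) + 2
    sub = np.pad(mask[r0:r1, c0:c1], pad)
    core = ndimage.binary_opening(sub, structure=_disk(int(round(width_max / 2))))
    if not core.any():
        return 0
    resid = sub & ~core
    if not resid.any():
        return 0
    depth_from_core = ndimage.distance_transform_edt(~core)
    lab, n = ndimage.label(resid, structure=np.ones((3, 3), dtype=int))
    count = 0
    for i in range(1, n + 1):
        if float(depth_from_core[lab == i].max()) >= depth_min:
            count += 1
    return count


def measure_cell_morphology(
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    depth_min: float = 5.0,
    width_max: float = 30.0,
) -> list[CellMorphology]:
    """Measure size/shape features per nucleus.

    Nuclei are the primary objects; each nucleus is assigned the cell
    body containing its centroid.  Nuclei without a clear cell body are
    flagged (``has_cell_body=False``) for downstream rejection.  Cell
    bodies without any nucleus are ignored.
    """
    nucleus_mask = np.asarray(nucleus_mask)
    cell_mask = np.asarray(cell_mask)
    if nucleus_mask.shape != cell_mask.shape:
        raise ValueError("masks must be aligned (same shape)")
    records: list[CellMorphology] = []
    cell_props = {p.label: p for p in measure.regionprops(cell_mask)}
    for npr in measure.regionprops(nucleus_mask):
        cy, cx = npr.centroid
        body_label = int(cell_mask[int(round(cy)), int(round(cx))])
        if body_label == 0:
            records.append(CellMorphology(
                cell_id=int(npr.label), area=0.0, perimeter=0.0,
                form_factor=0.0, spike_count=0,
                nucleus_area=float(npr.area), has_cell_body=False))
            continue
        bp = cell_props[body_label]
        perim = float(measure.perimeter_crofton(bp.image, directions=4))
        area = float(bp.area)
        ff = min(1.0, 4.0 * math.pi * area / perim ** 2) if perim > 0 else 1.0
        spikes = count_spikes(cell_mask == body_label,
                              depth_min=depth_min, width_max=width_max)
        records.append(CellMorphology(
            cell_id=int(npr.label), area=area, perimeter=perim,
            form_factor=ff, spike_count=spikes,
            nucleus_area=float(npr.area), has_cell_body=True))
    return records


def filter_images(cell_counts: Sequence[int], max_cells: int = 150) -> list[int]:
    """Indices of retained images (those with <= ``max_cells`` cells)."""
    return [i for i, c in enumerate(cell_counts) if c <= max_cells]


def records_to_frame(records: Sequence[CellMorphology]) -> pd.DataFrame:
    rows = [{"cell_id": r.cell_id, "area": r.area, "perimeter": r.perimeter,
             "form_factor": r.form_factor, "spike_count": r.spike_count,
             "nucleus_area": r.nucleus_area, "has_cell_body": r.has_cell_body}
            for r in records]
    return pd.DataFrame(rows, columns=["cell_id", "area", "perimeter",
                                       "form_factor", "spike_count",
                                       "nucleus_area", "has_cell_body"])


def profile_knockdown(
    cells: pd.DataFrame,
    mock_wells: Sequence[pd.DataFrame],
    features: Sequence[str] = MORPHOLOGY_FEATURES,
    floor: float = 0.25,
) -> pd.Series:
    """Per-feature log2 fold change of well medians versus pooled mock.

    ``mock_wells`` are the plate's mock-control cell tables (>= 2
    required); their cells are pooled before taking medians.  Orphan
    nuclei (no cell body) are rejected on both sides.  Zero medians are
    floored at ``floor`` so count-valued features stay finite.
    """
    if len(mock_wells) < 2:
        raise ValueError(">= 2 mock control wells per plate are required")
    mock = pd.concat(list(mock_wells), ignore_index=True)
    if "has_cell_body" in mock:
        mock = mock[mock["has_cell_body"]]
    kd = cells[cells["has_cell_body"]] if "has_cell_body" in cells else cells
    out = {}
    for f in features:
        m_kd = max(float(kd[f].median()), floor)
        m_mock = max(float(mock[f].median()), floor)
        out[f] = math.log2(m_kd / m_mock)
    return pd.Series(out, name="log2fc")


def cluster_profiles(profiles: pd.DataFrame, n_clusters: int | None = None
                     ) -> tuple[np.ndarray, pd.Series | None]:
    """Complete-linkage Euclidean clustering of knockdown profiles.

    Returns the scipy linkage matrix and, when ``n_clusters`` is given,
    flat cluster labels (1..k) indexed like ``profiles``.
    """
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values")
    n = profiles.shape[0]
    if n < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if n_clusters is not None and n_clusters > n:
        raise ValueError("more clusters requested than profiles")
    z = hierarchy.linkage(profiles.values, method="complete",
                          metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = pd.Series(
            hierarchy.fcluster(z, t=n_clusters, criterion="maxclust"),
            index=profiles.index, name="cluster")
    return z, labels


def linkage_to_newick(z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(leaf_names)
    if z.shape[0] != n - 1:
        raise ValueError("linkage size does not match leaf count")

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return str(leaf_names[i]), 0.0
        a, b, h, _ = z[i - n]
        sa, ha = node(int(a))
        sb, hb = node(int(b))
        return (f"({sa}:{h / 2 - ha:.6g},{sb}:{h / 2 - hb:.6g})", h / 2)

    s, _ = node(2 * n - 2)
    return s + ";"
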