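"""Single-cell segmentation, overlap tracking and the dual-control test.

Cells in GFP time-lapse stacks are segmented per frame (threshold +
watershed split of touching blobs) and linked between consecutive frames
by greatest pixel overlap.  Trajectories shorter than 2 h are discarded.
Knockdown speed distributions are compared against *two* negative
control wells (low and high density) with a Kruskal-Wallis test followed
by Dunn's post test; a knockdown counts as significant only when it
differs from both controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import feature, filters, measure, segmentation

from .datatypes import MigrationStats, Trajectory

__all__ = [
    "segment_cells_frame", "link_by_overlap", "build_trajectories",
    "track_movie", "trajectory_stats", "median_ci",
    "dunn_test", "compare_to_controls", "DualControlResult",
]


def segment_cells_frame(frame: np.ndarray, min_area_px: int = 20,
                        sigma: float = 1.0, min_distance_px: int = 15
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Segment one fluorescence frame into cell masks.

    Returns (label image, (n, 2) centroid array in (x, y) pixel order).
    Touching blobs are split by a watershed seeded at distance-transform
    maxima.  A blank frame yields zero cells.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be single-channel")
    smooth = ndimage.gaussian_filter(img, sigma)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-9:
        return np.zeros(img.shape, dtype=np.int32), np.empty((0, 2))
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    # reject contrast-free frames where otsu splits pure noise
    if smooth[mask].mean() - smooth[~mask].mean() < 6 * smooth[~mask].std():
        return np.zeros(img.shape, dtype=np.int32), np.empty((0, 2))
    mask = ndimage.binary_opening(mask, np.ones((3, 3), dtype=bool))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), np.empty((0, 2))
    dist = ndimage.distance_transform_edt(mask)
    peaks = feature.peak_local_max(dist, min_distance=min_distance_px,
                                   labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask)
    else:
        labels = segmentation.watershed(-dist, markers, mask=mask)
    # filter small fragments, relabel consecutively
    out = np.zeros(img.shape, dtype=np.int32)
    centroids = []
    nxt = 1
    for p in measure.regionprops(labels):
        if p.area < min_area_px:
            continue
        out[labels == p.label] = nxt
        cy, cx = p.centroid
        centroids.append((cx, cy))
        nxt += 1
    return out, np.asarray(centroids).reshape(-1, 2)


def link_by_overlap(labels_a: np.ndarray, labels_b: np.ndarray,
                    min_overlap_px: int = 1) -> dict[int, int]:
    """Greedy one-to-one matching of consecutive-frame masks by overlap.

    Pairs are taken in order of decreasing pixel overlap; overlaps below
    ``min_overlap_px`` never link.  Returns {label_a: label_b}.
    """
    na, nb = int(labels_a.max()), int(labels_b.max())
    if na == 0 or nb == 0:
        return {}
    joint = labels_a.astype(np.int64) * (nb + 1) + labels_b.astype(np.int64)
    counts = np.bincount(joint.ravel(), minlength=(na + 1) * (nb + 1))
    overlap = counts.reshape(na + 1, nb + 1)[1:, 1:]
    pairs = np.argwhere(overlap >= min_overlap_px)
    order = np.argsort(-overlap[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_a, used_b, match = set(), set(), {}
    for i, j in pairs[order]:
        if i in used_a or j in used_b:
            continue
        match[int(i) + 1] = int(j) + 1
        used_a.add(i)
        used_b.add(j)
    return match


def build_trajectories(
    frame_labels: list[np.ndarray],
    centroids: list[np.ndarray],
    dt: float = 12.0,
    min_duration: float = 120.0,
    um_per_px: float = 1.0,
    min_overlap_px: int = 1,
) -> list[Trajectory]:
    """Chain per-frame masks into trajectories; drop tracks shorter than 2 h.

    Gaps are not bridged: a missed detection terminates the track and any
    reappearance starts a new one.  With dt = 12 min the 2-h minimum
    keeps chains of >= 11 samples.
    """
    n_frames = len(frame_labels)
    if n_frames != len(centroids):
        raise ValueError("frame_labels and centroids length mismatch")
    chains: dict[int, list[tuple[int, int]]] = {}   # cell_id -> [(frame, label)]
    active: dict[int, int] = {}                     # label in current frame -> cell_id
    next_id = 0
    for f in range(n_frames):
        if f == 0:
            match = {}
        else:
            match = link_by_overlap(frame_labels[f - 1], frame_labels[f],
                                    min_overlap_px=min_overlap_px)
        new_active: dict[int, int] = {}
        matched_b = set()
        for la, cid in active.items():
            lb = match.get(la)
            if lb is not None:
                new_active[lb] = cid
                chains[cid].append((f, lb))
                matched_b.add(lb)
        for lb in range(1, int(frame_labels[f].max()) + 1):
            if lb not in matched_b and lb not in new_active:
                chains[next_id] = [(f, lb)]
                new_active[lb] = next_id
                next_id += 1
        active = new_active

    out = []
    for cid in sorted(chains):
        chain = chains[cid]
        if len(chain) < 2 or (len(chain) - 1) * dt < min_duration:
            continue
        samples = np.array([
            (f * dt,
             centroids[f][lb - 1, 0] * um_per_px,
             centroids[f][lb - 1, 1] * um_per_px)
            for f, lb in chain])
        out.append(Trajectory(cell_id=cid, samples=samples))
    return out


def track_movie(stack: np.ndarray, dt: float = 12.0,
                min_duration: float = 120.0, um_per_px: float = 1.0,
                min_overlap_px: int = 1, **seg_kwargs) -> list[Trajectory]:
    """Segment and link a whole (n_frames, H, W) stack."""
    frame_labels, cents = [], []
    for frame in stack:
        lab, c = segment_cells_frame(frame, **seg_kwargs)
        frame_labels.append(lab)
        cents.append(c)
    return build_trajectories(frame_labels, cents, dt=dt,
                              min_duration=min_duration,
                              um_per_px=um_per_px,
                              min_overlap_px=min_overlap_px)


def trajectory_stats(traj: Trajectory) -> MigrationStats:
    """Per-cell speed, displacement, path length and directionality."""
    xy = traj.samples[:, 1:]
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    disp = float(np.linalg.norm(xy[-1] - xy[0]))
    speed = path / traj.duration
    directionality = disp / path if path > 0 else 0.0
    return MigrationStats(cell_id=traj.cell_id, speed=speed,
                          displacement=disp, path_length=path,
                          directionality=directionality,
                          duration=traj.duration, n_samples=traj.n_samples)


def median_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI of the median from binomial order statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n == 0:
        return (math.nan, math.nan)
    if n == 1:
        return (x[0], x[0])
    alpha = 1 - level
    lo = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, 0.5))
    return (float(x[max(0, lo)]), float(x[min(n - 1, hi)]))


def dunn_test(groups: list[np.ndarray]) -> np.ndarray:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    Returns the symmetric matrix of Bonferroni-adjusted two-sided
    p-values over all pairwise comparisons (classical Dunn's correction
    for k groups: multiply by k(k-1)/2).  Tie-corrected.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1))) \
        if n > 1 else 0.0
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        ng = len(g)
        mean_ranks.append(ranks[start:start + ng].mean())
        sizes.append(ng)
        start += ng
    m = k * (k - 1) // 2
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt((n * (n + 1) / 12.0 - ties)
                           * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pij = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            p[i, j] = p[j, i] = pij
    return p


@dataclass
class DualControlResult:
    """Verdict of the knockdown-vs-two-controls comparison."""

    significant: bool
    direction: int                  # -1 slower, +1 faster, 0 none
    kruskal_p: float
    p_vs_low: float
    p_vs_high: float
    medians: dict[str, float]
    median_cis: dict[str, tuple[float, float]]
    reason: str = ""

    def summary(self) -> str:
        lines = ["dual-control migration comparison",
                 f"  Kruskal-Wallis p = {self.kruskal_p:.3g}",
                 f"  vs control_low  p = {self.p_vs_low:.3g}",
                 f"  vs control_high p = {self.p_vs_high:.3g}"]
        for name, med in self.medians.items():
            lo, hi = self.median_cis[name]
            lines.append(f"  median {name:<13} {med:.3f}  [{lo:.3f}, {hi:.3f}]")
        verdict = ("significant "
                   + ("decrease" if self.direction < 0 else "increase")
                   if self.significant else "not significant")
        if self.reason:
            verdict += f" ({self.reason})"
        lines.append(f"  verdict: {verdict}")
        return "\n".join(lines)


def compare_to_controls(
    knockdown: np.ndarray,
    control_low: np.ndarray,
    control_high: np.ndarray,
    alpha: float = 0.05,
    min_group: int = 5,
) -> DualControlResult:
    """Kruskal-Wallis + Dunn's post test against both control wells.

    Significant iff the omnibus test rejects and the knockdown differs
    from *both* controls at ``alpha`` (Dunn, Bonferroni-adjusted).
    Effect direction is the sign of the knockdown-median difference
    against the controls' pooled median.
    """
    groups = {"knockdown": np.asarray(knockdown, dtype=float),
              "control_low": np.asarray(control_low, dtype=float),
              "control_high": np.asarray(control_high, dtype=float)}
    medians = {k: float(np.median(v)) if len(v) else math.nan
               for k, v in groups.items()}
    cis = {k: median_ci(v) for k, v in groups.items()}
    small = [k for k, v in groups.items() if len(v) < min_group]
    if small:
        return DualControlResult(
            significant=False, direction=0, kruskal_p=math.nan,
            p_vs_low=math.nan, p_vs_high=math.nan, medians=medians,
            median_cis=cis,
            reason=f"inconclusive: group(s) below n={min_group}: {small}")
    vals = [groups["knockdown"], groups["control_low"], groups["control_high"]]
    try:
        kw_stat, kw_p = stats.kruskal(*vals)
    except ValueError:      # all values identical
        kw_p = 1.0
    p = dunn_test(vals)
    p_lo, p_hi = float(p[0, 1]), float(p[0, 2])
    significant = (kw_p < alpha) and (p_lo < alpha) and (p_hi < alpha)
    ctrl_med = float(np.median(np.concatenate(vals[1:])))
    diff = medians["knockdown"] - ctrl_med
    direction = int(np.sign(diff)) if significant else 0
    return DualControlResult(
        significant=bool(significant), direction=direction,
        kruskal_p=float(kw_p), p_vs_low=p_lo, p_vs_high=p_hi,
        medians=medians, median_cis=cis)
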