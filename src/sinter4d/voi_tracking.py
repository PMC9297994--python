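"""Detection and time-tracking of strut-slice volumes of interest (VOIs).

On each quarter-resampled volume the chain is: a trained slice classifier
flags the z-slices that show clean strut cross-sections; a region-based
level set segments those cross-sections; 26-connected 3D labeling of the
stacked masks yields one component per strut segment, whose unweighted
centroid becomes the VOI center; centers are mapped back to full-resolution
coordinates and fixed-size VOIs are extracted there. Across consecutive
time points, centers are linked by a minimum-total-Euclidean-distance
assignment with a displacement cap, and the links are chained into 4D
hyperstacks (one tracked VOI's sub-volumes over the whole series).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_core import ScanVolume, warn_once
from .segmentation import chan_vese_mask

N_HIST_BINS = 32


# ---------------------------------------------------------------------------
# slice classifier
# ---------------------------------------------------------------------------

def slice_feature_vector(sl: np.ndarray) -> np.ndarray:
    """Resolution-independent per-slice features.

    Normalized 32-bin intensity histogram, foreground fraction after Otsu,
    mean, standard deviation and Shannon entropy of the histogram (36
    values in total).
    """
    sl = np.asarray(sl)
    flat = sl.ravel().astype(np.float64)
    hist, _ = np.histogram(flat, bins=N_HIST_BINS, range=(0, 256))
    p = hist / max(flat.size, 1)
    if flat.min() == flat.max():
        fg_frac = 0.0
    else:
        fg_frac = float((sl > filters.threshold_otsu(sl, nbins=256)).mean())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.concatenate([p, [fg_frac, flat.mean() / 255.0, flat.std() / 255.0, entropy]])


@dataclass
class SliceClassifier:
    """Binary decision function over per-slice feature vectors."""

    model: Pipeline
    feature_recipe: str = "hist32+otsu_frac+mean+std+entropy"
    n_positive: int = 0
    n_negative: int = 0
    seed: int = 0

    def predict(self, feature_matrix: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(feature_matrix)).astype(bool)


def train_slice_classifier(
    labeled_slices: list[tuple[np.ndarray, int]], seed: int = 0
) -> SliceClassifier:
    """Fit the VOI-slice vs background SVM (RBF kernel, standardized input).

    ``labeled_slices`` pairs each 2D slice with 1 (contains VOIs) or 0
    (background). Training is order-independent and reproducible for a
    fixed seed.
    """
    if len(labeled_slices) < 4:
        raise ValueError("need at least 2 examples per class")
    X = np.stack([slice_feature_vector(sl) for sl, _ in labeled_slices])
    y = np.array([int(lbl) for _, lbl in labeled_slices])
    # canonical sample order so shuffled input yields the identical fit
    order = np.lexsort(X.T)
    X, y = X[order], y[order]
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed)),
        ]
    )
    model.fit(X, y)
    return SliceClassifier(
        model=model,
        n_positive=int((y == 1).sum()),
        n_negative=int((y == 0).sum()),
        seed=seed,
    )


def _filter_runs(flags: np.ndarray, min_run: int, max_gap: int, edge_trim: int = 0) -> np.ndarray:
    """Close gaps <= max_gap, trim run edges, then drop runs < min_run.

    ``edge_trim`` removes that many slices from both ends of every run:
    the classifier is least reliable right at the transition out of a
    strut-crossing region, and a single contaminated edge slice can fuse
    neighboring strut segments during 3D labeling.
    """
    out = flags.astype(bool).copy()
    if max_gap > 0:
        out = ndimage.binary_closing(out, structure=np.ones(max_gap + 2, bool))
    if edge_trim > 0:
        out = ndimage.binary_erosion(out, structure=np.ones(2 * edge_trim + 1, bool))
    lab, n = ndimage.label(out)
    for i in range(1, n + 1):
        if int((lab == i).sum()) < min_run:
            out[lab == i] = False
    return out


def classify_slices(
    volume_coarse: ScanVolume,
    clf: SliceClassifier,
    min_run: int = 3,
    max_gap: int = 2,
    edge_trim: int = 2,
) -> np.ndarray:
    """Predicted z indices containing VOIs, post-processed into runs.

    Isolated positives shorter than ``min_run`` slices are removed, gaps up
    to ``max_gap`` slices inside runs are filled, and ``edge_trim`` slices
    are shaved off both run ends (where lingering strut-crossing content
    would corrupt the region masks), suppressing misclassifications.
    """
    vox = volume_coarse.voxels
    X = np.stack([slice_feature_vector(vox[z]) for z in range(vox.shape[0])])
    flags = clf.predict(X)
    flags = _filter_runs(flags, min_run=min_run, max_gap=max_gap, edge_trim=edge_trim)
    return np.flatnonzero(flags)


# ---------------------------------------------------------------------------
# region segmentation, labeling, centers
# ---------------------------------------------------------------------------

def segment_strut_regions_2d(slice_2d: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Binary mask of strut cross-section regions in one flagged slice.

    A region-based (piecewise-constant) level set is evolved to
    convergence; a blank slice yields an empty mask.
    """
    return chan_vese_mask(slice_2d, max_iter=max_iter)


def label_and_center_3d(
    region_mask_3d: np.ndarray, min_size: int = 500
) -> list[tuple[int, tuple[float, float, float], int]]:
    """26-connected components with unweighted voxel centroids.

    Components smaller than ``min_size`` voxels are discarded. Returns
    ``(label, center_zyx, voxel_count)`` per surviving component; an empty
    mask yields an empty list.
    """
    mask = np.asarray(region_mask_3d, dtype=bool)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=3)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_size:
            continue
        cz, cy, cx = region.centroid
        out.append((int(region.label), (float(cz), float(cy), float(cx)), int(region.area)))
    return out


def upscale_centers(
    centers_coarse: list[tuple[float, float, float]], factor: float, round_to_int: bool = True
) -> list[tuple[float, float, float]]:
    """Convert resampled-volume coordinates back to full resolution.

    Each coordinate is divided by the resampling factor; by default the
    result is rounded to the nearest integer voxel.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0; got {factor}")
    out = []
    for c in centers_coarse:
        full = tuple(v / factor for v in c)
        if round_to_int:
            full = tuple(float(np.floor(v + 0.5)) for v in full)
        out.append(full)
    return out


def extract_voi(
    volume_full: ScanVolume | np.ndarray,
    center: tuple[float, float, float],
    extents: tuple[int, int, int],
) -> tuple[np.ndarray, bool]:
    """Fixed-size box centered on a coordinate, zero-padded at borders.

    Returns ``(sub_volume, clipped)`` where ``clipped`` flags that part of
    the requested box fell outside the volume and was zero-filled.
    """
    vox = volume_full.voxels if isinstance(volume_full, ScanVolume) else np.asarray(volume_full)
    center_i = tuple(int(np.floor(c + 0.5)) for c in center)
    for ax in range(3):
        if not (0 <= center_i[ax] < vox.shape[ax]):
            raise ValueError(f"center {center} outside volume of shape {vox.shape}")
    out = np.zeros(tuple(extents), dtype=vox.dtype)
    clipped = False
    src, dst = [], []
    for ax in range(3):
        start = center_i[ax] - extents[ax] // 2
        stop = start + extents[ax]
        s0, s1 = max(start, 0), min(stop, vox.shape[ax])
        if s0 > start or s1 < stop:
            clipped = True
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start, s1 - start))
    out[tuple(dst)] = vox[tuple(src)]
    return out, clipped


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _padded_cost(
    centers_t: np.ndarray, centers_t1: np.ndarray, max_displacement: float
) -> tuple[np.ndarray, float]:
    n, m = len(centers_t), len(centers_t1)
    k = max(n, m)
    dist = np.linalg.norm(centers_t[:, None, :] - centers_t1[None, :, :], axis=-1)
    big = max_displacement * (k + 1) + 1.0
    cost = np.full((k, k), big)
    allowed = dist <= max_displacement
    cost[:n, :m][allowed] = dist[allowed]
    return cost, big


def track_centers(
    centers_t: list[tuple[float, float, float]],
    centers_t1: list[tuple[float, float, float]],
    max_displacement: float = 20.0,
) -> list[tuple[int, int]]:
    """Link centers of consecutive time points.

    The result is the partial bijection that maximizes the number of pairs
    within ``max_displacement`` and, among those, minimizes the total
    Euclidean distance (solved exactly as a linear assignment on a padded
    cost matrix). Unmatched centers are simply absent from the pair list.
    """
    if not centers_t or not centers_t1:
        return []
    a = np.asarray(centers_t, dtype=float)
    b = np.asarray(centers_t1, dtype=float)
    cost, big = _padded_cost(a, b, max_displacement)
    rows, cols = optimize.linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < len(a) and j < len(b) and cost[i, j] < big
    ]
    return sorted(pairs)


def track_centers_bruteforce(
    centers_t: list[tuple[float, float, float]],
    centers_t1: list[tuple[float, float, float]],
    max_displacement: float = 20.0,
) -> list[tuple[int, int]]:
    """Exhaustive-enumeration oracle for :func:`track_centers` (small n).

    Enumerates all permutations of the padded cost matrix and returns the
    minimum-total-cost matching under the same objective. Only intended for
    instances with at most ~8 centers.
    """
    if not centers_t or not centers_t1:
        return []
    a = np.asarray(centers_t, dtype=float)
    b = np.asarray(centers_t1, dtype=float)
    if max(len(a), len(b)) > 8:
        raise ValueError("brute-force oracle limited to <= 8 centers")
    k = max(len(a), len(b))
    penalty = max_displacement * (k + 1) + 1.0
    best_key, best_pairs = None, []
    for perm in permutations(range(k)):
        pairs, total = [], 0.0
        for i, j in enumerate(perm):
            if i < len(a) and j < len(b):
                d = float(np.linalg.norm(a[i] - b[j]))
                if d <= max_displacement:
                    pairs.append((i, j))
                    total += d
                    continue
            total += penalty
        key = (total,)
        if best_key is None or key < best_key:
            best_key, best_pairs = key, pairs
    return sorted(best_pairs)


# ---------------------------------------------------------------------------
# VOI records and hyperstacks
# ---------------------------------------------------------------------------

DEFAULT_EXTENTS = {
    "parent": (70, 330, 306),
    "densification_child": (70, 150, 140),
    "diameter_child": (10, 330, 306),
}
"""Default VOI extents (z, y, x) for full-scale scans at 0.81 um/voxel:
the detected parent VOI, the interior child used for densification, and
the thin child used for diameter measurement."""


@dataclass
class VOIRecord:
    """One detected strut-slice VOI at one time point."""

    label: int
    center_zyx_full: tuple[float, float, float]
    center_zyx_coarse: tuple[float, float, float]
    time_index: int
    extents: tuple[int, int, int]
    voxel_count_coarse: int = 0
    clipped: bool = False


@dataclass
class Hyperstack:
    """Time-ordered sub-volumes of one tracked VOI (the 4D object)."""

    voi_track_id: int
    entries: list[tuple[int, VOIRecord, np.ndarray | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.entries]
        if times != sorted(set(times)):
            raise ValueError("time indices must be strictly increasing and unique")

    def append(self, time_index: int, record: VOIRecord, sub_volume: np.ndarray | None) -> None:
        if self.entries and time_index <= self.entries[-1][0]:
            raise ValueError("time indices must be strictly increasing")
        self.entries.append((time_index, record, sub_volume))

    @property
    def time_indices(self) -> list[int]:
        return [t for t, _, _ in self.entries]

    def centers(self) -> np.ndarray:
        return np.array([rec.center_zyx_full for _, rec, _ in self.entries])


class IncrementalTracker:
    """Chain per-time center lists into persistent tracks.

    Feed time points in order with :meth:`update`; each track keeps the
    indices of its matched center per time point. A track that finds no
    match at some time point simply has a gap there (kept, with a warning
    at assembly time).
    """

    def __init__(self, max_displacement: float = 20.0):
        self.max_displacement = max_displacement
        self.track_last_center: list[tuple[float, float, float]] = []
        self.track_entries: list[dict[int, int]] = []  # track -> {time_index: center index}

    def update(self, time_index: int, centers: list[tuple[float, float, float]]) -> None:
        if not self.track_last_center:
            for i, c in enumerate(centers):
                self.track_last_center.append(c)
                self.track_entries.append({time_index: i})
            return
        pairs = track_centers(self.track_last_center, centers, self.max_displacement)
        matched_new = set()
        for ti, ci in pairs:
            self.track_last_center[ti] = centers[ci]
            self.track_entries[ti][time_index] = ci
            matched_new.add(ci)
        for ci, c in enumerate(centers):
            if ci not in matched_new:
                self.track_last_center.append(c)
                self.track_entries.append({time_index: ci})

    @property
    def n_tracks(self) -> int:
        return len(self.track_entries)


def select_tracks_near_centroid(
    tracker: IncrementalTracker,
    first_centers: list[tuple[float, float, float]],
    n_select: int | None,
) -> list[int]:
    """Deterministic analysed-subset rule: tracks closest to the scaffold centroid.

    The centroid is the mean of all first-time-point centers; tracks
    present at the first time point are ranked by their distance to it.
    """
    pts = np.asarray(first_centers, dtype=float)
    centroid = pts.mean(axis=0)
    first_time = min(min(e) for e in tracker.track_entries if e)
    candidates = [
        (float(np.linalg.norm(pts[entries[first_time]] - centroid)), tid)
        for tid, entries in enumerate(tracker.track_entries)
        if entries and min(entries) == first_time
    ]
    candidates.sort()
    if n_select is None:
        return [tid for _, tid in candidates]
    return [tid for _, tid in candidates[:n_select]]


def build_hyperstacks(
    per_time_centers: list[list[tuple[float, float, float]]],
    per_time_records: list[list[VOIRecord]],
    n_select: int | None = 3,
    max_displacement: float = 20.0,
    volumes: list[ScanVolume] | None = None,
    extents: tuple[int, int, int] | None = None,
) -> list[Hyperstack]:
    """Assemble hyperstacks from tracked VOIs across all time points.

    ``per_time_centers[t][i]`` is the full-resolution center of record
    ``per_time_records[t][i]``. The ``n_select`` tracks whose first centers
    lie closest to the scaffold centroid are kept (all tracks when None).
    When ``volumes`` is given, the VOI sub-volume of ``extents`` (or each
    record's own extents) is extracted per entry; otherwise entries carry
    None. Tracks with gaps are kept and a warning is emitted.
    """
    n_time = len(per_time_centers)
    tracker = IncrementalTracker(max_displacement=max_displacement)
    for t in range(n_time):
        tracker.update(t, per_time_centers[t])
    selected = select_tracks_near_centroid(tracker, per_time_centers[0], n_select)
    stacks = []
    for track_id in selected:
        entries = tracker.track_entries[track_id]
        hs = Hyperstack(voi_track_id=track_id)
        for t in sorted(entries):
            rec = per_time_records[t][entries[t]]
            sub = None
            if volumes is not None:
                ext = extents if extents is not None else rec.extents
                sub, clipped = extract_voi(volumes[t], rec.center_zyx_full, ext)
                rec.clipped = clipped
            hs.append(t, rec, sub)
        if len(hs.entries) < n_time:
            warn_once(
                f"track {track_id} has gaps: present at {len(hs.entries)}/{n_time} time points"
            )
        stacks.append(hs)
    return stacks
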