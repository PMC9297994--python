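"""Glass-phase and strut segmentation inside VOIs, plus evaluation.

Two regimes are used for the glassy phase, switching as sintering proceeds:

* early sintering — the glass/pore intensity histograms overlap, so a
  trainable random forest (200 trees) classifies every voxel from a
  77-attribute multi-scale feature bank;
* once densification has reached about 90% — the histogram becomes bimodal
  and a global Otsu threshold suffices.

The strut outline (the circular cross-section, internal pores filled) is
segmented per slice with a morphological region-based level set so the
strut diameter can be measured from the cross-sectional area.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, segmentation as sk_segmentation
from sklearn.ensemble import RandomForestClassifier

from .io_core import warn_once

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)
DIRECTIONAL_SCALES = (1.0, 1.5, 2.0, 3.0, 4.0)
N_DIRECTIONS = 10


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

def feature_names(scales: tuple[float, ...] = DEFAULT_SCALES) -> list[str]:
    """Manifest of the per-voxel attributes, in stack order.

    With the default scale set the bank has exactly 77 attributes:
    raw intensity (1); Gaussian blur at 4 scales (4); difference of
    Gaussians over the 6 scale pairs (6); Sobel gradient magnitude of the
    blurred image at 4 scales (4); Hessian eigenvalues and determinant at
    4 scales (12); oriented first-derivative-of-Gaussian filters at 10
    orientations x 5 scales (50).
    """
    names = ["raw"]
    names += [f"gauss_s{s:g}" for s in scales]
    names += [
        f"dog_s{a:g}_s{b:g}" for i, a in enumerate(scales) for b in scales[i + 1 :]
    ]
    names += [f"sobel_s{s:g}" for s in scales]
    for s in scales:
        names += [f"hess_l1_s{s:g}", f"hess_l2_s{s:g}", f"hess_det_s{s:g}"]
    for s in DIRECTIONAL_SCALES:
        for k in range(N_DIRECTIONS):
            names.append(f"dir_s{s:g}_a{180 * k // N_DIRECTIONS}")
    return names


@dataclass
class FeatureStack:
    """Per-voxel feature vectors for one sub-volume.

    ``values`` has shape ``(*volume_shape, n_features)`` (float32);
    ``names`` records the recipe so classifiers can refuse mismatched input.
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[-1] != len(self.names):
            raise ValueError("feature count does not match name manifest")
        if not np.isfinite(self.values).all():
            raise ValueError("feature stack contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1, self.n_features)


def _slice_features(sl: np.ndarray, scales: tuple[float, ...]) -> list[np.ndarray]:
    feats: list[np.ndarray] = [sl]
    blurred = {s: ndimage.gaussian_filter(sl, s, mode="reflect") for s in scales}
    feats += [blurred[s] for s in scales]
    feats += [
        blurred[a] - blurred[b] for i, a in enumerate(scales) for b in scales[i + 1 :]
    ]
    for s in scales:
        gy = ndimage.sobel(blurred[s], axis=0, mode="reflect")
        gx = ndimage.sobel(blurred[s], axis=1, mode="reflect")
        feats.append(np.hypot(gy, gx))
    for s in scales:
        hyy = ndimage.gaussian_filter(sl, s, order=(2, 0), mode="reflect")
        hxx = ndimage.gaussian_filter(sl, s, order=(0, 2), mode="reflect")
        hxy = ndimage.gaussian_filter(sl, s, order=(1, 1), mode="reflect")
        # eigenvalues of [[hyy, hxy], [hxy, hxx]]
        tr = hyy + hxx
        disc = np.sqrt(np.maximum((hyy - hxx) ** 2 + 4 * hxy**2, 0.0))
        feats.append(0.5 * (tr + disc))
        feats.append(0.5 * (tr - disc))
        feats.append(hyy * hxx - hxy**2)
    for s in DIRECTIONAL_SCALES:
        dy = ndimage.gaussian_filter(sl, s, order=(1, 0), mode="reflect")
        dx = ndimage.gaussian_filter(sl, s, order=(0, 1), mode="reflect")
        for k in range(N_DIRECTIONS):
            theta = np.pi * k / N_DIRECTIONS
            feats.append(np.cos(theta) * dy + np.sin(theta) * dx)
    return feats


def compute_feature_stack(
    voi: np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES
) -> FeatureStack:
    """Compute the 77-attribute bank slice-by-slice over a sub-volume.

    Features are evaluated in 2D per z-slice (matching the slice-wise
    acquisition geometry); reflective boundary handling keeps every value
    finite on small VOIs.
    """
    voi = np.asarray(voi)
    if voi.ndim != 3:
        raise ValueError("expected a 3D sub-volume (z, y, x)")
    if max(scales) > max(voi.shape[1], voi.shape[2]):
        raise ValueError(
            f"largest scale {max(scales)} too big for in-plane extent {voi.shape[1:]}"
        )
    names = feature_names(scales)
    out = np.empty(voi.shape + (len(names),), dtype=np.float32)
    for z in range(voi.shape[0]):
        sl = voi[z].astype(np.float32)
        for j, f in enumerate(_slice_features(sl, scales)):
            out[z, :, :, j] = f
    return FeatureStack(values=out, names=names)


# ---------------------------------------------------------------------------
# voxel classifier (random forest)
# ---------------------------------------------------------------------------

@dataclass
class VoxelClassifier:
    """Random forest over the feature bank, with OOB error and seed."""

    forest: RandomForestClassifier
    feature_names: list[str]
    oob_error: float
    seed: int
    class_labels: tuple[str, str] = ("pore", "glass")

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "VoxelClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, VoxelClassifier):
            raise TypeError("file does not contain a VoxelClassifier")
        return obj


def train_voxel_classifier(
    features: FeatureStack | np.ndarray,
    labels: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
) -> VoxelClassifier:
    """Fit the glass/pore random forest on sparsely labeled voxels.

    ``labels`` holds 1 for glass and 0 for pore, one entry per feature row.
    Features per split are sqrt of the bank size; out-of-bag scoring is on,
    and the fit is reproducible for a fixed seed.
    """
    if isinstance(features, FeatureStack):
        X = features.flat()
        names = features.names
    else:
        X = np.asarray(features)
        names = feature_names()
        if X.shape[1] != len(names):
            names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels differ in length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return VoxelClassifier(
        forest=forest,
        feature_names=list(names),
        oob_error=float(1.0 - forest.oob_score_),
        seed=seed,
    )


def segment_glass_rf(
    voi: np.ndarray,
    clf: VoxelClassifier,
    features: FeatureStack | None = None,
) -> np.ndarray:
    """Per-voxel majority vote of the forest -> boolean glass mask."""
    if features is None:
        features = compute_feature_stack(voi)
    if features.names != clf.feature_names:
        raise ValueError("feature recipe mismatch between stack and classifier")
    pred = clf.forest.predict(features.flat())
    return pred.reshape(voi.shape).astype(bool)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def otsu_threshold(voi: np.ndarray) -> int:
    """Global Otsu threshold of an 8-bit volume (foreground is ``> t``)."""
    voi = np.asarray(voi)
    if voi.min() == voi.max():
        raise ValueError("constant volume has no Otsu threshold")
    return int(filters.threshold_otsu(voi, nbins=256))


def segment_glass_otsu(voi: np.ndarray, min_contrast: float = 40.0) -> np.ndarray:
    """Threshold maximizing between-class variance; voxels above = glass.

    Otsu always produces a split, even of a single-phase volume (e.g. a
    fully densified VOI with no pores left), where the split would just
    carve the noise in half. When the resulting class means differ by less
    than ``min_contrast`` intensity levels the volume is treated as
    single-phase: all glass if its mean is in the upper half of the 8-bit
    range, all pore otherwise.
    """
    voi = np.asarray(voi)
    if voi.min() == voi.max():
        warn_once("constant volume: Otsu segmentation returns empty foreground")
        return np.zeros(voi.shape, dtype=bool)
    mask = voi > otsu_threshold(voi)
    if mask.any() and (~mask).any():
        contrast = float(voi[mask].mean() - voi[~mask].mean())
        if contrast < min_contrast:
            return np.full(voi.shape, float(voi.mean()) > 127.5, dtype=bool)
    return mask


def choose_segmenter(density_history: list[float], threshold_pct: float = 90.0) -> str:
    """Pick ``"rf"`` or ``"otsu"`` for the next time point.

    The forest is used while the running density estimate is below
    ``threshold_pct``; once the estimate has been at or above the threshold
    for two consecutive time points the choice flips to Otsu permanently
    (hysteresis avoids oscillation around the switch point).
    """
    above = [d >= threshold_pct for d in density_history]
    for i in range(len(above) - 1):
        if above[i] and above[i + 1]:
            return "otsu"
    return "rf"


# ---------------------------------------------------------------------------
# level-set strut segmentation
# ---------------------------------------------------------------------------

def chan_vese_mask(
    image: np.ndarray,
    max_iter: int = 200,
    smoothing: int = 1,
    min_contrast: float = 40.0,
    check_every: int = 20,
) -> np.ndarray:
    """Region-based (piecewise-constant) level set on one 2D slice.

    A morphological Chan-Vese contour is evolved from a checkerboard
    initialization until the mask stops changing or ``max_iter`` is hit
    (non-convergence returns the best iterate with a warning). The brighter
    region is taken as foreground. Slices without separable structure
    (zero variance, or an Otsu split whose class means differ by less than
    ``min_contrast`` intensity levels — the split of pure noise) return an
    empty mask.
    """
    img = np.asarray(image, dtype=np.float32)
    if float(img.var()) < 1e-6:
        return np.zeros(img.shape, dtype=bool)
    t = filters.threshold_otsu(img, nbins=256)
    fg = img > t
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=bool)
    if float(img[fg].mean() - img[~fg].mean()) < min_contrast:
        return np.zeros(img.shape, dtype=bool)

    level = sk_segmentation.checkerboard_level_set(img.shape, square_size=5)
    done = 0
    converged = False
    while done < max_iter:
        step = min(check_every, max_iter - done)
        new = sk_segmentation.morphological_chan_vese(
            img, num_iter=step, init_level_set=level, smoothing=smoothing
        )
        done += step
        if np.array_equal(new, level):
            level = new
            converged = True
            break
        level = new
    if not converged and done >= max_iter:
        warn_once(f"level set did not converge within {max_iter} iterations; using best iterate")
    mask = level.astype(bool)
    if not mask.any() or mask.all():
        return np.zeros(img.shape, dtype=bool)
    if img[mask].mean() < img[~mask].mean():
        mask = ~mask
    return mask


def segment_strut_levelset(
    diameter_child: np.ndarray,
    max_iter: int = 200,
    convex: bool = True,
    presmooth_sigma: float = 1.0,
    min_region_px: int = 25,
    smoothing: int = 0,
) -> np.ndarray:
    """Solid strut cross-section per slice: level set + internal pore filling.

    Applied slice-by-slice over the diameter child volume. Each slice is
    lightly Gaussian-smoothed, then outlined by the level set (curvature
    smoothing off by default: curvature flow systematically erodes convex
    boundaries, and the hull below supplies the shape regularity instead);
    speckle regions below ``min_region_px`` are dropped, internal pores are
    filled, and (by default) the per-slice convex hull of the remaining
    regions is taken: a printed strut cross-section is convex, and the
    hull restores the envelope where the contour dips into particle-scale
    surface roughness.
    """
    child = np.asarray(diameter_child)
    if child.ndim != 3:
        raise ValueError("expected a 3D child volume (z, y, x)")
    out = np.zeros(child.shape, dtype=bool)
    empty = 0
    for z in range(child.shape[0]):
        sl = child[z].astype(np.float32)
        if presmooth_sigma > 0:
            sl = ndimage.gaussian_filter(sl, presmooth_sigma, mode="nearest")
        mask = chan_vese_mask(sl, max_iter=max_iter, smoothing=smoothing)
        if mask.any():
            labels, n = ndimage.label(mask)
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = np.isin(labels, 1 + np.flatnonzero(sizes >= min_region_px))
        if not mask.any():
            empty += 1
            continue
        mask = ndimage.binary_fill_holes(mask)
        if convex:
            mask = morphology.convex_hull_image(mask)
        out[z] = mask
    if empty == child.shape[0]:
        warn_once("no strut found in any slice of the diameter child volume")
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationMetrics:
    """Confusion counts with IoU, accuracy and precision."""

    tp: int
    fp: int
    fn: int
    tn: int
    iou: float = field(init=False)
    accuracy: float = field(init=False)
    precision: float = field(init=False)

    def __post_init__(self) -> None:
        union = self.tp + self.fp + self.fn
        total = union + self.tn
        self.iou = self.tp / union if union else 1.0
        self.accuracy = (self.tp + self.tn) / total if total else 1.0
        self.precision = self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def evaluate_segmentation(predicted: np.ndarray, truth: np.ndarray) -> SegmentationMetrics:
    """Confusion counts of a predicted mask against ground truth."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(predicted & truth))
    fp = int(np.count_nonzero(predicted & ~truth))
    fn = int(np.count_nonzero(~predicted & truth))
    tn = int(np.count_nonzero(~predicted & ~truth))
    return SegmentationMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
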