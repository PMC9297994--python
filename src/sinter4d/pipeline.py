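"""End-to-end orchestration: preprocess -> detect/track -> segment -> quantify.

The analyzer streams one scan at a time (a full-resolution series never has
to fit in memory), maintains persistent VOI tracks, and records per-scan
densification, strut diameter and pore-diagonal-distance measurements. Two
front ends drive it:

* :func:`run_pipeline` — disk-based runs from a validated YAML/JSON config
  (manifest + TIFF volumes + trained classifiers);
* :func:`run_phantom_pipeline` — fully self-contained runs on a synthetic
  scaffold, where the classifiers are trained from the phantom's own ground
  truth and every measurement is paired with its true value.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .io_core import ScanSeries, ScanVolume, read_manifest, read_scan_volume, warn_once
from .preprocess import (
    PreprocessConfig,
    align_and_crop,
    convert_to_8bit,
    denoise_nlm,
    equalize_histogram,
    resample_quarter,
)
from .quantify import (
    DensificationSeries,
    annotate_stages,
    assemble_series,
    pixels_to_um,
    pore_diagonal_distance,
    strut_diameter,
)
from .segmentation import (
    VoxelClassifier,
    choose_segmenter,
    compute_feature_stack,
    evaluate_segmentation,
    segment_glass_otsu,
    segment_glass_rf,
    segment_strut_levelset,
    train_voxel_classifier,
)
from .voi_tracking import (
    DEFAULT_EXTENTS,
    IncrementalTracker,
    SliceClassifier,
    classify_slices,
    extract_voi,
    label_and_center_3d,
    segment_strut_regions_2d,
    select_tracks_near_centroid,
    train_slice_classifier,
    upscale_centers,
)


# ---------------------------------------------------------------------------
# parameters and config files
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """Tunable knobs of the analysis chain (defaults match 0.81 um scans)."""

    voxel_size_um: float = 0.81
    resample_factor: float = 0.25
    n_select: int = 3
    n_pdd_pairs: int = 3
    switch_threshold_pct: float = 90.0
    min_component_size: int = 500
    max_displacement: float = 20.0
    slice_min_run: int = 3
    slice_max_gap: int = 2
    slice_edge_trim: int = 2
    n_trees: int = 200
    denoise: bool = True
    equalize: bool = False
    extents: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_EXTENTS)
    )
    stage_rise_pct: float = 1.0
    stage_final_cutoff_pct: float = 90.0
    seed: int = 0


_CONFIG_KEYS = {
    "manifest",
    "volume_root",
    "output_dir",
    "voxel_size_um",
    "seed",
    "resample_factor",
    "n_select",
    "n_pdd_pairs",
    "switch_threshold_pct",
    "min_component_size",
    "max_displacement",
    "slice_min_run",
    "slice_max_gap",
    "slice_edge_trim",
    "n_trees",
    "denoise",
    "equalize",
    "extents",
    "rotation_deg",
    "crop_zyx",
    "slice_classifier",
    "voxel_classifier",
    "stage_rise_pct",
    "stage_final_cutoff_pct",
    "force",
}

_REQUIRED_KEYS = {"manifest", "output_dir"}


@dataclass
class PipelineConfig:
    """Fully resolved disk-run configuration."""

    manifest: Path
    output_dir: Path
    volume_root: Path | None = None
    slice_classifier: Path | None = None
    voxel_classifier: Path | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    params: PipelineParams = field(default_factory=PipelineParams)
    force: bool = False


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default and validate a YAML/JSON pipeline config.

    Unknown keys, missing required keys and out-of-range values all raise
    before any work starts. Defaults: resample factor 0.25, 200 trees, 90%
    segmenter switch, 0.81 um voxels.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    missing = sorted(_REQUIRED_KEYS - set(raw))
    if missing:
        raise ValueError(f"missing required config key(s): {missing}")
    params = PipelineParams()
    for key in (
        "voxel_size_um",
        "resample_factor",
        "n_select",
        "n_pdd_pairs",
        "switch_threshold_pct",
        "min_component_size",
        "max_displacement",
        "slice_min_run",
        "slice_max_gap",
        "slice_edge_trim",
        "n_trees",
        "denoise",
        "equalize",
        "stage_rise_pct",
        "stage_final_cutoff_pct",
        "seed",
    ):
        if key in raw:
            if raw[key] is None:
                raise ValueError(f"config key {key!r} must not be null")
            setattr(params, key, raw[key])
    if "extents" in raw:
        params.extents = {k: tuple(v) for k, v in raw["extents"].items()}
    if params.voxel_size_um is None or params.voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be > 0")
    if not (0.0 < params.resample_factor <= 1.0):
        raise ValueError("resample_factor must be in (0, 1]")
    if params.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    pp = PreprocessConfig(
        rotation_deg=raw.get("rotation_deg", 0.0),
        crop_zyx=tuple(
            tuple(r) if r is not None else None for r in raw.get("crop_zyx", (None, None, None))
        ),
        resample_factor=params.resample_factor,
    )
    manifest = Path(raw["manifest"])
    if not manifest.exists():
        raise ValueError(f"manifest does not exist: {manifest}")
    return PipelineConfig(
        manifest=manifest,
        output_dir=Path(raw["output_dir"]),
        volume_root=Path(raw["volume_root"]) if raw.get("volume_root") else None,
        slice_classifier=Path(raw["slice_classifier"]) if raw.get("slice_classifier") else None,
        voxel_classifier=Path(raw["voxel_classifier"]) if raw.get("voxel_classifier") else None,
        preprocess=pp,
        params=params,
        force=bool(raw.get("force", False)),
    )


# ---------------------------------------------------------------------------
# per-series analyzer
# ---------------------------------------------------------------------------

def _diagonal_pairs(
    centers: np.ndarray,
    min_offset: float,
    same_run_tol: float,
    n_pairs: int,
) -> list[tuple[int, int]]:
    """Diagonal-neighbor pairs among VOI centers at one time point.

    A pair is diagonal when the two centers sit in the same z-run (|dz| <=
    ``same_run_tol``) and are offset by more than ``min_offset`` in both
    in-plane axes. The shortest such pairs are kept, tie-broken toward the
    scaffold centroid, mirroring the analysed interstrut pore channels.
    """
    if len(centers) < 2:
        return []
    centroid = centers.mean(axis=0)
    cands = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dz = abs(centers[i][0] - centers[j][0])
            dy = abs(centers[i][1] - centers[j][1])
            dx = abs(centers[i][2] - centers[j][2])
            if dz > same_run_tol or dy < min_offset or dx < min_offset:
                continue
            dist = float(np.hypot(dy, dx))
            mid = (centers[i] + centers[j]) / 2.0
            cands.append((dist, float(np.linalg.norm(mid - centroid)), i, j))
    if not cands:
        return []
    cands.sort()
    shortest = cands[0][0]
    near = [c for c in cands if c[0] <= 1.2 * shortest]
    near.sort(key=lambda c: (c[1], c[0]))
    return [(i, j) for _, _, i, j in near[:n_pairs]]


@dataclass
class TimePointMeasurement:
    time_index: int
    scan_id: str
    time_s: float
    temperature_C: float
    n_vois: int
    segmenter: str
    density_pct: float | None
    diameter_px: float | None
    diameter_um: float | None
    pdd_px: float | None
    pdd_um: float | None
    rf_iou: float | None = None
    otsu_iou: float | None = None
    truth_voi_density_pct: float | None = None  # true glass fraction in the measured VOIs


_CHILD_NLM = PreprocessConfig(nlm_patch_radius=1, nlm_search_radius=3)


def prepare_child(child: np.ndarray, params: PipelineParams) -> np.ndarray:
    """Child-VOI preprocessing before segmentation: NLM denoise (+ equalize).

    A compact NLM neighborhood (patch radius 1, search radius 3) is used on
    the small child volumes; equalization is off by default and intended
    for low-contrast scans.
    """
    vol = ScanVolume(voxels=child, voxel_size_um=params.voxel_size_um)
    if params.denoise:
        vol = denoise_nlm(vol, _CHILD_NLM)
    if params.equalize:
        vol = equalize_histogram(vol)
    return vol.voxels


class SeriesAnalyzer:
    """Streaming analysis of a scan series with persistent VOI tracks.

    Feed scans in time order through :meth:`process`; per scan the analyzer
    detects VOIs on the quarter-resampled volume, links them to the
    existing tracks, extracts the densification and diameter children of
    the selected tracks at full resolution, segments them and records the
    sintering descriptors.
    """

    def __init__(
        self,
        params: PipelineParams,
        slice_clf: SliceClassifier,
        voxel_clf: VoxelClassifier | None,
    ):
        self.params = params
        self.slice_clf = slice_clf
        self.voxel_clf = voxel_clf
        self.tracker = IncrementalTracker(max_displacement=params.max_displacement)
        self.selected: list[int] | None = None
        self.pdd_pairs: list[tuple[int, int]] = []
        self.density_history: list[float] = []
        self.measurements: list[TimePointMeasurement] = []
        self._first_centers: list[tuple[float, float, float]] | None = None

    # -- helpers --------------------------------------------------------

    def _prepare_child(self, child: np.ndarray) -> np.ndarray:
        return prepare_child(child, self.params)

    def _detect(self, volume_full: ScanVolume) -> list[tuple[float, float, float]]:
        coarse = resample_quarter(volume_full, self.params.resample_factor)
        z_idx = classify_slices(
            coarse,
            self.slice_clf,
            min_run=self.params.slice_min_run,
            max_gap=self.params.slice_max_gap,
            edge_trim=self.params.slice_edge_trim,
        )
        region = np.zeros(coarse.voxels.shape, dtype=bool)
        for z in z_idx:
            region[z] = segment_strut_regions_2d(coarse.voxels[z])
        comps = label_and_center_3d(region, min_size=self.params.min_component_size)
        coarse_centers = [c for _, c, _ in comps]
        return upscale_centers(coarse_centers, self.params.resample_factor, round_to_int=False)

    def _segment_child(
        self, child: np.ndarray, segmenter: str
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """(chosen mask, rf mask if it was computed anyway)."""
        if segmenter == "rf" and self.voxel_clf is not None:
            feats = compute_feature_stack(child)
            mask = segment_glass_rf(child, self.voxel_clf, features=feats)
            return mask, mask
        return segment_glass_otsu(child), None

    # -- main entry -----------------------------------------------------

    def process(
        self,
        time_index: int,
        volume_full: ScanVolume,
        truth: ph.PhantomTimePoint | None = None,
    ) -> TimePointMeasurement:
        p = self.params
        centers = self._detect(volume_full)
        self.tracker.update(time_index, centers)
        if self.selected is None:
            self._first_centers = centers
            self.selected = select_tracks_near_centroid(self.tracker, centers, p.n_select)
            all_tracks = select_tracks_near_centroid(self.tracker, centers, None)
            pts = np.array([self.tracker.track_last_center[t] for t in all_tracks])
            min_offset = p.extents["diameter_child"][1] / 4.0
            run_tol = p.extents["parent"][0] / 2.0
            raw_pairs = _diagonal_pairs(pts, min_offset, run_tol, p.n_pdd_pairs)
            self.pdd_pairs = [(all_tracks[i], all_tracks[j]) for i, j in raw_pairs]

        segmenter = choose_segmenter(self.density_history, p.switch_threshold_pct)

        densities, diam_px_list = [], []
        rf_ious, otsu_ious, truth_densities = [], [], []
        for track_id in self.selected:
            entries = self.tracker.track_entries[track_id]
            if time_index not in entries:
                warn_once(f"track {track_id} unmatched at time {time_index}; VOI skipped")
                continue
            center = self.tracker.track_last_center[track_id]
            child, _ = extract_voi(volume_full, center, p.extents["densification_child"])
            child = self._prepare_child(child)
            mask, rf_mask = self._segment_child(child, segmenter)
            densities.append(100.0 * float(mask.mean()))
            if truth is not None:
                truth_child, _ = extract_voi(truth.glass_mask, center, p.extents["densification_child"])
                truth_densities.append(100.0 * float(truth_child.mean()))
                if rf_mask is None and self.voxel_clf is not None:
                    rf_mask = segment_glass_rf(child, self.voxel_clf)
                if rf_mask is not None:
                    rf_ious.append(evaluate_segmentation(rf_mask, truth_child).iou)
                otsu_ious.append(
                    evaluate_segmentation(segment_glass_otsu(child), truth_child).iou
                )
            # the outline estimator smooths internally; NLM is not applied here
            dchild, _ = extract_voi(volume_full, center, p.extents["diameter_child"])
            strut_mask = segment_strut_levelset(dchild)
            rec = strut_diameter(strut_mask, p.voxel_size_um)
            if rec.mean_diameter_px > 0:
                diam_px_list.append(rec.mean_diameter_px)

        density = float(np.mean(densities)) if densities else None
        if density is not None:
            self.density_history.append(density)
        diameter_px = float(np.mean(diam_px_list)) if diam_px_list else None
        diameter_um = pixels_to_um(diameter_px, p.voxel_size_um) if diameter_px else None

        pdd_um = pdd_px = None
        if diameter_um is not None and self.pdd_pairs:
            vals = []
            for ta, tb in self.pdd_pairs:
                ea, eb = self.tracker.track_entries[ta], self.tracker.track_entries[tb]
                if time_index not in ea or time_index not in eb:
                    continue
                ca = self.tracker.track_last_center[ta]
                cb = self.tracker.track_last_center[tb]
                vals.append(
                    pore_diagonal_distance(ca, cb, diameter_um, p.voxel_size_um)
                )
            if vals:
                pdd_um = float(np.mean(vals))
                pdd_px = pdd_um / p.voxel_size_um

        m = TimePointMeasurement(
            time_index=time_index,
            scan_id=volume_full.scan_id,
            time_s=volume_full.time_s,
            temperature_C=volume_full.temperature_C,
            n_vois=len(centers),
            segmenter=segmenter,
            density_pct=density,
            diameter_px=diameter_px,
            diameter_um=diameter_um,
            pdd_px=pdd_px,
            pdd_um=pdd_um,
            rf_iou=float(np.mean(rf_ious)) if rf_ious else None,
            otsu_iou=float(np.mean(otsu_ious)) if otsu_ious else None,
            truth_voi_density_pct=float(np.mean(truth_densities)) if truth_densities else None,
        )
        self.measurements.append(m)
        return m

    # -- results --------------------------------------------------------

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.measurements])

    def tracked_fraction(self, n_expected: int, n_time_points: int) -> float:
        """Percent of expected segments followed through every time point."""
        complete = sum(
            1
            for entries in self.tracker.track_entries
            if len(entries) == n_time_points and min(entries) == 0
        )
        return 100.0 * complete / n_expected if n_expected else 0.0


# ---------------------------------------------------------------------------
# phantom-driven end-to-end run
# ---------------------------------------------------------------------------

def phantom_pipeline_params(spec: ph.PhantomSpec, seed: int = 0) -> PipelineParams:
    """Pipeline parameters matched to a phantom's geometry.

    VOI extents scale with the phantom's strut diameter and gap length (the
    full-scale defaults correspond to 0.81 um scans of ~300 px struts);
    the minimum component size scales with the coarse cross-section area.
    """
    d = spec.lattice.strut_diameter
    gap = spec.lattice.pitch - d
    f = 0.25
    parent_z = int(round(gap * 0.75))
    window = int(round(d * 4 / 3))
    dens = int(round(d * 0.5))
    dens_z = int(round(gap * 0.5))
    coarse_area = np.pi * (d * f / 2.0) ** 2
    min_size = int(coarse_area * max(3, int(gap * f * 0.5)) * 0.5)
    # shave run edges in proportion to the coarse gap length (>= 1 slice)
    edge_trim = max(1, int(round(gap * f * 0.12)))
    return PipelineParams(
        voxel_size_um=spec.voxel_size_um,
        resample_factor=f,
        extents={
            "parent": (parent_z, window, window),
            "densification_child": (dens_z, dens, dens),
            "diameter_child": (10, window, window),
        },
        min_component_size=min_size,
        slice_edge_trim=edge_trim,
        seed=seed,
    )


def _slice_labels(
    sim: ph.SinteringSimulator, t: int, factor: float = 0.25
) -> list[int | None]:
    """Geometry-derived training labels per coarse z slice (None = ambiguous)."""
    spec = sim.spec
    geom = sim.phantom.geometry
    scale = sim.scales[t]
    k = int(round(1.0 / factor))
    cz = geom.centroid[0]
    sz = scale[0]
    r = spec.lattice.strut_diameter / 2.0
    margin = 3.0
    cross = [cz + sz * (zc - cz) for zc in geom.crossing_z]
    half = r * sz
    span_lo = cz + sz * (geom.struts[0].span[0] - cz)
    span_hi = cz + sz * (geom.struts[0].span[1] - cz)
    gaps = [
        (cross[i] + half + margin, cross[i + 1] - half - margin)
        for i in range(len(cross) - 1)
    ]
    n_coarse = spec.shape_zyx[0] // k
    labels: list[int | None] = []
    for z in range(n_coarse):
        lo, hi = z * k, (z + 1) * k
        if any(lo >= a and hi <= b for a, b in gaps):
            labels.append(1)
        elif any(lo >= c - half + margin and hi <= c + half - margin for c in cross):
            labels.append(0)
        elif hi <= span_lo - margin or lo >= span_hi + margin:
            labels.append(0)
        else:
            labels.append(None)
    return labels


def train_classifiers_from_phantom(
    sim: ph.SinteringSimulator,
    params: PipelineParams,
    n_voxel_labels: int = 20_000,
    training_time_points: tuple[int, ...] | None = None,
    first_tp: ph.PhantomTimePoint | None = None,
) -> tuple[SliceClassifier, VoxelClassifier]:
    """Train the slice SVM and the voxel forest from phantom ground truth.

    Slice examples come from the first and last time points (labels derived
    from the lattice geometry); voxel labels are a stratified sample of the
    true glass mask inside one densification child at the first time point,
    preprocessed exactly as at prediction time.
    """
    if training_time_points is None:
        training_time_points = (0, sim.n_time_points - 1)
    labeled_slices: list[tuple[np.ndarray, int]] = []
    first: ph.PhantomTimePoint | None = first_tp
    for t in sorted(set(training_time_points)):
        tp = first if (t == 0 and first is not None) else sim.time_point(t)
        if t == 0:
            first = tp
        coarse = resample_quarter(tp.image, params.resample_factor)
        for z, lbl in enumerate(_slice_labels(sim, t, params.resample_factor)):
            if lbl is not None and z < coarse.voxels.shape[0]:
                labeled_slices.append((coarse.voxels[z], lbl))
    slice_clf = train_slice_classifier(labeled_slices, seed=params.seed)

    if first is None:
        first = sim.time_point(0)
    # train on the segment farthest from the scaffold centroid: the analysed
    # (centroid-nearest) VOIs then never coincide with the training region
    dists = np.linalg.norm(
        first.segment_centers - first.segment_centers.mean(axis=0), axis=1
    )
    center = tuple(first.segment_centers[int(np.argmax(dists))])
    ext = params.extents["densification_child"]
    child, _ = extract_voi(first.image, center, ext)
    child = prepare_child(child, params)
    truth_child, _ = extract_voi(first.glass_mask, center, ext)
    feats = compute_feature_stack(child)
    X = feats.flat()
    y = truth_child.ravel().astype(int)
    rng = np.random.default_rng([params.seed, 3])
    n = min(n_voxel_labels, len(y))
    idx = rng.choice(len(y), size=n, replace=False)
    voxel_clf = train_voxel_classifier(X[idx], y[idx], n_trees=params.n_trees, seed=params.seed)
    return slice_clf, voxel_clf


@dataclass
class PhantomRunResult:
    """Measurements, truth and tracking summary of a phantom run."""

    table: pd.DataFrame
    tracked_fraction_pct: float
    n_tracks: int
    n_true_segments: int
    params: PipelineParams
    spec: ph.PhantomSpec


def run_phantom_pipeline(
    spec: ph.PhantomSpec,
    params: PipelineParams | None = None,
    progress: bool = False,
) -> PhantomRunResult:
    """Generate a phantom series and analyze it end to end against truth.

    Returns a per-time-point table with measured and true density, strut
    diameter and PDD, the segmenter used, and RF/Otsu IoU against the true
    glass mask, plus the fraction of strut segments tracked through the
    whole series.
    """
    if params is None:
        params = phantom_pipeline_params(spec, seed=spec.seed)
    scaffold = ph.generate_scaffold_phantom(spec)
    sim = ph.SinteringSimulator(scaffold, include_noise=True)
    first_tp = sim.time_point(0)
    slice_clf, voxel_clf = train_classifiers_from_phantom(sim, params, first_tp=first_tp)
    analyzer = SeriesAnalyzer(params, slice_clf, voxel_clf)
    truth_rows = []
    for t in range(sim.n_time_points):
        tp = first_tp if t == 0 else sim.time_point(t)
        if t == 0:
            first_tp = None  # free after use
        analyzer.process(t, tp.image, truth=tp)
        truth_rows.append(
            {
                "time_index": t,
                "true_density_pct": tp.true_density_pct,
                "true_diameter_px": tp.true_diameter_px,
                "true_pdd_px": tp.true_pdd_px,
                "n_true_segments": len(tp.segment_centers),
            }
        )
        if progress:
            print(f"  processed time point {t + 1}/{sim.n_time_points}", flush=True)
    table = analyzer.results_frame().merge(pd.DataFrame(truth_rows), on="time_index")
    n_true = int(table["n_true_segments"].iloc[0])
    tracked = analyzer.tracked_fraction(n_true, sim.n_time_points)
    return PhantomRunResult(
        table=table,
        tracked_fraction_pct=tracked,
        n_tracks=analyzer.tracker.n_tracks,
        n_true_segments=n_true,
        params=params,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# disk-based run
# ---------------------------------------------------------------------------

def _iter_series_volumes(config: PipelineConfig) -> Iterable[ScanVolume]:
    series: ScanSeries = read_manifest(config.manifest, volume_root=config.volume_root)
    for row in series:
        sid = row["scan_id"]
        path = series.volume_paths.get(sid)
        if path is None:
            raise FileNotFoundError(f"no volume found for scan_id {sid!r}")
        vol = read_scan_volume(
            path,
            config.params.voxel_size_um,
            time_s=float(row["time_s"]),
            temperature_C=float(row["temperature_C"]),
            scan_id=sid,
        )
        vol = convert_to_8bit(vol)
        if config.preprocess.rotation_deg != 0.0 or any(
            r is not None for r in config.preprocess.crop_zyx
        ):
            vol = align_and_crop(vol, config.preprocess)
        yield vol


def run_pipeline(config: PipelineConfig) -> DensificationSeries:
    """Run the full analysis from a validated disk config.

    Writes the series CSV, plots and a JSON-lines run log into the output
    directory. A completed output (series.csv present) is returned as-is
    unless ``force`` is set. Any stage failure aborts with the scan id and
    stage name in the raised error; partial outputs are retained.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    series_csv = out / "series.csv"
    if series_csv.exists() and not config.force:
        return DensificationSeries(table=pd.read_csv(series_csv, dtype={"scan_id": str}))
    if config.slice_classifier is None:
        raise ValueError("disk runs require a trained slice classifier (slice_classifier)")
    import pickle

    with open(config.slice_classifier, "rb") as fh:
        slice_clf: SliceClassifier = pickle.load(fh)
    voxel_clf = (
        VoxelClassifier.load(config.voxel_classifier) if config.voxel_classifier else None
    )
    analyzer = SeriesAnalyzer(config.params, slice_clf, voxel_clf)
    manifest = read_manifest(config.manifest, volume_root=config.volume_root)
    log_path = out / "run_log.jsonl"
    records: dict[str, dict[str, float]] = {}
    with open(log_path, "a") as log:
        for t, vol in enumerate(_iter_series_volumes(config)):
            t0 = _time.monotonic()
            try:
                m = analyzer.process(t, vol)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                log.write(
                    json.dumps(
                        {"scan_id": vol.scan_id, "stage": "analyze", "error": str(exc)}
                    )
                    + "\n"
                )
                raise RuntimeError(f"stage 'analyze' failed for scan {vol.scan_id!r}") from exc
            rec: dict[str, float] = {}
            if m.density_pct is not None:
                rec["relative_density_pct"] = m.density_pct
            if m.diameter_um is not None:
                rec["strut_diameter_um"] = m.diameter_um
            if m.pdd_um is not None:
                rec["pdd_um"] = m.pdd_um
            records[vol.scan_id] = rec
            log.write(
                json.dumps(
                    {
                        "scan_id": vol.scan_id,
                        "stage": "analyze",
                        "seconds": round(_time.monotonic() - t0, 3),
                        "segmenter": m.segmenter,
                        "n_vois": m.n_vois,
                        "seed": config.params.seed,
                    }
                )
                + "\n"
            )
    series = assemble_series(records, manifest)
    annotate_stages(
        series,
        rise_pct_per_scan=config.params.stage_rise_pct,
        final_cutoff_pct=config.params.stage_final_cutoff_pct,
    )
    series.to_csv(series_csv)
    from .quantify import plot_series

    plot_series(series, out / "plots")
    return series
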