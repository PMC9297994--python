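"""Sintering descriptors computed from segmentations.

Definitions (all percentages on a 0-100 scale):

* intrastrut porosity = pore voxels / (pore + glass voxels) x 100, and
  relative density of the glassy phase = 100 - porosity;
* strut diameter = 2 * sqrt(area / pi) per slice, assuming a circular
  cross-section, averaged over the slices of the diameter child and over
  VOIs; the per-VOI mean in pixels is rounded to the nearest integer before
  conversion to micrometres;
* pore diagonal distance (PDD) = diagonal XY distance between neighboring
  strut centers minus the strut diameter;
* isotropic volume shrinkage = 1 - (1 - linear shrinkage)^3;
* strut overlap = strut diameter - z layer spacing (floored at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ScanSeries, warn_once


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class DensificationRecord:
    """Per-time-point intrastrut porosity bookkeeping for one or more VOIs."""

    time_s: float
    temperature_C: float
    glass_voxels: int
    pore_voxels: int
    porosity_pct: float = field(init=False)
    relative_density_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.glass_voxels < 0 or self.pore_voxels < 0:
            raise ValueError("voxel counts must be >= 0")
        self.porosity_pct, self.relative_density_pct = relative_density(
            self.glass_voxels, self.pore_voxels
        )


@dataclass
class StrutGeometryRecord:
    """Per-time-point strut cross-section geometry averaged over VOIs."""

    time_s: float
    slice_areas_px: list[float]
    slice_diameters_px: list[float]
    mean_diameter_px: float
    mean_diameter_um: float
    pdd_um: float | None
    n_vois: int


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------

def relative_density(glass_voxels: int, pore_voxels: int) -> tuple[float, float]:
    """(porosity %, relative density %) from voxel counts.

    Porosity is the pore fraction of the VOI in percent; relative density is
    its complement, so the two always sum to exactly 100.
    """
    total = glass_voxels + pore_voxels
    if total <= 0:
        raise ValueError("empty VOI: glass and pore voxel counts are both zero")
    porosity = 100.0 * pore_voxels / total
    return porosity, 100.0 - porosity


def diameter_from_area(area_px: float) -> float:
    """Equivalent-circle diameter (pixels) of a cross-sectional area."""
    if area_px < 0:
        raise ValueError("area must be >= 0")
    return 2.0 * math.sqrt(area_px / math.pi)


def strut_diameter(
    strut_mask: np.ndarray,
    voxel_size_um: float,
    time_s: float = 0.0,
    pdd_um: float | None = None,
    n_vois: int = 1,
) -> StrutGeometryRecord:
    """Strut diameter of one VOI from its per-slice strut masks.

    Per slice, the area is the foreground pixel count and the diameter
    ``2*sqrt(area/pi)``; the per-VOI diameter is the mean over the slices
    (empty slices are excluded with a warning). The reported value in
    micrometres applies the integer-pixel rounding rule before multiplying
    by the voxel size.
    """
    mask = np.asarray(strut_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected per-slice masks stacked as (z, y, x)")
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1).astype(float)
    diameters = [diameter_from_area(a) for a in areas]
    nonempty = [d for a, d in zip(areas, diameters) if a > 0]
    if len(nonempty) < len(diameters):
        warn_once(f"{len(diameters) - len(nonempty)} empty slice(s) excluded from diameter mean")
    mean_px = float(np.mean(nonempty)) if nonempty else 0.0
    return StrutGeometryRecord(
        time_s=time_s,
        slice_areas_px=list(areas),
        slice_diameters_px=diameters,
        mean_diameter_px=mean_px,
        mean_diameter_um=pixels_to_um(mean_px, voxel_size_um),
        pdd_um=pdd_um,
        n_vois=n_vois,
    )


def pixels_to_um(value_px: float, voxel_size_um: float) -> float:
    """Round a pixel measurement to the nearest integer, then convert to um."""
    return float(np.floor(value_px + 0.5)) * voxel_size_um


def pore_diagonal_distance(
    center_a: tuple[float, ...],
    center_b: tuple[float, ...],
    diameter_um: float,
    voxel_size_um: float,
) -> float:
    """PDD between two parallel struts across one interstrut pore channel.

    Euclidean XY distance between the strut centers (in pixels, rounded to
    the nearest integer) times the voxel size, minus the strut diameter.
    Centers are ``(z, y, x)`` (or ``(y, x)``) full-resolution coordinates.
    A negative result means overlapping struts and is returned with a
    warning.
    """
    a = np.asarray(center_a, dtype=float)[-2:]
    b = np.asarray(center_b, dtype=float)[-2:]
    dist_um = pixels_to_um(float(np.linalg.norm(a - b)), voxel_size_um)
    pdd = dist_um - diameter_um
    if pdd < 0:
        warn_once(f"negative pore diagonal distance ({pdd:.1f} um): overlapping struts")
    return pdd


def volume_shrinkage_isotropic(linear_shrinkage: float) -> float:
    """Volume shrinkage of an isotropically shrinking body: 1 - (1 - s)^3."""
    if not (0.0 <= linear_shrinkage <= 1.0):
        raise ValueError(f"linear shrinkage must be in [0, 1]; got {linear_shrinkage}")
    return 1.0 - (1.0 - linear_shrinkage) ** 3


def percent_reduction(initial: float, final: float) -> float:
    """Percent reduction of a positive quantity, e.g. strut diameter."""
    if initial <= 0:
        raise ValueError("initial value must be > 0")
    return 100.0 * (initial - final) / initial


def measured_volume_shrinkage(
    box_before: tuple[float, float, float], box_after: tuple[float, float, float]
) -> float:
    """1 - V_after / V_before from bounding-box extents in the same units."""
    v0 = float(np.prod(box_before))
    v1 = float(np.prod(box_after))
    if v0 <= 0:
        raise ValueError("initial bounding box has zero volume")
    return 1.0 - v1 / v0


def strut_overlap(diameter_um: float, z_spacing_um: float) -> tuple[float, float]:
    """Layer-to-layer strut overlap and its percentage of the diameter.

    Struts printed with a z layer spacing smaller than their diameter
    interpenetrate by ``diameter - spacing`` (floored at 0).
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    overlap = max(diameter_um - z_spacing_um, 0.0)
    return overlap, 100.0 * overlap / diameter_um


# ---------------------------------------------------------------------------
# series assembly and stage annotation
# ---------------------------------------------------------------------------

SERIES_COLUMNS = [
    "scan_id",
    "time_s",
    "temperature_C",
    "relative_density_pct",
    "porosity_pct",
    "strut_diameter_um",
    "pdd_um",
]


@dataclass
class DensificationSeries:
    """Per-time-point table of the sintering descriptors."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        times = self.table["time_s"].to_numpy()
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("time_s must be strictly increasing")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def assemble_series(
    records: dict[str, dict[str, float]],
    manifest: ScanSeries,
) -> DensificationSeries:
    """Join per-scan quantities with the manifest into a time-sorted table.

    ``records`` maps scan_id to a dict with any of ``relative_density_pct``,
    ``strut_diameter_um``, ``pdd_um``. Missing fields are kept as nulls with
    a warning; a record for an unknown scan_id raises.
    """
    known = set(manifest.manifest["scan_id"])
    unknown = sorted(set(records) - known)
    if unknown:
        raise ValueError(f"records reference unknown scan_id(s): {unknown}")
    rows = []
    for row in manifest:
        rec = records.get(row["scan_id"], {})
        density = rec.get("relative_density_pct")
        entry = {
            "scan_id": row["scan_id"],
            "time_s": float(row["time_s"]),
            "temperature_C": float(row["temperature_C"]),
            "relative_density_pct": density,
            "porosity_pct": None if density is None else 100.0 - density,
            "strut_diameter_um": rec.get("strut_diameter_um"),
            "pdd_um": rec.get("pdd_um"),
        }
        missing = [k for k in ("relative_density_pct", "strut_diameter_um") if entry[k] is None]
        if missing:
            warn_once(f"scan {row['scan_id']!r}: missing field(s) {missing}; row kept with nulls")
        rows.append(entry)
    return DensificationSeries(table=pd.DataFrame(rows, columns=SERIES_COLUMNS))


def annotate_stages(
    series: DensificationSeries,
    rise_pct_per_scan: float = 1.0,
    final_cutoff_pct: float = 90.0,
    monotone_tolerance_pct: float = 2.0,
) -> list[str]:
    """Label each row initial / intermediate / final by first crossings.

    The intermediate stage begins at the first sustained density rise (two
    consecutive scan-to-scan increases of at least ``rise_pct_per_scan``);
    the final stage begins once the density first reaches
    ``final_cutoff_pct``. These landmarks follow classical sintering theory
    (neck formation, bulk densification to ~90%, closed-pore elimination)
    and are reported as derived annotations. Density dips beyond the
    tolerance only trigger a warning; labels are still assigned by first
    crossings. The resulting labels are also written into a ``stage``
    column of the series table.
    """
    d = series.table["relative_density_pct"].to_numpy(dtype=float)
    n = len(d)
    valid = np.isfinite(d)
    if not valid.any():
        raise ValueError("density column is empty")
    diffs = np.diff(d)
    if np.nanmin(diffs, initial=0.0) < -monotone_tolerance_pct:
        warn_once("density decreases beyond tolerance; stage labels assigned by first crossings")
    final_start = n
    for i in range(n):
        if valid[i] and d[i] >= final_cutoff_pct:
            final_start = i
            break
    inter_start = final_start
    for i in range(n - 2):
        if diffs[i] >= rise_pct_per_scan and diffs[i + 1] >= rise_pct_per_scan:
            inter_start = min(i + 1, final_start)
            break
    labels = []
    for i in range(n):
        if i >= final_start:
            labels.append("final")
        elif i >= inter_start:
            labels.append("intermediate")
        else:
            labels.append("initial")
    series.table["stage"] = labels
    return labels


def plot_series(series: DensificationSeries, out_dir) -> list[str]:
    """Emit the descriptor-vs-time/temperature plots as vector graphics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = series.table
    written = []
    specs = [
        ("relative_density_pct", "Relative density of glassy phase (%)", "density_vs_time.svg"),
        ("strut_diameter_um", "Strut diameter (um)", "diameter_vs_time.svg"),
        ("pdd_um", "Pore diagonal distance (um)", "pdd_vs_time.svg"),
    ]
    for col, ylabel, fname in specs:
        if col not in t or t[col].isna().all():
            continue
        fig, ax1 = plt.subplots(figsize=(6, 4))
        ax1.plot(t["time_s"] / 60.0, t[col], "o-", ms=3)
        ax1.set_xlabel("Time (min)")
        ax1.set_ylabel(ylabel)
        ax2 = ax1.twinx()
        ax2.plot(t["time_s"] / 60.0, t["temperature_C"], "r--", lw=1, alpha=0.6)
        ax2.set_ylabel("Temperature (C)", color="r")
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))
    return written
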