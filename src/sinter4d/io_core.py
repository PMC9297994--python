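"""Image volume and manifest I/O plus the sintering temperature schedule.

Conventions used throughout the package:

* volumes are 3D arrays in ``(z, y, x)`` axis order, 0-based indices,
  half-open crop ranges;
* grayscale volumes are stored as multi-page TIFF stacks or directories of
  equally sized 2D TIFF slices (stacked in filename-sorted z order);
* binary masks are written as 8-bit TIFF with foreground 255, background 0;
* the scan manifest is a CSV with header ``scan_id,time_s,temperature_C``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

_TIFF_SUFFIXES = (".tif", ".tiff")

MANIFEST_COLUMNS = ("scan_id", "time_s", "temperature_C")


@dataclass
class ScanVolume:
    """One 3D intensity grid with acquisition metadata.

    Parameters
    ----------
    voxels
        3D array of scalar intensities in ``(z, y, x)`` order.
    voxel_size_um
        Isotropic voxel edge length in micrometres; must be positive.
    time_s
        Seconds since the start of the analysed phase.
    temperature_C
        Furnace temperature at acquisition, degrees Celsius.
    scan_id
        Opaque identifier of the scan.
    """

    voxels: np.ndarray
    voxel_size_um: float
    time_s: float = 0.0
    temperature_C: float = float("nan")
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x); got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1; got shape {self.voxels.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0; got {self.voxel_size_um}")
        if self.voxels.dtype == np.uint8:
            pass  # 8-bit by construction
        elif np.issubdtype(self.voxels.dtype, np.integer):
            info = np.iinfo(self.voxels.dtype)
            lo, hi = self.voxels.min(), self.voxels.max()
            if lo < info.min or hi > info.max:  # pragma: no cover - unreachable for ints
                raise ValueError("intensities outside declared bit depth")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray, voxel_size_um: float | None = None) -> "ScanVolume":
        """Return a copy carrying new voxel data but the same metadata."""
        return replace(
            self,
            voxels=voxels,
            voxel_size_um=self.voxel_size_um if voxel_size_um is None else voxel_size_um,
        )


@dataclass
class ScanSeries:
    """Ordered scan manifest, optionally with resolvable volume paths."""

    manifest: pd.DataFrame
    volume_paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.manifest.columns]
        if missing:
            raise ValueError(f"manifest missing column(s): {missing}")
        self.manifest = self.manifest.sort_values("time_s", kind="stable").reset_index(drop=True)
        ids = self.manifest["scan_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate scan_id(s) in manifest: {dupes}")
        times = self.manifest["time_s"].to_numpy()
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("time_s must be strictly increasing after sort (duplicate timestamps?)")

    def __len__(self) -> int:
        return len(self.manifest)

    def __iter__(self):
        return (row for _, row in self.manifest.iterrows())


@dataclass
class SinteringSchedule:
    """Linear ramp to a hold temperature, used when no furnace log exists.

    The furnace ramps from ``start_temperature_C`` at ``ramp_rate_C_per_min``
    and then holds at ``hold_temperature_C`` for ``hold_duration_min``.
    """

    start_temperature_C: float
    ramp_rate_C_per_min: float
    hold_temperature_C: float
    hold_duration_min: float = 120.0

    def __post_init__(self) -> None:
        if self.ramp_rate_C_per_min < 0:
            raise ValueError("ramp_rate_C_per_min must be >= 0")
        if self.hold_temperature_C < self.start_temperature_C:
            raise ValueError("hold_temperature_C must be >= start_temperature_C")


def temperature_at(schedule: SinteringSchedule, t_s: float) -> float:
    """Temperature (degrees C) at ``t_s`` seconds into the analysed phase.

    ``min(start + ramp_rate * t_min, hold_temperature)``; the temperature is
    non-decreasing in time and clipped at the hold temperature (the model
    does not include cool-down).
    """
    if t_s < 0:
        raise ValueError(f"time must be >= 0; got {t_s}")
    ramped = schedule.start_temperature_C + schedule.ramp_rate_C_per_min * (t_s / 60.0)
    return min(ramped, schedule.hold_temperature_C)


def _sorted_slice_paths(directory: Path) -> list[Path]:
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no TIFF slices found in directory {directory}")
    return paths


def read_scan_volume(
    path: str | Path,
    voxel_size_um: float,
    *,
    time_s: float = 0.0,
    temperature_C: float = float("nan"),
    scan_id: str = "",
) -> ScanVolume:
    """Read a multi-page TIFF or a directory of 2D TIFF slices as a volume.

    Slices of a directory are stacked in filename-sorted z order; a
    single-page TIFF becomes a ``(1, H, W)`` volume.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        slice_paths = _sorted_slice_paths(path)
        first = tifffile.imread(slice_paths[0])
        if first.ndim != 2:
            raise ValueError(f"expected 2D slices in {path}; got shape {first.shape}")
        voxels = np.empty((len(slice_paths),) + first.shape, dtype=first.dtype)
        voxels[0] = first
        for i, p in enumerate(slice_paths[1:], start=1):
            sl = tifffile.imread(p)
            if sl.shape != first.shape or sl.dtype != first.dtype:
                raise ValueError(
                    f"inconsistent slice {p.name}: shape {sl.shape} dtype {sl.dtype}, "
                    f"expected {first.shape} {first.dtype}"
                )
            voxels[i] = sl
    else:
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis, :, :]
        elif voxels.ndim != 3:
            raise ValueError(f"unsupported TIFF layout with ndim={voxels.ndim} in {path}")
    if not scan_id:
        scan_id = path.stem if not path.is_dir() else path.name
    return ScanVolume(
        voxels=voxels,
        voxel_size_um=voxel_size_um,
        time_s=time_s,
        temperature_C=temperature_C,
        scan_id=scan_id,
    )


def write_scan_volume(volume: ScanVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (bit-exact round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.voxels, photometric="minisblack")


def read_manifest(path: str | Path, volume_root: str | Path | None = None) -> ScanSeries:
    """Parse a scan manifest CSV into a time-sorted :class:`ScanSeries`.

    The file must carry a header with columns ``scan_id,time_s,temperature_C``.
    Rows are sorted by ``time_s``; duplicate scan ids or timestamps raise.
    When ``volume_root`` is given, ``<root>/<scan_id>`` or
    ``<root>/<scan_id>.tif(f)`` is recorded as the volume path per scan.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path, dtype={"scan_id": str})
    series = ScanSeries(manifest=df)
    if volume_root is not None:
        root = Path(volume_root)
        paths: dict[str, Path] = {}
        for sid in series.manifest["scan_id"]:
            for cand in (root / sid, root / f"{sid}.tif", root / f"{sid}.tiff"):
                if cand.exists():
                    paths[sid] = cand
                    break
        series.volume_paths = paths
    return series


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit TIFF stack (foreground 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D (z, y, x); got ndim={mask.ndim}")
    out = np.where(mask.astype(bool), np.uint8(255), np.uint8(0))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, out, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to boolean."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    return arr > 0


def warn_once(message: str) -> None:
    """Log and emit a UserWarning (single helper so callers stay terse)."""
    logger.warning(message)
    warnings.warn(message, UserWarning, stacklevel=3)


def series_from_rows(rows: Sequence[tuple[str, float, float]]) -> ScanSeries:
    """Build a ScanSeries from ``(scan_id, time_s, temperature_C)`` tuples."""
    return ScanSeries(manifest=pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)))
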