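"""Normalization of reconstructed volumes before detection and segmentation.

The raw reconstructions are large 16/32-bit grids. Before any macroscale
feature detection they are linearly rescaled to 8 bits, rotated so the strut
axes align with the image axes, cropped to the scaffold, and downsampled by
a factor of 0.25 with block-mean anti-aliasing. Inside extracted VOIs,
non-local-means denoising and global histogram equalization prepare the
intensities for voxel classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import restoration, transform

from .io_core import ScanVolume, warn_once


@dataclass
class PreprocessConfig:
    """Parameters of the normalization chain.

    ``rotation_deg`` is the in-plane rotation about z applied before
    cropping ("auto" estimates it from the strut orientation).
    ``crop_zyx`` holds half-open ``(start, stop)`` ranges per axis or None
    for the full extent. ``resample_factor`` scales each axis length
    (default 0.25). The non-local-means parameters follow common usage:
    patch radius 2, search radius 5, filtering strength 0.8 of the
    estimated noise sigma.
    """

    rotation_deg: float | str = 0.0
    crop_zyx: tuple[tuple[int, int] | None, tuple[int, int] | None, tuple[int, int] | None] = (
        None,
        None,
        None,
    )
    resample_factor: float = 0.25
    nlm_patch_radius: int = 2
    nlm_search_radius: int = 5
    nlm_strength: float = 0.8
    equalize: bool = True
    auto_angle_grid: tuple[float, float, float] = (-45.0, 45.0, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 < self.resample_factor <= 1.0):
            raise ValueError(f"resample_factor must be in (0, 1]; got {self.resample_factor}")


def convert_to_8bit(volume: ScanVolume) -> ScanVolume:
    """Linear min-max rescale of the whole volume onto [0, 255].

    Rounding is half-up. A constant volume has no dynamic range and maps to
    all zeros with a warning. The map is monotone: it never inverts contrast.
    """
    vox = volume.voxels
    if vox.dtype == np.uint8:
        return volume
    lo = float(vox.min())
    hi = float(vox.max())
    if hi == lo:
        warn_once(f"scan {volume.scan_id!r}: constant volume, zero dynamic range; mapped to 0")
        return volume.with_voxels(np.zeros(vox.shape, dtype=np.uint8))
    scaled = (vox.astype(np.float64) - lo) * (255.0 / (hi - lo))
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return volume.with_voxels(out)


def estimate_rotation(volume: ScanVolume, angle_grid: np.ndarray) -> float:
    """Estimate the in-plane rotation that axis-aligns the struts.

    For each candidate angle, the central slices are rotated and the
    variance of the intensity sums projected onto each in-plane axis is
    computed; axis-aligned struts concentrate mass into a few rows/columns
    and maximize that variance. Returns the angle (deg) to pass as
    ``rotation_deg``.
    """
    nz = volume.voxels.shape[0]
    picks = np.unique(np.clip([nz // 4, nz // 2, (3 * nz) // 4], 0, nz - 1))
    ref = volume.voxels[picks].astype(np.float32).mean(axis=0)
    best_angle, best_score = 0.0, -np.inf
    for ang in angle_grid:
        rot = ndimage.rotate(ref, ang, reshape=False, order=1, mode="constant", cval=float(ref.mean()))
        score = float(np.var(rot.sum(axis=0)) + np.var(rot.sum(axis=1)))
        if score > best_score:
            best_angle, best_score = float(ang), score
    return best_angle


def align_and_crop(volume: ScanVolume, config: PreprocessConfig) -> ScanVolume:
    """Rotate about z (fixed angle or "auto") then crop to the config ranges."""
    angle = config.rotation_deg
    if angle == "auto":
        lo, hi, step = config.auto_angle_grid
        angle = estimate_rotation(volume, np.arange(lo, hi + step / 2, step))
    angle = float(angle)
    vox = volume.voxels
    if angle != 0.0:
        vox = ndimage.rotate(vox, angle, axes=(1, 2), reshape=False, order=1)
        if volume.voxels.dtype == np.uint8:
            vox = np.clip(np.round(vox), 0, 255).astype(np.uint8)
    slices = []
    for ax, rng in enumerate(config.crop_zyx):
        if rng is None:
            slices.append(slice(None))
            continue
        start, stop = rng
        if not (0 <= start < stop <= vox.shape[ax]):
            raise ValueError(
                f"crop range {rng} outside bounds for axis {ax} of length {vox.shape[ax]}"
            )
        slices.append(slice(start, stop))
    return volume.with_voxels(vox[tuple(slices)])


def resampled_shape(shape: tuple[int, ...], factor: float) -> tuple[int, ...]:
    """Axis lengths after resampling: ``floor(n * factor)`` per axis."""
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"factor must be in (0, 1]; got {factor}")
    out = tuple(int(np.floor(n * factor)) for n in shape)
    if min(out) < 1:
        raise ValueError(f"factor {factor} produces a zero-length axis from shape {shape}")
    return out


def resample_quarter(volume: ScanVolume, factor: float | None = None) -> ScanVolume:
    """Anti-aliased downsampling of each axis by ``factor`` (default 0.25).

    For factors of the form 1/k the volume is cropped to a multiple of k and
    reduced by k-block local means (exact for constants and robust to noise);
    other factors fall back to anti-aliased resizing. ``voxel_size_um`` is
    divided by the factor so physical scale is preserved.
    """
    if factor is None:
        factor = 0.25
    target = resampled_shape(volume.voxels.shape, factor)
    if factor == 1.0:
        return volume
    inv = 1.0 / factor
    vox = volume.voxels
    if abs(inv - round(inv)) < 1e-9:
        k = int(round(inv))
        trimmed = vox[: target[0] * k, : target[1] * k, : target[2] * k]
        out = transform.downscale_local_mean(trimmed.astype(np.float64), (k, k, k))
    else:
        out = transform.resize(
            vox.astype(np.float64), target, order=1, anti_aliasing=True, preserve_range=True
        )
    if np.issubdtype(vox.dtype, np.integer):
        info = np.iinfo(vox.dtype)
        out = np.clip(np.floor(out + 0.5), info.min, info.max).astype(vox.dtype)
    else:
        out = out.astype(vox.dtype)
    return volume.with_voxels(out, voxel_size_um=volume.voxel_size_um / factor)


def denoise_nlm(volume: ScanVolume, config: PreprocessConfig | None = None) -> ScanVolume:
    """Non-local-means denoising of an 8-bit volume (shape preserved).

    Pixel values are replaced by weighted averages of similar patches; the
    filtering strength defaults to ``nlm_strength`` times a wavelet-based
    noise sigma estimate.
    """
    if config is None:
        config = PreprocessConfig()
    vox = volume.voxels
    patch = 2 * config.nlm_patch_radius + 1
    if patch > min(vox.shape):
        raise ValueError(f"patch size {patch} exceeds smallest volume extent {min(vox.shape)}")
    as_float = vox.astype(np.float32)
    sigma = float(restoration.estimate_sigma(as_float))
    if sigma <= 0:
        return volume.with_voxels(vox.copy())
    out = restoration.denoise_nl_means(
        as_float,
        patch_size=patch,
        patch_distance=2 * config.nlm_search_radius + 1,
        h=config.nlm_strength * sigma,
        sigma=sigma,
        fast_mode=True,
        preserve_range=True,
    )
    if vox.dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    else:
        out = out.astype(vox.dtype)
    return volume.with_voxels(out)


def equalize_histogram(volume: ScanVolume) -> ScanVolume:
    """Global histogram equalization of an 8-bit volume.

    Each intensity v maps to ``round(cdf(v) * 255)`` where cdf includes v's
    own bin, so the output cumulative histogram is approximately linear and
    the map is monotone (rank preserving).
    """
    vox = volume.voxels
    if vox.dtype != np.uint8:
        raise ValueError("equalize_histogram expects an 8-bit volume")
    hist = np.bincount(vox.ravel(), minlength=256).astype(np.float64)
    cdf = np.cumsum(hist) / vox.size
    lut = np.floor(cdf * 255.0 + 0.5).astype(np.uint8)
    return volume.with_voxels(lut[vox])
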