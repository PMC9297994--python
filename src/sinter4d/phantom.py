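"""Ground-truthed synthetic scaffolds and simulated sintering time series.

The phantom emulates a direct-ink-written woodpile scaffold: layers of
parallel cylindrical struts, alternating orientation between layers, each
strut packed with glass particles (spheres with a log-normal-like radius
distribution, placed with bounded overlap so the green body looks granular
but connected). A simulated sintering run then produces, per time point:

* densification — the particle indicator is smoothed with a growing
  Gaussian kernel and re-thresholded so that the glass fraction inside the
  strut core follows a programmed densification curve. Small gaps between
  particles close first (neck growth), then interconnected pores pinch off
  into isolated pores, then those disappear — the classical stage
  progression — while the glass fraction tracks the programme exactly by
  construction;
* shrinkage — the whole geometry contracts affinely toward the scaffold
  centroid along a per-axis linear-shrinkage schedule (anisotropy allowed);
* imaging — a two-level intensity model (glass vs background) with Gaussian
  blur, additive Gaussian noise and 8-bit clipping. At the default noise
  level the glass and pore intensity histograms overlap.

Every quantity the analysis pipeline later measures (density, strut
diameter, pore diagonal distance, segment centers) is also available as
exact ground truth, voxel-aligned with the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import ScanVolume, SinteringSchedule, temperature_at, warn_once

def core_margin(spec: "PhantomSpec") -> float:
    """Erosion depth (voxels) of the strut core used as the intrastrut support.

    The densification programme describes the strut interior (the region an
    inscribed child volume samples), away from the particle-scale surface
    roughness shell; the core keeps radii up to ``1/sqrt(2)`` of the strut
    radius, the circumradius of an inscribed half-diameter square.
    """
    r = spec.lattice.strut_diameter / 2.0
    return max(2.0, r * (1.0 - 1.0 / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class LatticeSpec:
    """Woodpile geometry in voxels (z is the axis of the tracked struts).

    ``surface_skin_px`` is a thin continuous glass shell at the strut wall,
    mimicking the smooth nozzle-formed surface of an extruded particle
    paste (the interior stays granular).
    """

    n_struts_per_layer: int = 4
    n_layers: int = 8
    pitch: float = 112.0
    layer_spacing: float = 40.0
    strut_diameter: float = 48.0
    surface_skin_px: float = 1.5

    def __post_init__(self) -> None:
        if self.pitch <= self.strut_diameter:
            raise ValueError("pitch must exceed the strut diameter")


@dataclass
class ParticleSpec:
    """Particle radius distribution (voxels) and packing target."""

    r_min: float = 2.5
    r_max: float = 9.0
    r_median: float = 4.5
    packing_fraction: float = 0.55
    overlap_factor: float = 0.5  # min center distance = factor * (r1 + r2)
    max_attempts: int = 200_000


@dataclass
class SinteringSpec:
    """Programmed densification and shrinkage of the simulated run."""

    n_time_points: int = 20
    density_start_pct: float = 55.0
    density_end_pct: float = 95.0
    curve: str = "logistic"  # or "linear"
    linear_shrinkage_zyx: tuple[float, float, float] = (0.08, 0.15, 0.15)
    neck_sigma_min: float = 0.6
    neck_sigma_max: float = 5.0
    scan_interval_s: float = 120.0

    def __post_init__(self) -> None:
        if self.density_end_pct < self.density_start_pct:
            raise ValueError("densification curve must be non-decreasing")
        if any(not (0.0 <= s < 1.0) for s in self.linear_shrinkage_zyx):
            raise ValueError("linear shrinkage must be in [0, 1)")
        if self.curve not in ("logistic", "linear"):
            raise ValueError(f"unknown curve {self.curve!r}")


@dataclass
class NoiseSpec:
    """Two-level imaging model: levels, blur and additive Gaussian noise."""

    glass_level: float = 180.0
    background_level: float = 60.0
    blur_sigma: float = 1.0
    sigma: float = 15.0


@dataclass
class PhantomSpec:
    """Complete description of a synthetic scan series (seed mandatory)."""

    seed: int
    shape_zyx: tuple[int, int, int] = (400, 512, 512)
    voxel_size_um: float = 0.81
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    particles: ParticleSpec = field(default_factory=ParticleSpec)
    sintering: SinteringSpec = field(default_factory=SinteringSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)


# ---------------------------------------------------------------------------
# densification / shrinkage schedules
# ---------------------------------------------------------------------------

def densification_curve(spec: SinteringSpec) -> np.ndarray:
    """Programmed relative density (%) per time point (non-decreasing)."""
    n = spec.n_time_points
    if n == 1:
        return np.array([spec.density_start_pct])
    if spec.curve == "logistic":
        x = np.linspace(-6.0, 6.0, n)
        f = 1.0 / (1.0 + np.exp(-x))
        f = (f - f[0]) / (f[-1] - f[0])
    else:
        f = np.linspace(0.0, 1.0, n)
    return spec.density_start_pct + f * (spec.density_end_pct - spec.density_start_pct)


def scale_factors(spec: SinteringSpec) -> np.ndarray:
    """Per-axis affine scale (z, y, x) per time point, following the curve."""
    d = densification_curve(spec)
    span = max(d[-1] - d[0], 1e-12)
    progress = (d - d[0]) / span
    shrink = np.asarray(spec.linear_shrinkage_zyx)
    return 1.0 - progress[:, None] * shrink[None, :]


def neck_sigmas(spec: SinteringSpec) -> np.ndarray:
    """Smoothing scale (voxels) of the densification operator per time point."""
    d = densification_curve(spec)
    span = max(d[-1] - d[0], 1e-12)
    progress = (d - d[0]) / span
    return spec.neck_sigma_min + progress * (spec.neck_sigma_max - spec.neck_sigma_min)


# ---------------------------------------------------------------------------
# lattice geometry
# ---------------------------------------------------------------------------

@dataclass
class StrutDef:
    """One cylindrical strut: axis 'z' (tracked family) or 'y' (crossing)."""

    axis: str
    center: tuple[float, float]  # (y, x) for z-struts, (z, x) for y-struts
    radius: float
    span: tuple[float, float]  # extent along the strut axis


@dataclass
class ScaffoldGeometry:
    struts: list[StrutDef]
    segment_centers: np.ndarray  # (n, 3) green-state centers of trackable segments
    centroid: np.ndarray  # (3,) lattice centroid, the shrinkage fixed point
    gap_length: float  # clean span between crossing struts along z
    crossing_z: np.ndarray


def lattice_geometry(spec: PhantomSpec) -> ScaffoldGeometry:
    """Place the woodpile struts and derive trackable segment centers.

    Even layers hold struts along z (the tracked family); odd layers hold
    struts along y that cross them. The trackable segments are the spans of
    the z-struts between consecutive crossings.
    """
    lat = spec.lattice
    Z, Y, X = spec.shape_zyx
    d = lat.strut_diameter
    r = d / 2.0
    x_span = (lat.n_layers - 1) * lat.layer_spacing + d
    y_span = (lat.n_struts_per_layer - 1) * lat.pitch + d
    if x_span > X or y_span > Y:
        raise ValueError("lattice exceeds requested volume bounds")
    x0 = (X - x_span) / 2.0 + r
    y0 = (Y - y_span) / 2.0 + r
    xs = [x0 + i * lat.layer_spacing for i in range(lat.n_layers)]
    ys = [y0 + j * lat.pitch for j in range(lat.n_struts_per_layer)]
    z0 = lat.pitch / 2.0
    zs_cross = np.array([z0 + k * lat.pitch for k in range(lat.n_struts_per_layer)])
    zs_cross = zs_cross[zs_cross < Z + r]
    z_min = max(zs_cross[0] - r, 0.0)
    z_max = min(zs_cross[-1] + r, float(Z))
    struts: list[StrutDef] = []
    for i, x in enumerate(xs):
        if i % 2 == 0:
            for y in ys:
                struts.append(StrutDef("z", (y, x), r, (z_min, z_max)))
        else:
            for zc in zs_cross:
                struts.append(StrutDef("y", (zc, x), r, (y0 - r, ys[-1] + r)))
    centers = []
    for k in range(len(zs_cross) - 1):
        lo, hi = zs_cross[k] + r, zs_cross[k + 1] - r
        zc = (zs_cross[k] + zs_cross[k + 1]) / 2.0
        if hi - lo < d / 2.0:
            continue
        for i, x in enumerate(xs):
            if i % 2 == 0:
                for y in ys:
                    centers.append((zc, y, x))
    centroid = np.array([(z_min + z_max) / 2.0, float(np.mean(ys)), float(np.mean(xs))])
    return ScaffoldGeometry(
        struts=struts,
        segment_centers=np.array(centers),
        centroid=centroid,
        gap_length=lat.pitch - d,
        crossing_z=zs_cross,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _rasterize_cylinders(
    shape: tuple[int, int, int],
    struts: list[StrutDef],
    scale: np.ndarray,
    centroid: np.ndarray,
    radius_margin: float = 0.0,
) -> np.ndarray:
    """Boolean union of the strut cylinders under an affine scale about the centroid."""
    out = np.zeros(shape, dtype=bool)
    sz, sy, sx = scale
    cz, cy, cx = centroid
    for s in struts:
        if s.axis == "z":
            y = cy + sy * (s.center[0] - cy)
            x = cx + sx * (s.center[1] - cx)
            ry, rx = s.radius * sy - radius_margin, s.radius * sx - radius_margin
            if min(ry, rx) <= 0:
                continue
            a0 = cz + sz * (s.span[0] - cz)
            a1 = cz + sz * (s.span[1] - cz)
            z_lo = max(int(np.floor(a0)), 0)
            z_hi = min(int(np.ceil(a1)) + 1, shape[0])
            y_lo = max(int(np.floor(y - ry)), 0)
            y_hi = min(int(np.ceil(y + ry)) + 1, shape[1])
            x_lo = max(int(np.floor(x - rx)), 0)
            x_hi = min(int(np.ceil(x + rx)) + 1, shape[2])
            yy = (np.arange(y_lo, y_hi) - y) / ry
            xx = (np.arange(x_lo, x_hi) - x) / rx
            disk = yy[:, None] ** 2 + xx[None, :] ** 2 <= 1.0
            out[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] |= disk[None, :, :]
        else:  # axis 'y'
            z = cz + sz * (s.center[0] - cz)
            x = cx + sx * (s.center[1] - cx)
            rz, rx = s.radius * sz - radius_margin, s.radius * sx - radius_margin
            if min(rz, rx) <= 0:
                continue
            a0 = cy + sy * (s.span[0] - cy)
            a1 = cy + sy * (s.span[1] - cy)
            y_lo = max(int(np.floor(a0)), 0)
            y_hi = min(int(np.ceil(a1)) + 1, shape[1])
            z_lo = max(int(np.floor(z - rz)), 0)
            z_hi = min(int(np.ceil(z + rz)) + 1, shape[0])
            x_lo = max(int(np.floor(x - rx)), 0)
            x_hi = min(int(np.ceil(x + rx)) + 1, shape[2])
            zz = (np.arange(z_lo, z_hi) - z) / rz
            xx = (np.arange(x_lo, x_hi) - x) / rx
            ellipse = zz[:, None] ** 2 + xx[None, :] ** 2 <= 1.0
            out[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] |= ellipse[:, None, :]
    return out


def _rasterize_particles(
    out: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    scale: np.ndarray,
    centroid: np.ndarray,
) -> None:
    """OR ellipsoids (spheres under per-axis scale) into ``out`` in place."""
    shape = out.shape
    scaled = centroid[None, :] + scale[None, :] * (centers - centroid[None, :])
    semis = radii[:, None] * scale[None, :]
    for (pz, py, px), (az, ay, ax) in zip(scaled, semis):
        z_lo = max(int(np.floor(pz - az)), 0)
        z_hi = min(int(np.ceil(pz + az)) + 1, shape[0])
        y_lo = max(int(np.floor(py - ay)), 0)
        y_hi = min(int(np.ceil(py + ay)) + 1, shape[1])
        x_lo = max(int(np.floor(px - ax)), 0)
        x_hi = min(int(np.ceil(px + ax)) + 1, shape[2])
        if z_lo >= z_hi or y_lo >= y_hi or x_lo >= x_hi:
            continue
        zz = ((np.arange(z_lo, z_hi) - pz) / az) ** 2
        yy = ((np.arange(y_lo, y_hi) - py) / ay) ** 2
        xx = ((np.arange(x_lo, x_hi) - px) / ax) ** 2
        ball = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0
        out[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] |= ball


# ---------------------------------------------------------------------------
# particle packing
# ---------------------------------------------------------------------------

def _sample_radii(p: ParticleSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal radii about the median, clipped to [r_min, r_max]."""
    sigma_ln = min(np.log(p.r_max / p.r_median), np.log(p.r_median / p.r_min)) / 2.5
    r = p.r_median * np.exp(rng.normal(0.0, sigma_ln, size=n))
    return np.clip(r, p.r_min, p.r_max)


class _CellList:
    """Uniform-grid neighbor lookup for bounded-overlap sphere placement."""

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.centers: list[np.ndarray] = []
        self.radii: list[float] = []

    def _key(self, c: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(v // self.cell) for v in c)  # type: ignore[return-value]

    def accepts(self, c: np.ndarray, r: float, factor: float) -> bool:
        kz, ky, kx = self._key(c)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for idx in self.cells.get((kz + dz, ky + dy, kx + dx), ()):
                        min_d = factor * (self.radii[idx] + r)
                        if np.dot(c - self.centers[idx], c - self.centers[idx]) < min_d * min_d:
                            return False
        return True

    def add(self, c: np.ndarray, r: float) -> None:
        self.cells.setdefault(self._key(c), []).append(len(self.centers))
        self.centers.append(c)
        self.radii.append(r)


def _pack_cylinder(
    strut: StrutDef,
    particles: ParticleSpec,
    rng: np.random.Generator,
    cell_list: _CellList,
    canvas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Place spheres around one strut cylinder until its measured fill hits target.

    Candidates are sampled well beyond the wall (the raster is clipped to
    the cylinder later) so the fill stays radially uniform; a sphere is
    accepted when no previously placed sphere is closer than
    ``overlap_factor * (r1 + r2)``. Accepted spheres are rasterized into
    ``canvas`` and the voxel fill inside the cylinder is re-measured after
    each batch; packing stops at the target fraction or, with a warning,
    when the attempt budget runs out (best effort).
    """
    r_cyl = strut.radius
    length = strut.span[1] - strut.span[0]
    cyl = _rasterize_cylinders(canvas.shape, [strut], np.ones(3), np.zeros(3))
    cyl_idx = np.nonzero(cyl)
    box = tuple(
        slice(int(i.min()), int(i.max()) + 1) for i in cyl_idx
    )
    cyl_box = cyl[box]
    n_cyl = int(cyl_box.sum())
    mean_vol = 4.0 / 3.0 * np.pi * particles.r_median**3 * 1.3
    r_sample = r_cyl + 2.0 * particles.r_max
    # only ~ (r_cyl / r_sample)^2 of accepted spheres land inside the wall
    yield_factor = (r_cyl / r_sample) ** 2
    centers, radii = [], []
    attempts = 0
    one = np.ones(3)
    zero = np.zeros(3)
    while attempts < particles.max_attempts:
        fill = float(canvas[box][cyl_box].sum()) / n_cyl
        if fill >= particles.packing_fraction:
            break
        deficit = (particles.packing_fraction - fill) * n_cyl
        batch_target = max(10, int(deficit / mean_vol / yield_factor * 0.6))
        got = 0
        batch_c, batch_r = [], []
        while got < batch_target and attempts < particles.max_attempts:
            attempts += 1
            rad = float(_sample_radii(particles, rng, 1)[0])
            rho = r_sample * np.sqrt(rng.uniform(0.0, 1.0))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            along = strut.span[0] + rng.uniform(0.0, 1.0) * length
            if strut.axis == "z":
                c = np.array(
                    [along, strut.center[0] + rho * np.sin(phi), strut.center[1] + rho * np.cos(phi)]
                )
            else:
                c = np.array(
                    [strut.center[0] + rho * np.sin(phi), along, strut.center[1] + rho * np.cos(phi)]
                )
            if not cell_list.accepts(c, rad, particles.overlap_factor):
                continue
            cell_list.add(c, rad)
            got += 1
            if rho < r_cyl + rad:  # touches the cylinder: worth rasterizing
                batch_c.append(c)
                batch_r.append(rad)
        if batch_c:
            _rasterize_particles(
                canvas, np.array(batch_c), np.array(batch_r), one, zero
            )
            centers.extend(batch_c)
            radii.extend(batch_r)
    else:
        fill = float(canvas[box][cyl_box].sum()) / n_cyl
    if fill < particles.packing_fraction - 0.03:
        warn_once(
            f"packing fraction {particles.packing_fraction:.2f} not reached in "
            f"{particles.max_attempts} attempts; best effort ({fill:.2f})"
        )
    return np.array(centers).reshape(-1, 3), np.array(radii)


# ---------------------------------------------------------------------------
# phantom objects
# ---------------------------------------------------------------------------

@dataclass
class GreenStrut:
    """Single particle-packed strut with its ground-truth masks."""

    glass_mask: np.ndarray
    strut_mask: np.ndarray
    particle_centers: np.ndarray
    particle_radii: np.ndarray
    achieved_fraction: float


@dataclass
class ScaffoldPhantom:
    """Green (as-printed) scaffold: geometry plus all particle positions."""

    spec: PhantomSpec
    geometry: ScaffoldGeometry
    particle_centers: np.ndarray
    particle_radii: np.ndarray

    def green_mask(self) -> np.ndarray:
        """Rasterized green glass (particles plus surface skin, clipped to struts)."""
        scale = np.ones(3)
        mask = np.zeros(self.spec.shape_zyx, dtype=bool)
        _rasterize_particles(mask, self.particle_centers, self.particle_radii, scale, self.geometry.centroid)
        struts = _rasterize_cylinders(
            self.spec.shape_zyx, self.geometry.struts, scale, self.geometry.centroid
        )
        skin = self.spec.lattice.surface_skin_px
        if skin > 0:
            inner = _rasterize_cylinders(
                self.spec.shape_zyx, self.geometry.struts, scale, self.geometry.centroid,
                radius_margin=skin,
            )
            mask |= struts & ~inner
        mask &= struts
        return mask


@dataclass
class PhantomTimePoint:
    """One simulated scan with voxel-aligned ground truth."""

    time_index: int
    image: ScanVolume
    glass_mask: np.ndarray
    strut_mask: np.ndarray
    core_mask: np.ndarray
    segment_centers: np.ndarray
    true_density_pct: float
    true_diameter_px: float
    true_pdd_px: float
    scale_zyx: tuple[float, float, float]


@dataclass
class PhantomSeries:
    """Materialized simulated series (small phantoms; use the simulator for large ones)."""

    spec: PhantomSpec
    entries: list[PhantomTimePoint]

    def __len__(self) -> int:
        return len(self.entries)


def generate_green_strut(
    spec: PhantomSpec, length: float | None = None
) -> GreenStrut:
    """Particle-packed single strut (cylinder along z) with truth masks."""
    lat = spec.lattice
    r = lat.strut_diameter / 2.0
    length = float(length if length is not None else 3 * lat.strut_diameter)
    pad = 4.0
    shape = (int(np.ceil(length)), int(np.ceil(2 * (r + pad))), int(np.ceil(2 * (r + pad))))
    strut = StrutDef("z", (r + pad, r + pad), r, (0.0, length))
    rng = np.random.default_rng([spec.seed, 11])
    cell = _CellList(cell=2.0 * spec.particles.r_max)
    canvas = np.zeros(shape, dtype=bool)
    centers, radii = _pack_cylinder(strut, spec.particles, rng, cell, canvas)
    scale = np.ones(3)
    centroid = np.zeros(3)
    strut_mask = _rasterize_cylinders(shape, [strut], scale, centroid)
    glass = canvas
    # packing fraction refers to the particle fill alone, before the skin
    achieved = float((glass & strut_mask).sum() / max(strut_mask.sum(), 1))
    if spec.lattice.surface_skin_px > 0:
        inner = _rasterize_cylinders(
            shape, [strut], scale, centroid, radius_margin=spec.lattice.surface_skin_px
        )
        glass |= strut_mask & ~inner
    glass &= strut_mask
    return GreenStrut(
        glass_mask=glass,
        strut_mask=strut_mask,
        particle_centers=centers,
        particle_radii=radii,
        achieved_fraction=achieved,
    )


def generate_scaffold_phantom(spec: PhantomSpec) -> ScaffoldPhantom:
    """Green woodpile scaffold: lattice plus per-strut particle packings."""
    geometry = lattice_geometry(spec)
    rng = np.random.default_rng([spec.seed, 1])
    cell = _CellList(cell=2.0 * spec.particles.r_max)
    canvas = np.zeros(spec.shape_zyx, dtype=bool)
    all_centers, all_radii = [], []
    for strut in geometry.struts:
        centers, radii = _pack_cylinder(strut, spec.particles, rng, cell, canvas)
        if len(centers):
            all_centers.append(centers)
            all_radii.append(radii)
    return ScaffoldPhantom(
        spec=spec,
        geometry=geometry,
        particle_centers=np.concatenate(all_centers, axis=0),
        particle_radii=np.concatenate(all_radii, axis=0),
    )


def apply_imaging_noise(
    glass_mask: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Two-level image from a glass mask: blur, additive noise, 8-bit clip."""
    img = np.where(glass_mask, np.float32(noise.glass_level), np.float32(noise.background_level))
    if noise.blur_sigma > 0:
        ndimage.gaussian_filter(img, noise.blur_sigma, output=img, truncate=3.0)
    if noise.sigma > 0:
        img += noise.sigma * rng.standard_normal(img.shape, dtype=np.float32)
    np.clip(img, 0.0, 255.0, out=img)
    return (img + 0.5).astype(np.uint8)


def _bbox_of(mask: np.ndarray, pad: int) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, n))
        for i, n in zip(idx, mask.shape)
    )


class SinteringSimulator:
    """Lazy renderer of the simulated sintering series.

    Holds the green phantom and the programmed schedules; ``time_point(t)``
    renders one scan plus its ground truth on demand, so a full-size series
    never needs to live in memory at once.
    """

    def __init__(self, phantom: ScaffoldPhantom, include_noise: bool = True):
        self.phantom = phantom
        self.spec = phantom.spec
        self.include_noise = include_noise
        self.densities = densification_curve(self.spec.sintering)
        self.scales = scale_factors(self.spec.sintering)
        self.sigmas = neck_sigmas(self.spec.sintering)
        self.schedule = SinteringSchedule(
            start_temperature_C=500.0, ramp_rate_C_per_min=3.0, hold_temperature_C=690.0
        )

    @property
    def n_time_points(self) -> int:
        return self.spec.sintering.n_time_points

    def time_point(self, t: int) -> PhantomTimePoint:
        spec = self.spec
        geom = self.phantom.geometry
        scale = self.scales[t]
        target = self.densities[t]
        sigma = self.sigmas[t]

        strut_mask = _rasterize_cylinders(spec.shape_zyx, geom.struts, scale, geom.centroid)
        core_mask = _rasterize_cylinders(
            spec.shape_zyx, geom.struts, scale, geom.centroid, radius_margin=core_margin(spec)
        )
        # densification support: strut cores away from layer crossings, where
        # two packings meet and the fill is structurally denser
        r = spec.lattice.strut_diameter / 2.0
        cz = geom.centroid[0]
        keep_z = np.ones(spec.shape_zyx[0], dtype=bool)
        for zc in geom.crossing_z:
            zs = cz + scale[0] * (zc - cz)
            half = r * scale[0] + 2.0
            keep_z[max(int(np.floor(zs - half)), 0) : int(np.ceil(zs + half)) + 1] = False
        core_mask &= keep_z[:, None, None]
        green = np.zeros(spec.shape_zyx, dtype=bool)
        _rasterize_particles(
            green, self.phantom.particle_centers, self.phantom.particle_radii, scale, geom.centroid
        )
        skin = spec.lattice.surface_skin_px
        if skin > 0:
            inner = _rasterize_cylinders(
                spec.shape_zyx, geom.struts, scale, geom.centroid,
                radius_margin=skin * float((scale[1] + scale[2]) / 2.0),
            )
            green |= strut_mask & ~inner
            del inner
        box = _bbox_of(strut_mask, pad=int(np.ceil(3 * sigma)) + 2)
        blurred = np.zeros(spec.shape_zyx, dtype=np.float32)
        sub = green[box].astype(np.float32)
        ndimage.gaussian_filter(sub, sigma, output=sub, truncate=2.5)
        blurred[box] = sub
        del sub, green
        core_vals = blurred[core_mask]
        thr = float(np.quantile(core_vals, 1.0 - target / 100.0))
        glass = (blurred >= thr) & strut_mask
        del blurred, core_vals
        true_density = 100.0 * float((glass & core_mask).sum()) / float(core_mask.sum())

        centers = geom.centroid[None, :] + scale[None, :] * (
            geom.segment_centers - geom.centroid[None, :]
        )
        # voxel-aligned truth: equivalent-circle diameter of the rasterized
        # axial-strut cross-section at the (crossing-free) segment slices
        n_axial = sum(1 for s in geom.struts if s.axis == "z")
        z_slices = np.unique(np.clip(np.round(centers[:, 0]).astype(int), 0, spec.shape_zyx[0] - 1))
        area = float(strut_mask[z_slices].sum()) / (len(z_slices) * n_axial)
        true_diameter = float(2.0 * np.sqrt(area / np.pi))
        dy = spec.lattice.pitch * scale[1]
        dx = 2.0 * spec.lattice.layer_spacing * scale[2]
        true_pdd = float(np.hypot(dy, dx) - true_diameter)

        time_s = t * spec.sintering.scan_interval_s
        if self.include_noise:
            rng = np.random.default_rng([spec.seed, 7, t])
            img = apply_imaging_noise(glass, spec.noise, rng)
        else:
            img = np.where(glass, np.uint8(spec.noise.glass_level), np.uint8(spec.noise.background_level))
        volume = ScanVolume(
            voxels=img,
            voxel_size_um=spec.voxel_size_um,
            time_s=time_s,
            temperature_C=temperature_at(self.schedule, time_s),
            scan_id=f"scan_{t:03d}",
        )
        return PhantomTimePoint(
            time_index=t,
            image=volume,
            glass_mask=glass,
            strut_mask=strut_mask,
            core_mask=core_mask,
            segment_centers=centers,
            true_density_pct=true_density,
            true_diameter_px=true_diameter,
            true_pdd_px=true_pdd,
            scale_zyx=tuple(float(s) for s in scale),
        )


def simulate_sintering_series(
    phantom: ScaffoldPhantom, include_noise: bool = False
) -> PhantomSeries:
    """Materialize the whole simulated series (intended for small phantoms)."""
    sim = SinteringSimulator(phantom, include_noise=include_noise)
    return PhantomSeries(
        spec=phantom.spec, entries=[sim.time_point(t) for t in range(sim.n_time_points)]
    )


def add_imaging_noise(series: PhantomSeries, spec: PhantomSpec | None = None) -> PhantomSeries:
    """Re-render the images of a clean series with the imaging noise model.

    Ground truth is untouched; with a fixed seed the noise field is
    reproducible. ``sigma = 0`` and ``blur_sigma = 0`` leave images unchanged.
    """
    spec = spec or series.spec
    entries = []
    for e in series.entries:
        rng = np.random.default_rng([spec.seed, 7, e.time_index])
        img = apply_imaging_noise(e.glass_mask, spec.noise, rng)
        volume = e.image.with_voxels(img)
        entries.append(
            PhantomTimePoint(
                time_index=e.time_index,
                image=volume,
                glass_mask=e.glass_mask,
                strut_mask=e.strut_mask,
                core_mask=e.core_mask,
                segment_centers=e.segment_centers,
                true_density_pct=e.true_density_pct,
                true_diameter_px=e.true_diameter_px,
                true_pdd_px=e.true_pdd_px,
                scale_zyx=e.scale_zyx,
            )
        )
    return PhantomSeries(spec=spec, entries=entries)


def ground_truth_report(series: PhantomSeries | list[PhantomTimePoint]) -> pd.DataFrame:
    """Per-time-point truth table: the recovery targets for validation."""
    entries = series.entries if isinstance(series, PhantomSeries) else series
    rows = []
    for e in entries:
        rows.append(
            {
                "time_index": e.time_index,
                "time_s": e.image.time_s,
                "temperature_C": e.image.temperature_C,
                "true_density_pct": e.true_density_pct,
                "true_diameter_px": e.true_diameter_px,
                "true_pdd_px": e.true_pdd_px,
                "n_segments": len(e.segment_centers),
            }
        )
    return pd.DataFrame(rows)
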