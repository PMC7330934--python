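"""Particle analysis: exclusion, labelling, area filtering, regions, sampling, density.

Turns a binary chromogen mask into counted objects and region-stratified
densities in cells/mm². Components are 8-connected by default (configurable),
areas are converted to μm² through the image calibration, and the default
inclusion interval keeps areas in [8, 300] μm² with both endpoints included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import ValidationError
from .io_calibration import BasalLineAnnotation, CalibratedImage, ExclusionMask
from .stain_separation import otsu_threshold

__all__ = [
    "Particle",
    "ParticleSet",
    "AreaInterval",
    "RegionSpec",
    "FieldSample",
    "apply_exclusion",
    "label_particles",
    "filter_by_area",
    "nucleus_filter",
    "depth_band_regions",
    "sample_hpfs",
    "particles_in_fields",
    "particles_in_region",
    "compute_density",
    "calibrate_area_range",
]


@dataclass(frozen=True)
class Particle:
    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    touches_field_border: bool
    has_nucleus: bool | None = None


@dataclass(frozen=True)
class ParticleSet:
    """Labelled connected components with their source calibration."""

    particles: tuple[Particle, ...]
    microns_per_pixel: float
    connectivity: int
    label_image: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        labels = [p.label for p in self.particles]
        if len(labels) != len(set(labels)):
            raise ValidationError("particle labels must be unique")
        object.__setattr__(self, "particles", tuple(self.particles))

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.asarray([p.area_um2 for p in self.particles], dtype=float)


@dataclass(frozen=True)
class AreaInterval:
    """Inclusive μm² area interval for particle inclusion."""

    min_um2: float
    max_um2: float

    def __post_init__(self):
        if not (0 <= self.min_um2 < self.max_um2):
            raise ValidationError(
                f"need 0 <= min < max, got [{self.min_um2}, {self.max_um2}]"
            )

    def contains(self, area_um2: float) -> bool:
        return self.min_um2 <= area_um2 <= self.max_um2


@dataclass(frozen=True)
class RegionSpec:
    """Named pixel region with its physical area in mm²."""

    name: str
    mask: np.ndarray
    area_mm2: float

    @classmethod
    def from_mask(
        cls, name: str, mask: np.ndarray, microns_per_pixel: float
    ) -> "RegionSpec":
        mask = np.asarray(mask, dtype=bool)
        area_mm2 = float(mask.sum()) * microns_per_pixel**2 / 1e6
        return cls(name=name, mask=mask, area_mm2=area_mm2)


@dataclass(frozen=True)
class FieldSample:
    """Randomly sampled high-power-field rectangles, (row, col, height, width)."""

    rectangles: tuple[tuple[int, int, int, int], ...]
    seed: int
    field_area_mm2: float

    @property
    def total_area_mm2(self) -> float:
        return self.field_area_mm2 * len(self.rectangles)


def apply_exclusion(mask: np.ndarray, exclusion: ExclusionMask) -> np.ndarray:
    """Remove excluded pixels: output is True where mask is True and exclusion False."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != exclusion.shape:
        raise ValidationError(
            f"mask shape {mask.shape} != exclusion shape {exclusion.shape}"
        )
    return mask & ~exclusion.grid


def label_particles(
    mask: np.ndarray,
    microns_per_pixel: float,
    connectivity: int = 8,
) -> ParticleSet:
    """Label connected components with exact pixel counts and μm² areas.

    ``connectivity`` is 8 (diagonal neighbours connect, the ImageJ particle
    default) or 4.
    """
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError(f"binary mask must be 2-D, got shape {mask.shape}")
    skimage_conn = 2 if connectivity == 8 else 1
    lab = sk_label(mask, connectivity=skimage_conn)
    h, w = mask.shape
    particles = []
    for rp in regionprops(lab):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        particles.append(
            Particle(
                label=int(rp.label),
                area_px=int(rp.area),
                area_um2=float(rp.area) * microns_per_pixel**2,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                touches_field_border=touches,
            )
        )
    return ParticleSet(
        particles=tuple(particles),
        microns_per_pixel=microns_per_pixel,
        connectivity=connectivity,
        label_image=lab,
    )


def filter_by_area(particles: ParticleSet, interval: AreaInterval) -> ParticleSet:
    """Keep particles whose μm² area lies in the inclusive interval; order preserved."""
    kept = tuple(p for p in particles.particles if interval.contains(p.area_um2))
    return replace(particles, particles=kept)


def nucleus_filter(
    particles: ParticleSet,
    counterstain: np.ndarray,
    overlap_fraction_min: float = 0.2,
) -> ParticleSet:
    """Keep particles overlapping counterstained (nuclear) pixels.

    A particle has a nucleus when at least ``overlap_fraction_min`` of its
    pixels, after a 1-px dilation, exceed the counterstain channel's Otsu
    threshold. With ``overlap_fraction_min = 0`` every particle passes.
    Requires the originating label image.
    """
    if particles.label_image is None:
        raise ValidationError("nucleus_filter needs a ParticleSet with a label image")
    counterstain = np.asarray(counterstain, dtype=float)
    if counterstain.shape != particles.label_image.shape:
        raise ValidationError(
            f"counterstain shape {counterstain.shape} does not match label image "
            f"shape {particles.label_image.shape}"
        )
    thr = otsu_threshold(counterstain)
    nuclear = np.clip(counterstain, 0.0, None) > thr
    structure = np.ones((3, 3), dtype=bool)
    kept = []
    for p in particles.particles:
        blob = particles.label_image == p.label
        blob = ndimage.binary_dilation(blob, structure=structure)
        frac = nuclear[blob].mean()
        has_nuc = bool(frac >= overlap_fraction_min)
        if has_nuc:
            kept.append(replace(p, has_nucleus=True))
    return replace(particles, particles=tuple(kept))


def _rasterize_polyline(
    annotation: BasalLineAnnotation, shape: tuple[int, int]
) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    verts = np.rint(annotation.vertices).astype(int)
    for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        grid[rr, cc] = True
    return grid


def _line_row_per_column(line_grid: np.ndarray) -> np.ndarray:
    """Mean line row per column, extended to unspanned columns by interpolation."""
    h, w = line_grid.shape
    counts = line_grid.sum(axis=0)
    rows = np.arange(h, dtype=float)
    sums = (line_grid * rows[:, None]).sum(axis=0)
    cols = np.arange(w)
    filled = counts > 0
    if not filled.any():
        raise ValidationError("rasterized basal line is empty")
    means = np.where(filled, sums / np.maximum(counts, 1), np.nan)
    return np.interp(cols, cols[filled], means[filled])


def depth_band_regions(
    annotation: BasalLineAnnotation,
    image: CalibratedImage,
    bands: list[tuple[float, float]],
    names: list[str] | None = None,
) -> list[RegionSpec]:
    """Build depth-band region masks measured from the basal polyline.

    For each ``(lo_um, hi_um)`` band, the mask holds the pixels on the dermal
    side whose Euclidean distance to the rasterized polyline (distance
    transform, converted to μm) lies in ``[lo_um, hi_um)``. Depth 0 is the
    line itself, so adjacent bands partition the dermal strip.
    """
    annotation.check_in_bounds(image.shape)
    for lo, hi in bands:
        if not lo < hi:
            raise ValidationError(f"band bounds must satisfy lo < hi, got ({lo}, {hi})")
    spans = sorted(bands)
    for (_, hi_a), (lo_b, _) in zip(spans[:-1], spans[1:]):
        if lo_b < hi_a:
            raise ValidationError(f"bands overlap: {spans}")
    line = _rasterize_polyline(annotation, image.shape)
    dist_um = ndimage.distance_transform_edt(~line) * image.microns_per_pixel
    line_row = _line_row_per_column(line)
    rows = np.arange(image.shape[0], dtype=float)[:, None]
    if annotation.tissue_side == "below":
        dermal = rows >= line_row[None, :]
    else:
        dermal = rows <= line_row[None, :]
    if names is None:
        names = [f"band_{lo:g}_{hi:g}" for lo, hi in bands]
    regions = []
    for name, (lo, hi) in zip(names, bands):
        mask = dermal & (dist_um >= lo) & (dist_um < hi)
        regions.append(RegionSpec.from_mask(name, mask, image.microns_per_pixel))
    return regions


def sample_hpfs(
    region: RegionSpec,
    n: int,
    field_shape_px: tuple[int, int],
    seed: int,
    microns_per_pixel: float,
) -> FieldSample:
    """Draw ``n`` field rectangles at random positions centred in the region.

    Candidate top-left positions are those for which the rectangle fits
    inside the image and its centre pixel lies in the region mask; ``n`` are
    drawn without replacement with a seeded generator, so the sample is
    deterministic given (region, n, shape, seed).
    """
    if n < 1:
        raise ValidationError("need n >= 1 fields")
    h_img, w_img = region.mask.shape
    fh, fw = int(field_shape_px[0]), int(field_shape_px[1])
    if fh < 1 or fw < 1 or fh > h_img or fw > w_img:
        raise ValidationError(
            f"field shape {(fh, fw)} does not fit inside image {(h_img, w_img)}"
        )
    # top-left (r, c) valid iff centre pixel (r + fh//2, c + fw//2) is in the region
    centre_window = region.mask[
        fh // 2 : h_img - fh + fh // 2 + 1, fw // 2 : w_img - fw + fw // 2 + 1
    ]
    candidates = np.argwhere(centre_window)
    if len(candidates) < n:
        raise ValidationError(
            f"only {len(candidates)} candidate field positions available, need {n}"
        )
    rng = np.random.default_rng(seed)
    picks = candidates[rng.choice(len(candidates), size=n, replace=False)]
    rects = tuple((int(r), int(c), fh, fw) for r, c in picks)
    field_area_mm2 = fh * fw * microns_per_pixel**2 / 1e6
    return FieldSample(rectangles=rects, seed=seed, field_area_mm2=field_area_mm2)


def particles_in_fields(particles: ParticleSet, fields: FieldSample) -> ParticleSet:
    """Keep particles whose centroid lies inside a sampled field, counted once."""
    kept = []
    for p in particles.particles:
        cr, cc = p.centroid
        for r, c, h, w in fields.rectangles:
            if r <= cr < r + h and c <= cc < c + w:
                kept.append(p)
                break
    return replace(particles, particles=tuple(kept))


def particles_in_region(particles: ParticleSet, region: RegionSpec) -> ParticleSet:
    """Keep particles whose (rounded) centroid pixel lies inside the region mask."""
    h, w = region.mask.shape
    kept = []
    for p in particles.particles:
        r = min(max(int(round(p.centroid[0])), 0), h - 1)
        c = min(max(int(round(p.centroid[1])), 0), w - 1)
        if region.mask[r, c]:
            kept.append(p)
    return replace(particles, particles=tuple(kept))


def compute_density(
    particles: ParticleSet, sampled_area_mm2: float
) -> tuple[int, float]:
    """Return (count, density in cells/mm²) for an already-filtered ParticleSet."""
    if sampled_area_mm2 <= 0:
        raise ValidationError(
            f"sampled_area_mm2 must be positive, got {sampled_area_mm2}"
        )
    n = len(particles)
    return n, n / sampled_area_mm2


def calibrate_area_range(
    confirmed_cell_areas_um2,
    lo_quantile: float = 0.0,
    hi_quantile: float = 1.0,
) -> AreaInterval:
    """Empirical-quantile area interval from confirmed cell areas.

    With quantiles (0, 1) this is simply (min, max). A degenerate interval
    (equal bounds) is rejected.
    """
    areas = np.asarray(list(confirmed_cell_areas_um2), dtype=float)
    if areas.size < 2:
        raise ValidationError("need at least 2 confirmed cell areas")
    if not (0 <= lo_quantile < hi_quantile <= 1):
        raise ValidationError(
            f"need 0 <= lo < hi <= 1, got ({lo_quantile}, {hi_quantile})"
        )
    lo, hi = np.quantile(areas, [lo_quantile, hi_quantile])
    if lo == hi:
        raise ValidationError(
            f"degenerate interval [{lo}, {hi}] from supplied areas"
        )
    return AreaInterval(min_um2=float(lo), max_um2=float(hi))
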