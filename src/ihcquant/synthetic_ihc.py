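"""Synthetic brightfield-IHC scene generator with exact ground truth.

Scenes are rendered in optical-density space (Beer–Lambert additive
absorbance, matching the deconvolution model) and converted back to 8-bit
RGB, so recall tests exercise the analysis pipeline rather than the physics.
Each scene carries a per-pixel label image, per-object truth records, and a
ready-made exclusion mask covering the oversized distractors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .errors import PackingError, ValidationError
from .io_calibration import BasalLineAnnotation, CalibratedImage, ExclusionMask
from .stain_separation import FAST_RED_OD, HEMATOXYLIN_OD, od_to_rgb
from .agreement_stats import RatingsTable

__all__ = [
    "SceneSpec",
    "ObjectTruth",
    "GroundTruth",
    "generate_scene",
    "basal_annotation",
    "generate_ratings",
]

CELL = "cell"
DISTRACTOR = "distractor"
SPECK = "speck"
ANUCLEATE = "anucleate_focus"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; identical spec + seed → identical output."""

    height: int = 512
    width: int = 512
    microns_per_pixel: float = 1.0
    n_cells: int = 30
    cell_area_log_mean: float = float(np.log(60.0))  # lognormal location, μm²
    cell_area_log_sigma: float = 0.5
    cell_area_range: tuple[float, float] = (8.0, 300.0)
    n_distractors: int = 5
    distractor_area_range: tuple[float, float] = (450.0, 1200.0)
    n_specks: int = 10
    speck_area_range: tuple[float, float] = (1.5, 6.5)
    n_anucleate_foci: int = 0
    basal_line: dict | None = None  # e.g. {"kind": "straight", "row": 40}
    chromogen_od: tuple[float, float, float] = FAST_RED_OD
    counterstain_od: tuple[float, float, float] = HEMATOXYLIN_OD
    chromogen_intensity_range: tuple[float, float] = (0.9, 1.1)
    counterstain_intensity: float = 0.8
    cell_axis_ratio_range: tuple[float, float] = (1.0, 2.0)
    nucleus_area_fraction: float = 0.4
    noise_sd: float = 0.02
    max_placement_attempts: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValidationError("scene must be at least 8x8 pixels")
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be positive")
        for name in ("n_cells", "n_distractors", "n_specks", "n_anucleate_foci"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.cell_area_range
        if not 0 < lo < hi:
            raise ValidationError(f"invalid cell_area_range {self.cell_area_range}")
        if self.cell_area_log_sigma <= 0:
            raise ValidationError("cell_area_log_sigma must be positive")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValidationError("nucleus_area_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SceneSpec":
        known = {f: payload[f] for f in payload if f in cls.__dataclass_fields__}
        for key in ("cell_area_range", "distractor_area_range", "speck_area_range",
                    "chromogen_od", "counterstain_od", "chromogen_intensity_range",
                    "cell_axis_ratio_range"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ObjectTruth:
    label: int
    category: str
    centroid: tuple[float, float]
    area_um2: float  # exact rendered pixel area * μm²/px²
    target_area_um2: float  # sampled (pre-rasterization) area
    region: str
    has_nucleus: bool


@dataclass(frozen=True)
class GroundTruth:
    objects: tuple[ObjectTruth, ...]
    label_image: np.ndarray = field(repr=False)
    appendage_mask: ExclusionMask = field(repr=False)

    def by_category(self, category: str) -> tuple[ObjectTruth, ...]:
        return tuple(o for o in self.objects if o.category == category)

    def count(self, category: str) -> int:
        return len(self.by_category(category))

    def to_dict(self) -> dict:
        return {
            "objects": [asdict(o) for o in self.objects],
            "counts": {
                c: self.count(c) for c in (CELL, DISTRACTOR, SPECK, ANUCLEATE)
            },
        }


def basal_annotation(spec: SceneSpec) -> BasalLineAnnotation | None:
    """Build the basal-membrane polyline described by the scene spec, if any."""
    geom = spec.basal_line
    if geom is None:
        return None
    kind = geom.get("kind", "straight")
    row = float(geom.get("row", spec.height // 8))
    if kind == "straight":
        verts = [[row, 0.0], [row, float(spec.width - 1)]]
    elif kind == "sinusoidal":
        amp = float(geom.get("amplitude", 10.0))
        period = float(geom.get("period", 128.0))
        cols = np.arange(0, spec.width, 4, dtype=float)
        if cols[-1] != spec.width - 1:
            cols = np.append(cols, spec.width - 1)
        rows = row + amp * np.sin(2 * np.pi * cols / period)
        rows = np.clip(rows, 0, spec.height - 1)
        verts = np.stack([rows, cols], axis=1).tolist()
    else:
        raise ValidationError(f"unknown basal line kind {kind!r}")
    return BasalLineAnnotation(vertices=np.asarray(verts), tissue_side="below")


def _ellipse_pixels(rng, area_px, ratio_range, shape, rotation=None):
    """Pixel coordinates of a random-orientation ellipse of ~area_px pixels."""
    ratio = rng.uniform(*ratio_range)
    minor = np.sqrt(area_px / (np.pi * ratio))
    major = ratio * minor
    theta = rng.uniform(0, np.pi) if rotation is None else rotation
    margin = int(np.ceil(major)) + 2
    if shape[0] - margin <= margin or shape[1] - margin <= margin:
        return None, None, None
    r0 = rng.integers(margin, shape[0] - margin)
    c0 = rng.integers(margin, shape[1] - margin)
    rr, cc = draw_ellipse(r0, c0, major, minor, shape=shape, rotation=theta)
    return rr, cc, (r0, c0, major, minor, theta)


def _speck_pixels(rng, area_px, shape):
    radius = max(np.sqrt(area_px / np.pi), 0.6)
    margin = int(np.ceil(radius)) + 2
    r0 = rng.integers(margin, shape[0] - margin)
    c0 = rng.integers(margin, shape[1] - margin)
    rr, cc = draw_disk((r0, c0), radius, shape=shape)
    return rr, cc


def _free(occupied, rr, cc):
    """True when the footprint plus a 2-px guard ring touches nothing placed yet."""
    r_lo = max(rr.min() - 2, 0)
    r_hi = min(rr.max() + 3, occupied.shape[0])
    c_lo = max(cc.min() - 2, 0)
    c_hi = min(cc.max() + 3, occupied.shape[1])
    window = occupied[r_lo:r_hi, c_lo:c_hi]
    if not window.any():
        return True
    local = np.zeros_like(window)
    local[rr - r_lo, cc - c_lo] = True
    grown = ndimage.binary_dilation(local, structure=np.ones((5, 5), dtype=bool))
    return not (grown & window).any()


def _sample_cell_area(rng, spec: SceneSpec) -> float:
    lo, hi = spec.cell_area_range
    for _ in range(1000):
        a = float(rng.lognormal(spec.cell_area_log_mean, spec.cell_area_log_sigma))
        if lo < a < hi:
            return a
    raise ValidationError(
        "cell-area distribution incompatible with its truncation range"
    )


def generate_scene(spec: SceneSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render a scene and its ground truth.

    Objects are placed without overlap by rejection sampling; a
    :class:`PackingError` reports the achieved count when the canvas is too
    crowded. Rendered (pixel-count) areas are the authoritative truth areas,
    and cells are re-sampled until their rendered area sits safely inside the
    inclusion range so that rasterization cannot flip an object's class.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    mpp2 = spec.microns_per_pixel**2
    occupied = np.zeros(shape, dtype=bool)
    label_image = np.zeros(shape, dtype=np.int32)
    od = np.zeros((*shape, 3), dtype=np.float64)
    chrom = np.asarray(spec.chromogen_od, dtype=float)
    chrom = chrom / np.linalg.norm(chrom)
    counter = np.asarray(spec.counterstain_od, dtype=float)
    counter = counter / np.linalg.norm(counter)

    lo_cell, hi_cell = spec.cell_area_range
    objects: list[ObjectTruth] = []
    next_label = 1
    plan = (
        [(DISTRACTOR, None)] * spec.n_distractors
        + [(CELL, None)] * spec.n_cells
        + [(ANUCLEATE, None)] * spec.n_anucleate_foci
        + [(SPECK, None)] * spec.n_specks
    )

    for category, _ in plan:
        placed = False
        for _ in range(spec.max_placement_attempts):
            if category == CELL or category == ANUCLEATE:
                target = _sample_cell_area(rng, spec)
                rr, cc, geom = _ellipse_pixels(
                    rng, target / mpp2, spec.cell_axis_ratio_range, shape
                )
                ok_area = (
                    rr is not None
                    and 1.1 * lo_cell <= len(rr) * mpp2 <= 0.9 * hi_cell
                )
            elif category == DISTRACTOR:
                target = float(rng.uniform(*spec.distractor_area_range))
                rr, cc, geom = _ellipse_pixels(rng, target / mpp2, (3.0, 6.0), shape)
                ok_area = rr is not None and len(rr) * mpp2 >= 1.2 * hi_cell
            else:  # speck
                target = float(rng.uniform(*spec.speck_area_range))
                rr, cc = _speck_pixels(rng, target / mpp2, shape)
                geom = None
                ok_area = len(rr) > 0 and len(rr) * mpp2 <= 0.85 * lo_cell
            if not ok_area or not _free(occupied, rr, cc):
                continue
            amp = float(rng.uniform(*spec.chromogen_intensity_range))
            od[rr, cc] += amp * chrom
            occupied[rr, cc] = True
            label_image[rr, cc] = next_label
            has_nucleus = False
            if category == CELL and geom is not None:
                r0, c0, major, minor, theta = geom
                scale = np.sqrt(spec.nucleus_area_fraction)
                nr, nc = draw_ellipse(
                    r0, c0, major * scale, minor * scale, shape=shape, rotation=theta
                )
                od[nr, nc] += spec.counterstain_intensity * counter
                has_nucleus = True
            objects.append(
                ObjectTruth(
                    label=next_label,
                    category=category,
                    centroid=(float(np.mean(rr)), float(np.mean(cc))),
                    area_um2=len(rr) * mpp2,
                    target_area_um2=target,
                    region="",
                    has_nucleus=has_nucleus,
                )
            )
            next_label += 1
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place all objects; achieved {len(objects)} of {len(plan)}",
                achieved=len(objects),
            )

    if spec.noise_sd > 0:
        od += rng.normal(0.0, spec.noise_sd, size=od.shape)
    image = CalibratedImage(
        pixels=od_to_rgb(np.clip(od, 0.0, None)),
        microns_per_pixel=spec.microns_per_pixel,
    )

    appendage = np.zeros(shape, dtype=bool)
    for obj in objects:
        if obj.category == DISTRACTOR:
            appendage |= label_image == obj.label
    if appendage.any():
        appendage = ndimage.binary_dilation(appendage, iterations=3)
    truth = GroundTruth(
        objects=tuple(objects),
        label_image=label_image,
        appendage_mask=ExclusionMask(grid=appendage, provenance="generator"),
    )
    annotation = basal_annotation(spec)
    if annotation is not None:
        truth = _assign_regions(truth, annotation, spec)
    return image, truth


def _assign_regions(
    truth: GroundTruth, annotation: BasalLineAnnotation, spec: SceneSpec
) -> GroundTruth:
    from .particle_quant import depth_band_regions  # local import: avoid cycle

    image = CalibratedImage(
        pixels=np.zeros((spec.height, spec.width, 3), dtype=np.uint8),
        microns_per_pixel=spec.microns_per_pixel,
    )
    regions = depth_band_regions(
        annotation,
        image,
        bands=[(0.0, 296.0), (296.0, 1184.0)],
        names=["subepidermal", "deep_dermal"],
    )
    assigned = []
    for obj in truth.objects:
        r = min(max(int(round(obj.centroid[0])), 0), spec.height - 1)
        c = min(max(int(round(obj.centroid[1])), 0), spec.width - 1)
        name = ""
        for region in regions:
            if region.mask[r, c]:
                name = region.name
                break
        assigned.append(replace(obj, region=name))
    return replace(truth, objects=tuple(assigned))


def generate_ratings(
    n_specimens: int,
    k_raters: int,
    sigma_between: float,
    sigma_within: float,
    mean: float,
    seed: int,
) -> RatingsTable:
    """Simulate a specimens x raters count matrix with known variance components.

    ``count_ij = round(max(0, mean + b_i + e_ij))`` with
    ``b_i ~ N(0, sigma_between²)`` and ``e_ij ~ N(0, sigma_within²)``, so the
    population ICC is ``σ_b² / (σ_b² + σ_w²)`` up to rounding.
    """
    if n_specimens < 2 or k_raters < 2:
        raise ValidationError("need n >= 2 specimens and k >= 2 raters")
    if sigma_between < 0 or sigma_within < 0:
        raise ValidationError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_between, size=(n_specimens, 1))
    e = rng.normal(0.0, sigma_within, size=(n_specimens, k_raters))
    counts = np.round(np.maximum(0.0, mean + b + e))
    return RatingsTable.from_array(counts)
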