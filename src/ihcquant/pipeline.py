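"""Pipeline orchestration: configuration and the fixed quantification stage order.

Stage order: deconvolve → binarize → exclusion → label → (optional nucleus
filter) → area filter → regions/HPFs → density. Every parameter is echoed
into the run log so results are reproducible from their own metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_calibration import (
    BasalLineAnnotation,
    CalibratedImage,
    ExclusionMask,
    QuantResultRow,
)
from .particle_quant import (
    AreaInterval,
    RegionSpec,
    apply_exclusion,
    compute_density,
    depth_band_regions,
    filter_by_area,
    label_particles,
    nucleus_filter,
    particles_in_fields,
    particles_in_region,
    sample_hpfs,
)
from .stain_separation import (
    StainMatrix,
    binarize,
    deconvolve,
    default_stain_matrix,
    otsu_threshold,
    rgb_to_od,
)

__all__ = ["RunConfig", "run_quantify"]

_DEFAULT_STAINS = default_stain_matrix()


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; serializes losslessly to/from JSON.

    Defaults follow the published protocol where it states them: inclusion
    interval [8, 300] μm², depth bands (0, 296) and (296, 1184) μm, 5 HPFs.
    The HPF pixel size has no defensible default (field dimensions depend on
    the scanner) and must be set explicitly to enable field sampling.
    """

    stain_names: tuple[str, str, str] = _DEFAULT_STAINS.names
    stain_vectors: tuple = tuple(map(tuple, _DEFAULT_STAINS.vectors.tolist()))
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    threshold_floor: float = 0.1
    area_min_um2: float = 8.0
    area_max_um2: float = 300.0
    connectivity: int = 8
    bands: tuple = ((0.0, 296.0), (296.0, 1184.0))
    band_names: tuple = ("subepidermal", "deep_dermal")
    hpf_n: int = 5
    hpf_size_px: tuple[int, int] | None = None
    nucleus_filter_enabled: bool = False
    nucleus_overlap_min: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError(
                f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}"
            )
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("threshold_method 'fixed' requires fixed_threshold")
        if len(self.bands) != len(self.band_names):
            raise ValidationError("bands and band_names must have equal length")
        object.__setattr__(self, "stain_names", tuple(self.stain_names))
        object.__setattr__(
            self, "stain_vectors", tuple(tuple(float(x) for x in v) for v in self.stain_vectors)
        )
        object.__setattr__(
            self, "bands", tuple((float(lo), float(hi)) for lo, hi in self.bands)
        )
        object.__setattr__(self, "band_names", tuple(self.band_names))
        if self.hpf_size_px is not None:
            object.__setattr__(
                self, "hpf_size_px", (int(self.hpf_size_px[0]), int(self.hpf_size_px[1]))
            )

    @property
    def stain_matrix(self) -> StainMatrix:
        return StainMatrix(names=self.stain_names, vectors=np.asarray(self.stain_vectors))

    @property
    def area_interval(self) -> AreaInterval:
        return AreaInterval(min_um2=self.area_min_um2, max_um2=self.area_max_um2)

    def to_dict(self) -> dict:
        return {
            "stain_names": list(self.stain_names),
            "stain_vectors": [list(v) for v in self.stain_vectors],
            "threshold_method": self.threshold_method,
            "fixed_threshold": self.fixed_threshold,
            "threshold_floor": self.threshold_floor,
            "area_min_um2": self.area_min_um2,
            "area_max_um2": self.area_max_um2,
            "connectivity": self.connectivity,
            "bands": [list(b) for b in self.bands],
            "band_names": list(self.band_names),
            "hpf_n": self.hpf_n,
            "hpf_size_px": list(self.hpf_size_px) if self.hpf_size_px else None,
            "nucleus_filter_enabled": self.nucleus_filter_enabled,
            "nucleus_overlap_min": self.nucleus_overlap_min,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                payload = tomllib.load(fh)
        else:
            with open(path) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)


def _build_regions(
    config: RunConfig,
    image: CalibratedImage,
    basal: BasalLineAnnotation | None,
    region_names: list[str] | None,
) -> list[RegionSpec]:
    if basal is not None:
        regions = depth_band_regions(
            basal, image, bands=list(config.bands), names=list(config.band_names)
        )
    else:
        full = np.ones(image.shape, dtype=bool)
        regions = [RegionSpec.from_mask("granulation", full, image.microns_per_pixel)]
    if region_names:
        known = {r.name: r for r in regions}
        missing = [n for n in region_names if n not in known]
        if missing:
            raise ValidationError(
                f"unknown region(s) {missing}; available: {sorted(known)}"
            )
        regions = [known[n] for n in region_names]
    return regions


def run_quantify(
    config: RunConfig,
    image: CalibratedImage,
    exclusion: ExclusionMask | None = None,
    basal: BasalLineAnnotation | None = None,
    region_names: list[str] | None = None,
    specimen: str = "specimen",
) -> tuple[list[QuantResultRow], dict]:
    """Run the full quantification pipeline on one calibrated image.

    Returns one result row per region plus a JSON-serializable log of every
    parameter, threshold and intermediate count. Without HPF sampling
    (``config.hpf_size_px is None``) densities are pooled over the whole
    region; with it, counts are pooled over the sampled fields and per-field
    counts are reported in the log.
    """
    stains = config.stain_matrix
    od = rgb_to_od(image)
    concentrations = deconvolve(od, stains)
    chrom_idx = stains.index_of("chromogen") if "chromogen" in stains.names else 1
    chrom = concentrations[:, :, chrom_idx]
    if config.threshold_method == "fixed":
        threshold = float(config.fixed_threshold)
    else:
        # floor guards against Otsu splitting background noise on stain-free images
        threshold = max(otsu_threshold(chrom), config.threshold_floor)
    mask = binarize(chrom, method="fixed", fixed_threshold=threshold)
    if exclusion is not None:
        mask = apply_exclusion(mask, exclusion)
    particles = label_particles(
        mask, image.microns_per_pixel, connectivity=config.connectivity
    )
    n_labelled = len(particles)
    if config.nucleus_filter_enabled:
        counter_idx = (
            stains.index_of("hematoxylin") if "hematoxylin" in stains.names else 0
        )
        particles = nucleus_filter(
            particles,
            concentrations[:, :, counter_idx],
            overlap_fraction_min=config.nucleus_overlap_min,
        )
    particles = filter_by_area(particles, config.area_interval)

    regions = _build_regions(config, image, basal, region_names)
    threshold_label = f"{config.threshold_method}:{threshold:.6g}"
    rows: list[QuantResultRow] = []
    region_logs = []
    for idx, region in enumerate(regions):
        if config.hpf_size_px is not None:
            fields = sample_hpfs(
                region,
                config.hpf_n,
                config.hpf_size_px,
                seed=config.seed + idx,
                microns_per_pixel=image.microns_per_pixel,
            )
            in_region = particles_in_fields(particles, fields)
            n, density = compute_density(in_region, fields.total_area_mm2)
            per_field = []
            for r, c, h, w in fields.rectangles:
                cnt = sum(
                    1
                    for p in in_region.particles
                    if r <= p.centroid[0] < r + h and c <= p.centroid[1] < c + w
                )
                per_field.append(
                    {"rect": [r, c, h, w], "n_cells": cnt,
                     "density_per_mm2": cnt / fields.field_area_mm2}
                )
            area_mm2 = fields.total_area_mm2
            region_logs.append(
                {"region": region.name, "n_cells": n, "sampled_area_mm2": area_mm2,
                 "fields": per_field}
            )
        else:
            in_region = particles_in_region(particles, region)
            n, density = compute_density(in_region, region.area_mm2)
            area_mm2 = region.area_mm2
            region_logs.append(
                {"region": region.name, "n_cells": n, "sampled_area_mm2": area_mm2}
            )
        rows.append(
            QuantResultRow(
                specimen=specimen,
                region=region.name,
                n_cells=n,
                sampled_area_mm2=area_mm2,
                density_per_mm2=density,
                area_min_um2=config.area_min_um2,
                area_max_um2=config.area_max_um2,
                threshold=threshold_label,
                seed=config.seed,
            )
        )
    log = {
        "config": config.to_dict(),
        "specimen": specimen,
        "image_shape": list(image.shape),
        "microns_per_pixel": image.microns_per_pixel,
        "threshold_value": threshold,
        "n_particles_labelled": n_labelled,
        "n_particles_after_filters": len(particles),
        "exclusion_applied": exclusion is not None,
        "regions": region_logs,
    }
    return rows, log
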