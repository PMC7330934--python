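"""Optical-density colour deconvolution and binarization.

Stain absorbances combine approximately additively in optical-density (OD)
space, so per-pixel inversion of the linear mixing system ``OD = c @ M``
(rows of ``M`` are unit stain vectors) recovers per-stain concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .io_calibration import CalibratedImage

__all__ = [
    "OD_EPSILON",
    "OD_I0",
    "StainMatrix",
    "default_stain_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "remix",
    "otsu_threshold",
    "binarize",
]

#: Guard added to intensities before the log, and implicitly to I0 so that a
#: pure-white pixel maps to exactly zero OD.
OD_EPSILON = 1.0 / 255.0
#: Incident-light intensity for 8-bit data.
OD_I0 = 255.0

#: Harris hematoxylin OD direction (Ruifrok & Johnston catalogue).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
#: Alkaline-phosphatase "fast red"-type chromogen OD direction.
FAST_RED_OD = (0.214, 0.851, 0.478)

_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class StainMatrix:
    """Named unit OD direction vectors for up to three stains.

    ``vectors`` is a 3x3 float array whose *rows* are the stain directions,
    each with unit Euclidean norm and non-negative entries.
    """

    names: tuple[str, str, str]
    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValidationError(f"stain matrix must be 3x3, got {v.shape}")
        if np.any(v < -1e-12):
            raise ValidationError("stain vectors must have non-negative entries")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms <= 0):
            raise ValidationError("stain vectors must be nonzero")
        v = v / norms[:, None]
        if np.linalg.cond(v) > _MAX_CONDITION:
            raise ValidationError("stain matrix is singular or near-singular")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "names", tuple(self.names))

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(
                f"no stain named {name!r}; available: {self.names}"
            ) from None


def default_stain_matrix() -> StainMatrix:
    """Hematoxylin counterstain + fast-red chromogen + orthogonal residual."""
    h = np.asarray(HEMATOXYLIN_OD, dtype=float)
    r = np.asarray(FAST_RED_OD, dtype=float)
    residual = np.cross(h, r)
    residual = np.abs(residual)  # keep entries non-negative
    residual /= np.linalg.norm(residual)
    return StainMatrix(
        names=("hematoxylin", "chromogen", "residual"),
        vectors=np.stack([h, r, residual]),
    )


def rgb_to_od(image: CalibratedImage | np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density per channel.

    ``OD_c = -log10((I_c + eps) / (I0 + eps))`` with ``I0 = 255`` and
    ``eps = 1/255``; white maps to the zero vector exactly, black to the
    maximum finite OD, and OD decreases monotonically with intensity.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    px = px.astype(np.float64)
    od = -np.log10((px + OD_EPSILON) / (OD_I0 + OD_EPSILON))
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, rounding to 8-bit intensities."""
    intensity = (OD_I0 + OD_EPSILON) * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(intensity - OD_EPSILON), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Solve the per-pixel mixing system, returning H x W x n_stain concentrations.

    Concentrations may be negative where noise pushes a pixel outside the
    stain simplex; they are stored unclipped so the round trip
    ``remix(deconvolve(od)) == od`` holds to numerical tolerance.
    """
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValidationError(f"OD image must be H x W x 3, got shape {od.shape}")
    m = stains.vectors
    if np.linalg.cond(m) > _MAX_CONDITION:
        raise ValidationError("stain matrix is singular; cannot deconvolve")
    inv = np.linalg.inv(m)
    # OD_pixel = c @ M  =>  c = OD_pixel @ M^-1
    return od @ inv


def remix(concentrations: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Recompose an OD image from per-stain concentrations."""
    return np.asarray(concentrations, dtype=np.float64) @ stains.vectors


def otsu_threshold(channel: np.ndarray) -> float:
    """Otsu threshold of the non-negative part of a concentration channel."""
    vals = np.asarray(channel, dtype=float)
    vals = vals[np.isfinite(vals)]
    vals = np.clip(vals, 0.0, None)
    if vals.size == 0 or vals.max() == vals.min():
        raise ValidationError(
            "channel is constant; Otsu is undefined — use a fixed threshold"
        )
    return float(threshold_otsu(vals))


def binarize(
    channel: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    otsu_floor: float = 0.0,
) -> np.ndarray:
    """Threshold a concentration channel into a boolean stained-pixel mask.

    Negative concentrations are treated as zero here (and only here); the
    mask is True strictly above the threshold. ``otsu_floor`` lower-bounds
    the Otsu threshold: on a chromogen-free image Otsu would otherwise split
    the background noise itself, so pipelines pass a small floor (in
    concentration units) below which nothing counts as stained.
    """
    if method not in ("otsu", "fixed"):
        raise ValidationError(f"unknown binarization method {method!r}")
    vals = np.clip(np.asarray(channel, dtype=float), 0.0, None)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValidationError("method 'fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        thr = max(otsu_threshold(vals), float(otsu_floor))
    return vals > thr
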