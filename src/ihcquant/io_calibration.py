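"""Image, mask and annotation I/O, plus the physical calibration model.

Every downstream area computation hangs on :class:`CalibratedImage`, which
pairs an 8-bit RGB pixel grid with an isotropic micron-per-pixel scale.
Pixel coordinates are (row, col), 0-based, origin at the top-left pixel.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError

__all__ = [
    "CalibratedImage",
    "ExclusionMask",
    "BasalLineAnnotation",
    "QuantResultRow",
    "read_image",
    "read_mask",
    "write_mask",
    "read_annotation",
    "write_annotation",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class CalibratedImage:
    """8-bit RGB image with an isotropic physical calibration.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Channel intensities in [0, 255].
    microns_per_pixel : float
        Physical edge length of one pixel in micrometres; must be positive.
    """

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"expected an H x W x 3 pixel grid, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValidationError(
                    f"pixel values must be 8-bit integers in [0, 255], got dtype {px.dtype}"
                )
        object.__setattr__(self, "pixels", px)
        mpp = float(self.microns_per_pixel)
        if not np.isfinite(mpp) or mpp <= 0:
            raise ValidationError(
                f"microns_per_pixel must be a positive finite number, got {self.microns_per_pixel!r}"
            )
        object.__setattr__(self, "microns_per_pixel", mpp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def physical_area_um2(self) -> float:
        """Total physical area of the image, H * W * (um/px)^2."""
        h, w = self.shape
        return h * w * self.microns_per_pixel**2


@dataclass(frozen=True)
class ExclusionMask:
    """Boolean grid of pixels to drop before counting (True = excluded)."""

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(f"exclusion mask must be 2-D, got shape {g.shape}")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class BasalLineAnnotation:
    """Polyline marking the basal membrane, with the dermal side stated.

    ``tissue_side`` is ``"below"`` when rows larger than the line are dermal,
    ``"above"`` for the opposite convention.
    """

    vertices: np.ndarray  # (N, 2) float array of (row, col)
    tissue_side: str = "below"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValidationError(
                "basal line needs at least 2 (row, col) vertices, "
                f"got array of shape {v.shape}"
            )
        if self.tissue_side not in ("below", "above"):
            raise ValidationError(
                f"tissue_side must be 'below' or 'above', got {self.tissue_side!r}"
            )
        object.__setattr__(self, "vertices", v)

    def check_in_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() > h - 1 or c.max() > w - 1:
            raise ValidationError(
                f"basal line vertices fall outside the {h}x{w} image bounds"
            )


@dataclass(frozen=True)
class QuantResultRow:
    """One counted region of one specimen, with the parameters that produced it."""

    specimen: str
    region: str
    n_cells: int
    sampled_area_mm2: float
    density_per_mm2: float
    area_min_um2: float
    area_max_um2: float
    threshold: str
    seed: int

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be non-negative")
        if self.sampled_area_mm2 <= 0:
            raise ValidationError("sampled_area_mm2 must be positive")
        expected = self.n_cells / self.sampled_area_mm2
        if not np.isclose(self.density_per_mm2, expected, rtol=1e-9, atol=1e-12):
            raise ValidationError(
                f"density {self.density_per_mm2} inconsistent with "
                f"{self.n_cells}/{self.sampled_area_mm2} = {expected}"
            )


RESULT_COLUMNS = [
    "specimen",
    "region",
    "n_cells",
    "sampled_area_mm2",
    "density_per_mm2",
    "area_min_um2",
    "area_max_um2",
    "threshold",
    "seed",
]


def read_image(path: str | Path, microns_per_pixel: float) -> CalibratedImage:
    """Read an 8-bit TIFF or PNG as a calibrated RGB image.

    Greyscale inputs are promoted to RGB by channel triplication; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    if not (
        np.isscalar(microns_per_pixel)
        and np.isfinite(microns_per_pixel)
        and microns_per_pixel > 0
    ):
        raise ValidationError(
            f"microns_per_pixel must be positive, got {microns_per_pixel!r}"
        )
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding backends vary
        raise IOError(f"could not decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"unsupported image shape {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        raise ValidationError(
            f"{path} is not 8-bit (dtype {arr.dtype}); only 8-bit images are supported"
        )
    return CalibratedImage(pixels=arr, microns_per_pixel=float(microns_per_pixel))


def read_mask(path: str | Path, expected_shape: tuple[int, int]) -> ExclusionMask:
    """Read a single-channel mask PNG; nonzero pixels are excluded."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not decode mask file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # tolerate RGB(A) masks by collapsing identical channels
        arr = arr[..., :3].max(axis=2)
    if arr.ndim != 2:
        raise ValidationError(f"mask {path} is not single-channel (shape {arr.shape})")
    if tuple(arr.shape) != tuple(expected_shape):
        raise ValidationError(
            f"mask shape {tuple(arr.shape)} does not match image shape "
            f"{tuple(expected_shape)}"
        )
    return ExclusionMask(grid=arr != 0, provenance=str(path))


def write_mask(mask: ExclusionMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (255 = excluded)."""
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_annotation(path: str | Path) -> BasalLineAnnotation:
    """Read a basal-line JSON annotation: {"vertices": [[r,c],...], "tissue_side": ...}."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if "vertices" not in payload:
        raise ValidationError(f"annotation {path} lacks a 'vertices' key")
    return BasalLineAnnotation(
        vertices=np.asarray(payload["vertices"], dtype=float),
        tissue_side=payload.get("tissue_side", "below"),
    )


def write_annotation(annotation: BasalLineAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "vertices": annotation.vertices.tolist(),
                "tissue_side": annotation.tissue_side,
            },
            fh,
            indent=2,
        )


def write_results(rows: list[QuantResultRow], path: str | Path) -> None:
    """Write result rows as CSV; round-trips losslessly through read_results."""
    if not rows:
        raise ValidationError("write_results requires at least one row")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.specimen,
                    row.region,
                    row.n_cells,
                    repr(row.sampled_area_mm2),
                    repr(row.density_per_mm2),
                    repr(row.area_min_um2),
                    repr(row.area_max_um2),
                    row.threshold,
                    row.seed,
                ]
            )


def read_results(path: str | Path) -> list[QuantResultRow]:
    """Read a result CSV written by :func:`write_results`."""
    rows: list[QuantResultRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != RESULT_COLUMNS:
            raise ValidationError(
                f"unexpected result columns {reader.fieldnames} in {path}"
            )
        for rec in reader:
            rows.append(
                QuantResultRow(
                    specimen=rec["specimen"],
                    region=rec["region"],
                    n_cells=int(rec["n_cells"]),
                    sampled_area_mm2=float(rec["sampled_area_mm2"]),
                    density_per_mm2=float(rec["density_per_mm2"]),
                    area_min_um2=float(rec["area_min_um2"]),
                    area_max_um2=float(rec["area_max_um2"]),
                    threshold=rec["threshold"],
                    seed=int(rec["seed"]),
                )
            )
    if not rows:
        raise ValidationError(f"result file {path} contains no rows")
    return rows
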