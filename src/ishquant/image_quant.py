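"""Densitometry of chromogenic ISH signal in embryo images.

The measurement pipeline mirrors the standard ImageJ workflow for
quantifying whole-mount in situ hybridisation staining: each image is
inverted to negative (dark stain becomes high intensity) and converted
to 8-bit grayscale; a hand-drawn polygon ROI over the stained tissue and
an equal-area background ROI over unstained tissue are each reduced to
their mean pixel intensity; the embryo's score is signal mean minus
background mean. The subtraction removes uniform illumination offsets,
and can legitimately produce a (rare) negative score when the chosen
background region is darker than the signal region — such scores are
flagged but retained.

Pixel conventions: 0-based coordinates, x = column, y = row. A pixel
(x, y) belongs to a polygon ROI iff its center (x+0.5, y+0.5) lies
inside the polygon under the even-odd rule; boundary ties follow the
half-open ray-casting convention (top/left edges in).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "Roi",
    "IntensityMeasurement",
    "DegenerateRoiError",
    "UnequalAreaError",
    "to_grayscale_8bit",
    "invert",
    "rasterize",
    "mean_intensity",
    "score_embryo",
    "translate_roi",
    "batch_convert",
    "read_roi_file",
    "write_roi_file",
    "read_image",
    "write_image",
    "measurements_to_frame",
]

logger = logging.getLogger(__name__)

# ImageJ's RGB->8-bit default is the unweighted channel mean; ITU-R BT.601
# luminance weights are available as an option.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateRoiError(ValueError):
    """ROI rasterizes to an empty pixel mask."""


class UnequalAreaError(ValueError):
    """Signal and background ROI areas differ beyond the tolerance."""


@dataclass(frozen=True)
class Roi:
    """A simple polygon in pixel coordinates (x = column, y = row)."""

    label: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"ROI {self.label!r} needs >= 3 vertices")
        object.__setattr__(self, "vertices", verts)


@dataclass(frozen=True)
class IntensityMeasurement:
    """Per-embryo densitometry record: score = signal mean - background mean."""

    embryo_id: str
    signal_mean: float
    background_mean: float

    @property
    def score(self) -> float:
        return self.signal_mean - self.background_mean

    @property
    def negative(self) -> bool:
        return self.score < 0


def to_grayscale_8bit(
    img: np.ndarray, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale (unweighted channel mean).

    Rounds half-to-even to the nearest integer, matching numpy's rint.
    Already-grayscale input passes through unchanged. Pass
    ``weights=LUMINANCE_WEIGHTS`` for the weighted conversion.
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")
    rgb = arr[..., :3].astype(np.float64)
    if weights is None:
        gray = rgb.mean(axis=2)
    else:
        w = np.asarray(weights, dtype=np.float64)
        gray = rgb @ (w / w.sum())
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def invert(img: np.ndarray) -> np.ndarray:
    """Photographic negative of an 8-bit image: v -> 255 - v."""
    arr = np.asarray(img)
    return (255 - arr.astype(np.int16)).clip(0, 255).astype(np.uint8)


def rasterize(roi: Roi, height: int, width: int) -> np.ndarray:
    """Boolean pixel mask of the ROI on a height x width raster.

    Even-odd (crossing-number) containment evaluated at pixel centers,
    vectorized over all pixels; half-open edge treatment makes abutting
    polygons partition pixels without overlap.
    """
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    px, py = np.meshgrid(xs, ys)
    inside = np.zeros((height, width), dtype=bool)
    verts = roi.vertices
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # Edge crosses the horizontal ray through the pixel center iff the
        # endpoints straddle it (half-open in y); toggle parity at crossings
        # left of the center.
        straddles = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
        inside ^= straddles & (px > x_cross)
    if not inside.any():
        raise DegenerateRoiError(
            f"ROI {roi.label!r} covers no pixel on a {height}x{width} image"
        )
    return inside


def mean_intensity(img: np.ndarray, roi: Roi) -> float:
    """Mean pixel intensity under the ROI mask, in full float precision."""
    arr = np.asarray(img)
    mask = rasterize(roi, arr.shape[0], arr.shape[1])
    return float(arr[mask].mean())


def translate_roi(roi: Roi, dx: float, dy: float, label: str | None = None) -> Roi:
    """Clone the ROI translated by (dx, dy) — guarantees equal area."""
    return Roi(
        label or f"{roi.label}+({dx},{dy})",
        tuple((x + dx, y + dy) for x, y in roi.vertices),
    )


def score_embryo(
    img: np.ndarray,
    signal: Roi,
    background: Roi,
    embryo_id: str = "",
    area_tolerance: float = 0.01,
) -> IntensityMeasurement:
    """Background-subtracted mean intensity of the signal ROI.

    The two ROIs must have (near-)equal rasterized areas — the background
    region is meant to be the same shape and size as the signal region —
    within ``area_tolerance`` (fraction of the signal area, default 1%).
    Negative scores are legitimate output, flagged via the record.
    """
    arr = np.asarray(img)
    h, w = arr.shape[0], arr.shape[1]
    sig_mask = rasterize(signal, h, w)
    bg_mask = rasterize(background, h, w)
    a_sig, a_bg = int(sig_mask.sum()), int(bg_mask.sum())
    if abs(a_sig - a_bg) / a_sig > area_tolerance:
        raise UnequalAreaError(
            f"signal area {a_sig} vs background area {a_bg} differs by "
            f"more than {area_tolerance:.1%}"
        )
    m = IntensityMeasurement(
        embryo_id=embryo_id,
        signal_mean=float(arr[sig_mask].mean()),
        background_mean=float(arr[bg_mask].mean()),
    )
    if m.negative:
        logger.warning(
            "embryo %s: background exceeds signal (score %.2f)",
            embryo_id or "<unnamed>",
            m.score,
        )
    return m


# ---------------------------------------------------------------------------
# Batch conversion and I/O

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit array (HxW or HxWx3)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB" if "A" in im.mode or im.mode == "P" else "L")
        return np.asarray(im)


def write_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(img)).save(path)


def batch_convert(input_dir: str | Path, output_dir: str | Path) -> int:
    """Invert + grayscale-convert every image in a directory.

    The batch analogue of the per-image preprocessing step: every readable
    PNG/TIFF in ``input_dir`` is written to ``output_dir`` under the same
    stem, ready for ROI measurement. Non-image files are skipped with a
    warning. Returns the number of images converted.
    """
    in_dir, out_dir = Path(input_dir), Path(output_dir)
    if not in_dir.is_dir():
        raise IOError(f"input directory not readable: {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    count = 0
    for path in sorted(in_dir.iterdir()):
        if not path.is_file():
            continue
        if path.suffix.lower() not in _IMAGE_SUFFIXES:
            logger.warning("skipping non-image file %s", path.name)
            continue
        try:
            img = read_image(path)
        except (UnidentifiedImageError, OSError):
            logger.warning("skipping unreadable image %s", path.name)
            continue
        write_image(invert(to_grayscale_8bit(img)), out_dir / path.name)
        count += 1
    return count


def read_roi_file(path: str | Path) -> list[dict]:
    """Read ROI JSON: one record or a list of records per file.

    Each record: {"embryo_id": ..., "signal": [[x, y], ...],
    "background": [[x, y], ...]}.
    """
    with open(path) as fh:
        data = json.load(fh)
    records = data if isinstance(data, list) else [data]
    out = []
    for rec in records:
        out.append(
            {
                "embryo_id": str(rec["embryo_id"]),
                "signal": Roi("signal", tuple(map(tuple, rec["signal"]))),
                "background": Roi(
                    "background", tuple(map(tuple, rec["background"]))
                ),
            }
        )
    return out


def write_roi_file(records: Iterable[dict], path: str | Path) -> None:
    payload = [
        {
            "embryo_id": rec["embryo_id"],
            "signal": [list(v) for v in rec["signal"].vertices],
            "background": [list(v) for v in rec["background"].vertices],
        }
        for rec in records
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def measurements_to_frame(
    measurements: Iterable[IntensityMeasurement],
) -> pd.DataFrame:
    """Tabulate measurements: embryo_id, means, score, negative flag."""
    return pd.DataFrame(
        [
            {
                "embryo_id": m.embryo_id,
                "signal_mean": m.signal_mean,
                "background_mean": m.background_mean,
                "score": m.score,
                "negative_flag": m.negative,
            }
            for m in measurements
        ]
    )
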