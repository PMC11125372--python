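"""Silhouette ingestion: binarization, boundary tracing, resampling.

Seed silhouettes arrive as flatbed-scanner rasters (dark seed on a light
background, resolution known in dots per inch). This module turns them into
closed outline polygons in millimetres, sampled at equidistant points along
the curvilinear abscissa, ready for the elliptic Fourier transform.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "RasterSilhouette",
    "Outline",
    "EmptySilhouetteError",
    "binarize",
    "extract_outline",
    "resample_outline",
    "load_image",
    "read_manifest",
    "outlines_from_manifest",
    "write_outlines_csv",
]

MM_PER_INCH = 25.4
MIN_FOREGROUND_PIXELS = 50


class EmptySilhouetteError(ValueError):
    """Raised when an image contains no foreground after thresholding."""


@dataclass(frozen=True)
class RasterSilhouette:
    """A cleaned binary seed image: one filled connected component.

    ``pixels`` is a boolean grid with True = seed; ``dpi`` fixes the
    physical scale (mm = px * 25.4 / dpi).
    """

    pixels: np.ndarray
    dpi: float
    specimen_id: str = ""
    view: str = "dorsal"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.sum() < MIN_FOREGROUND_PIXELS:
            raise ValueError(
                f"silhouette {self.specimen_id!r}: foreground area "
                f"{int(px.sum())} px below minimum {MIN_FOREGROUND_PIXELS}"
            )


@dataclass(frozen=True)
class Outline:
    """Ordered closed polygon of a seed boundary.

    Points are (x, y) pairs; the last point connects back to the first
    implicitly. Orientation is canonicalized to counter-clockwise (positive
    signed area) on construction, because the signs of elliptic Fourier
    coefficients depend on traversal direction.
    """

    points: np.ndarray
    specimen_id: str = ""
    closed: bool = field(default=True)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("outline needs at least 3 (x, y) points")
        # drop an explicit closing point and any consecutive duplicates
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if pts.shape[0] < 3:
            raise ValueError("outline degenerate after removing duplicates")
        if self.signed_area(pts) < 0:
            pts = np.vstack([pts[:1], pts[1:][::-1]])
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "closed", True)

    @staticmethod
    def signed_area(pts: np.ndarray) -> float:
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def area(self) -> float:
        return abs(self.signed_area(self.points))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def binarize(
    image: np.ndarray,
    threshold_policy: str | float = "otsu",
    dpi: float = 600.0,
    specimen_id: str = "",
    view: str = "dorsal",
) -> RasterSilhouette:
    """Threshold a grayscale raster into a cleaned binary silhouette.

    The seed is assumed dark on a light background (scanner silhouette), so
    foreground = value below threshold. Boolean input is taken as-is with
    True = foreground. Cleaning keeps the largest connected component,
    discards components below 1% of its area, and fills interior holes (a
    seed silhouette is simply connected; holes are scanner artifacts).

    Parameters
    ----------
    threshold_policy : "otsu" or a fixed numeric threshold.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == bool:
        fg = img.copy()
    else:
        img = img.astype(float)
        if threshold_policy == "otsu":
            if np.ptp(img) == 0:
                raise EmptySilhouetteError(
                    f"empty silhouette for specimen {specimen_id!r}: "
                    "image is constant"
                )
            thr = threshold_otsu(img)
        else:
            thr = float(threshold_policy)
        fg = img < thr
    if not fg.any():
        raise EmptySilhouetteError(
            f"empty silhouette for specimen {specimen_id!r}: "
            "no foreground pixels"
        )
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    fg = labels == largest
    fg = ndimage.binary_fill_holes(fg)
    return RasterSilhouette(pixels=fg, dpi=dpi, specimen_id=specimen_id, view=view)


def extract_outline(sil: RasterSilhouette) -> Outline:
    """Trace the silhouette boundary at sub-pixel precision, in millimetres.

    The boundary is the 0.5 iso-contour of the (zero-padded) binary grid,
    which passes midway between foreground and background pixel centres.
    Coordinates are converted to mm using the silhouette's dpi, with
    x = column, y = row.
    """
    padded = np.pad(sil.pixels.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError(f"no boundary found for specimen {sil.specimen_id!r}")
    if len(contours) > 1:
        raise ValueError(
            f"specimen {sil.specimen_id!r}: {len(contours)} boundary loops "
            "after cleaning; expected exactly one"
        )
    rc = contours[0] - 1.0  # undo padding offset
    scale = MM_PER_INCH / sil.dpi
    pts = np.column_stack([rc[:, 1], rc[:, 0]]) * scale
    return Outline(points=pts, specimen_id=sil.specimen_id)


def resample_outline(o: Outline, n_points: int = 360) -> Outline:
    """Resample a closed outline to equidistant points along its arc length.

    The first output point equals the input's first point; spacing is the
    closed-curve perimeter divided by ``n_points``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = np.vstack([o.points, o.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("outline has zero perimeter")
    target = np.arange(n_points) * (total / n_points)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    return Outline(points=np.column_stack([x, y]), specimen_id=o.specimen_id)


def load_image(path: str | pathlib.Path) -> np.ndarray:
    """Read a PNG/TIFF raster as a grayscale float array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def read_manifest(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a specimen manifest CSV.

    Required columns: specimen_id, path, group, view, dpi. ``group`` is a
    label string or the distinguished value "unknown". Image paths are
    resolved relative to the manifest's directory.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str, "group": str})
    required = {"specimen_id", "path", "group", "view", "dpi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    df["path"] = [
        str((path.parent / p)) if not pathlib.Path(p).is_absolute() else p
        for p in df["path"]
    ]
    return df


def outlines_from_manifest(
    manifest: pd.DataFrame,
    threshold_policy: str | float = "otsu",
    n_points: int | None = 360,
) -> list[Outline]:
    """Ingest every manifest row: load, binarize, trace, resample."""
    outlines = []
    for row in manifest.itertuples(index=False):
        sil = binarize(
            load_image(row.path),
            threshold_policy=threshold_policy,
            dpi=float(row.dpi),
            specimen_id=str(row.specimen_id),
            view=str(row.view),
        )
        o = extract_outline(sil)
        if n_points is not None:
            o = resample_outline(o, n_points)
        outlines.append(o)
    return outlines


def write_outlines_csv(outlines: list[Outline], path) -> None:
    """Write outlines as long-format CSV (specimen_id, point_index, x_mm, y_mm)."""
    frames = [
        pd.DataFrame(
            {
                "specimen_id": o.specimen_id,
                "point_index": np.arange(o.n_points),
                "x_mm": o.points[:, 0],
                "y_mm": o.points[:, 1],
            }
        )
        for o in outlines
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
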