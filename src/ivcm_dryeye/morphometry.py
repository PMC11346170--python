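"""Quantitative morphometry of corneal confocal frames.

A frame covers 400 x 400 um imaged at 384 x 384 px, so the pixel size is
exactly 400/384 um and the field area is 0.16 mm².  Per-frame metrics:

* inflammatory-cell density -- cells / 0.16 mm²
* nerve fiber density (NFD) -- annotated polylines / 0.16 mm² (each
  annotated polyline counts as one nerve; no branch merging)
* nerve fiber length (NFL) -- summed polyline arc length per frame area,
  in mm/mm²
* tortuosity -- arc length / Euclidean chord per nerve, averaged
* reflectivity -- mean intensity along nerves over the robust background
* sharpness -- variance of the 3x3 Laplacian, the objective proxy used to
  select the five sharpest frames of an eye before averaging

The canonical pipeline path consumes annotation files (mirroring manual
counting/tracing); :func:`detect_cells` offers an automated
Laplacian-of-Gaussian alternative for cell counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.feature import blob_log

#: exact pixel size, um per px
PIXEL_SIZE_UM: float = 400.0 / 384.0
#: frame field area in mm2
FIELD_AREA_MM2: float = 0.16


@dataclass(frozen=True)
class FrameMetrics:
    image_id: str
    n_cells: int
    ic_density: float          # cells/mm2
    nfd: float                 # nerves/mm2
    nfl: float                 # mm/mm2
    mean_tortuosity: float     # >= 1 (1.0 by convention when no nerves)
    reflectivity_index: float
    sharpness: float


@dataclass(frozen=True)
class MorphometrySummary:
    eye_id: str
    n_images_used: int
    mean_ic_density: float
    mean_nfd: float
    mean_nfl: float
    mean_tortuosity: float
    mean_reflectivity: float

    def __post_init__(self) -> None:
        if self.n_images_used < 1:
            raise ValueError("a summary needs at least one frame")


def ic_density(n_cells: int, field_area: float = FIELD_AREA_MM2) -> float:
    """Cell count over field area (mm²) -> cells/mm²."""
    if field_area <= 0:
        raise ValueError(f"field area must be > 0, got {field_area}")
    return n_cells / field_area


def polyline_length(polyline: np.ndarray) -> float:
    """Arc length of an (N,2) vertex array, in the vertex units."""
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    return float(np.hypot(*np.diff(p, axis=0).T).sum())


def polyline_tortuosity(polyline: np.ndarray) -> float:
    """Arc length over Euclidean chord; NaN for a degenerate (closed) chord."""
    p = np.asarray(polyline, dtype=float)
    chord = float(np.hypot(*(p[-1] - p[0])))
    if chord == 0.0:
        return float("nan")
    return polyline_length(p) / chord


def nerve_metrics(
    polylines: Sequence[np.ndarray],
    pixel_size: float = PIXEL_SIZE_UM,
    field_area: float = FIELD_AREA_MM2,
) -> tuple[float, float, float]:
    """(NFD nerves/mm², NFL mm/mm², mean tortuosity) from traced polylines."""
    if pixel_size <= 0:
        raise ValueError(f"pixel size must be > 0, got {pixel_size}")
    nfd = len(polylines) / field_area
    total_mm = sum(polyline_length(p) for p in polylines) * pixel_size / 1000.0
    nfl = total_mm / field_area
    torts = []
    for p in polylines:
        t = polyline_tortuosity(p)
        if np.isnan(t):
            warnings.warn("degenerate polyline (zero chord) excluded from tortuosity")
        else:
            torts.append(t)
    mean_tort = float(np.mean(torts)) if torts else 1.0
    return nfd, nfl, mean_tort


def sharpness(image: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian; higher = better focus."""
    return float(ndimage.laplace(np.asarray(image, dtype=float)).var())


def select_sharpest(frames: Sequence[np.ndarray], k: int = 5) -> list[np.ndarray]:
    """Top-k frames by focus measure, returned in input order (stable ties)."""
    idx = select_sharpest_indices([sharpness(f) for f in frames], k)
    return [frames[i] for i in idx]


def select_sharpest_indices(values: Sequence[float], k: int = 5) -> list[int]:
    if len(values) == 0:
        raise ValueError("no frames to select from")
    order = np.argsort(-np.asarray(values, dtype=float), kind="stable")
    return sorted(int(i) for i in order[:k])


def _nerve_mask(shape: tuple[int, int], polylines: Sequence[np.ndarray]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for p in polylines:
        v = np.round(np.asarray(p, dtype=float)).astype(int)
        v[:, 0] = np.clip(v[:, 0], 0, shape[1] - 1)  # x
        v[:, 1] = np.clip(v[:, 1], 0, shape[0] - 1)  # y
        for (x0, y0), (x1, y1) in zip(v[:-1], v[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            mask[rr, cc] = True
    return mask


def reflectivity_index(
    image: np.ndarray,
    polylines: Sequence[np.ndarray],
    exclusion_px: int = 5,
) -> float:
    """Mean nerve-path intensity over the median background intensity.

    Background = median of pixels farther than ``exclusion_px`` from any
    traced nerve, which is robust to the bright nerves themselves and to
    cell blobs of moderate number.
    """
    if len(polylines) == 0:
        raise ValueError("reflectivity needs at least one traced nerve")
    img = np.asarray(image, dtype=float)
    mask = _nerve_mask(img.shape, polylines)
    dist = ndimage.distance_transform_edt(~mask)
    background = float(np.median(img[dist > exclusion_px]))
    if background == 0:
        raise ValueError("background median is zero; reflectivity undefined")
    return float(img[mask].mean()) / background


def detect_cells(
    image: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 5.0,
    threshold_rel: float = 0.2,
) -> list[tuple[float, float]]:
    """Laplacian-of-Gaussian blob detection of inflammatory cells.

    The threshold is relative to the frame's background-subtracted peak, so
    the same setting works across contrast levels.  Returns (x, y) pixel
    coordinates.
    """
    img = np.asarray(image, dtype=float)
    img = img - np.median(img)
    peak = img.max()
    if peak <= 0:
        return []
    blobs = blob_log(
        img / peak,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=6,
        threshold=threshold_rel * 0.3,
    )
    return [(float(c), float(r)) for r, c, _s in blobs]


def compute_frame_metrics(
    image: np.ndarray,
    image_id: str,
    cells: Sequence[tuple[float, float]],
    polylines: Sequence[np.ndarray],
    pixel_size: float = PIXEL_SIZE_UM,
    field_area: float = FIELD_AREA_MM2,
) -> FrameMetrics:
    nfd, nfl, tort = nerve_metrics(polylines, pixel_size, field_area)
    refl = reflectivity_index(image, polylines) if len(polylines) else 1.0
    return FrameMetrics(
        image_id=image_id,
        n_cells=len(cells),
        ic_density=ic_density(len(cells), field_area),
        nfd=nfd,
        nfl=nfl,
        mean_tortuosity=tort,
        reflectivity_index=refl,
        sharpness=sharpness(image),
    )


def summarize_eye(
    frame_metrics: Sequence[FrameMetrics], eye_id: str, k: int = 5
) -> MorphometrySummary:
    """Average metrics over the k sharpest frames of one eye."""
    if len(frame_metrics) == 0:
        raise ValueError("cannot summarise an eye with no frames")
    idx = select_sharpest_indices([m.sharpness for m in frame_metrics], k)
    chosen = [frame_metrics[i] for i in idx]
    return MorphometrySummary(
        eye_id=eye_id,
        n_images_used=len(chosen),
        mean_ic_density=float(np.mean([m.ic_density for m in chosen])),
        mean_nfd=float(np.mean([m.nfd for m in chosen])),
        mean_nfl=float(np.mean([m.nfl for m in chosen])),
        mean_tortuosity=float(np.mean([m.mean_tortuosity for m in chosen])),
        mean_reflectivity=float(np.mean([m.reflectivity_index for m in chosen])),
    )
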