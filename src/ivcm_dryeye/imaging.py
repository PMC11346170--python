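"""Synthetic corneal sub-basal plexus frames with exact ground truth.

Real confocal frames of the sub-basal plexus show bright curvilinear nerve
fibers and bright dendritiform inflammatory cells over a darker stromal
background.  The renderer plants both object classes with known geometry so
that morphometry and grading can be validated against exact annotations:

* nerves: a chord across the frame plus a sinusoidal perpendicular
  displacement whose amplitude controls tortuosity, stroked ~3 px wide
  (about 3 um, the caliber of sub-basal fibers at this magnification);
* cells: isotropic Gaussian spots (sigma ~3 px) with a few short radial
  processes mimicking dendritiform morphology (maturity is not modelled);
* optics: Gaussian blur then additive Gaussian noise, clipped to 8-bit.

Raster convention, used everywhere in the package: origin at the top-left,
x rightward, y downward, 0-based pixel coordinates; image arrays are
indexed [y, x].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import line as draw_line, line_aa

from .morphometry import PIXEL_SIZE_UM, polyline_length, polyline_tortuosity


@dataclass(frozen=True)
class ImageSpec:
    width_px: int = 384
    height_px: int = 384
    field_um: float = 400.0
    n_cells: int = 8
    n_nerves: int = 5
    tortuosity_amplitude: float = 8.0  # px, perpendicular displacement scale
    nerve_contrast: float = 90.0
    cell_contrast: float = 80.0
    background_level: float = 40.0
    noise_sd: float = 4.0
    blur_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_nerves < 0:
            raise ValueError("object counts must be >= 0")
        if min(self.nerve_contrast, self.cell_contrast, self.background_level) < 0:
            raise ValueError("intensities must be >= 0")
        if self.tortuosity_amplitude < 0 or self.blur_sigma_px < 0:
            raise ValueError("amplitude and blur must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.field_um / self.width_px


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """Exact planted geometry of one rendered frame."""

    image_id: str
    cells: list[tuple[float, float]]           # (x, y) px
    nerves: list[np.ndarray]                   # (N,2) float px polylines
    nerve_tortuosity: list[float] = field(default_factory=list)
    nerve_length_um: list[float] = field(default_factory=list)
    reflectivity_truth: float = 1.0            # (background+contrast)/background


def plant_nerve(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """One nerve polyline crossing the frame; wigglier at larger amplitude.

    A straight random chord through the frame interior is displaced
    perpendicular to itself by a sine of random frequency (3-8 periods) and
    phase, scaled by ``tortuosity_amplitude``.  Amplitude 0 yields an exactly
    straight segment (tortuosity 1.0); the arc/chord ratio grows with the
    amplitude in expectation.  Vertices are clipped to the frame.
    """
    w, h = spec.width_px, spec.height_px
    theta = rng.uniform(0, np.pi)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    d = np.array([np.cos(theta), np.sin(theta)])
    half = float(np.hypot(w, h))  # long enough to span, clipped below
    n_pts = 200
    t = np.linspace(-half / 2, half / 2, n_pts)
    base = np.array([cx, cy]) + t[:, None] * d
    if spec.tortuosity_amplitude > 0:
        freq = rng.integers(3, 9)
        phase = rng.uniform(0, 2 * np.pi)
        amp = spec.tortuosity_amplitude * rng.uniform(0.6, 1.0)
        disp = amp * np.sin(2 * np.pi * freq * (t - t[0]) / (t[-1] - t[0]) + phase)
        perp = np.array([-d[1], d[0]])
        base = base + disp[:, None] * perp
    # keep the in-frame run only, then clip residual excursions
    inside = (
        (base[:, 0] >= 0) & (base[:, 0] <= w - 1)
        & (base[:, 1] >= 0) & (base[:, 1] <= h - 1)
    )
    if inside.sum() >= 2:
        first, last = np.nonzero(inside)[0][[0, -1]]
        base = base[first : last + 1]
    base[:, 0] = np.clip(base[:, 0], 0, w - 1)
    base[:, 1] = np.clip(base[:, 1], 0, h - 1)
    return base


def _stroke_polyline(canvas: np.ndarray, polyline: np.ndarray, value: float) -> None:
    """Anti-aliased ~3 px wide stroke; accumulates the max coverage."""
    v = np.round(polyline).astype(int)
    center = np.zeros(canvas.shape, dtype=bool)
    for (x0, y0), (x1, y1) in zip(v[:-1], v[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        center[rr, cc] = True
    # ~5 px stroke (a sub-basal fiber bundle with its reflective halo at
    # ~1 um/px): full weight within 1.5 px of the centerline, soft 1 px edge
    dist = ndimage.distance_transform_edt(~center)
    weight = np.clip(2.5 - dist, 0.0, 1.0)
    np.maximum(canvas, weight * value, out=canvas)


def _place_cells(
    spec: ImageSpec, rng: np.random.Generator, min_dist: float = 14.0, margin: int = 10
) -> list[tuple[float, float]]:
    cells: list[tuple[float, float]] = []
    for _ in range(spec.n_cells * 200):
        if len(cells) == spec.n_cells:
            break
        x = rng.uniform(margin, spec.width_px - 1 - margin)
        y = rng.uniform(margin, spec.height_px - 1 - margin)
        if all(np.hypot(x - cx, y - cy) >= min_dist for cx, cy in cells):
            cells.append((x, y))
    while len(cells) < spec.n_cells:  # dense frames: give up on spacing
        cells.append(
            (
                rng.uniform(margin, spec.width_px - 1 - margin),
                rng.uniform(margin, spec.height_px - 1 - margin),
            )
        )
    return cells


def render_frame(
    spec: ImageSpec, image_id: str = "frame"
) -> tuple[np.ndarray, GroundTruthAnnotation]:
    """Render one 8-bit frame and its exact annotation; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w]

    nerves = [plant_nerve(spec, rng) for _ in range(spec.n_nerves)]
    nerve_layer = np.zeros((h, w))
    for p in nerves:
        _stroke_polyline(nerve_layer, p, spec.nerve_contrast)

    cells = _place_cells(spec, rng)
    cell_layer = np.zeros((h, w))
    cell_sigma = 3.0
    for cx, cy in cells:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        cell_layer = np.maximum(
            cell_layer, spec.cell_contrast * np.exp(-r2 / (2 * cell_sigma**2))
        )
        for _ in range(rng.integers(2, 5)):  # short dendritiform processes
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(5, 9)
            ex = np.clip(cx + length * np.cos(ang), 0, w - 1)
            ey = np.clip(cy + length * np.sin(ang), 0, h - 1)
            proc = np.zeros((h, w))
            rr, cc, val = line_aa(int(round(cy)), int(round(cx)), int(round(ey)), int(round(ex)))
            proc[rr, cc] = val
            cell_layer = np.maximum(cell_layer, 0.5 * spec.cell_contrast * proc)

    img = spec.background_level + np.maximum(nerve_layer, cell_layer)
    if img.max() > 255:
        warnings.warn("contrast exceeds the 8-bit range; clipping")
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)
    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)

    annotation = GroundTruthAnnotation(
        image_id=image_id,
        cells=cells,
        nerves=nerves,
        nerve_tortuosity=[polyline_tortuosity(p) for p in nerves],
        nerve_length_um=[polyline_length(p) * spec.pixel_size_um for p in nerves],
        reflectivity_truth=(
            (spec.background_level + spec.nerve_contrast) / spec.background_level
            if spec.background_level > 0
            else 1.0
        ),
    )
    return img8, annotation


def render_eye(
    spec: ImageSpec, eye_id: str, n_frames: int = 5
) -> list[tuple[np.ndarray, GroundTruthAnnotation]]:
    """Independent frames of one eye, seeds split from the spec seed."""
    out = []
    for j in range(n_frames):
        frame_spec = replace(spec, seed=spec.seed * 1000 + j)
        out.append(render_frame(frame_spec, image_id=f"{eye_id}-f{j + 1}"))
    return out


# ---------------------------------------------------------------------------
# annotation / image round-trip IO (TSV dialects shared with morphometry)

def write_frames(
    frames: list[tuple[np.ndarray, GroundTruthAnnotation]], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write TIFFs plus the two annotation TSVs; returns (cells, nerves) paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_rows, nerve_rows = [], []
    for img, ann in frames:
        tifffile.imwrite(out_dir / f"{ann.image_id}.tif", img)
        for x, y in ann.cells:
            cell_rows.append({"image_id": ann.image_id, "x": x, "y": y})
        for nerve_id, p in enumerate(ann.nerves):
            for vi, (x, y) in enumerate(np.asarray(p)):
                nerve_rows.append(
                    {
                        "image_id": ann.image_id,
                        "nerve_id": nerve_id,
                        "vertex_index": vi,
                        "x": x,
                        "y": y,
                    }
                )
    cells_path = out_dir / "cells.tsv"
    nerves_path = out_dir / "nerves.tsv"
    pd.DataFrame(cell_rows, columns=["image_id", "x", "y"]).to_csv(
        cells_path, sep="\t", index=False
    )
    pd.DataFrame(
        nerve_rows, columns=["image_id", "nerve_id", "vertex_index", "x", "y"]
    ).to_csv(nerves_path, sep="\t", index=False)
    return cells_path, nerves_path


def read_annotations(
    cells_path: str | Path, nerves_path: str | Path
) -> dict[str, tuple[list[tuple[float, float]], list[np.ndarray]]]:
    """Parse the annotation TSVs back into per-image (cells, polylines)."""
    cells_df = pd.read_csv(cells_path, sep="\t")
    nerves_df = pd.read_csv(nerves_path, sep="\t")
    image_ids = sorted(set(cells_df["image_id"]) | set(nerves_df["image_id"]))
    out = {}
    for image_id in image_ids:
        cdf = cells_df[cells_df["image_id"] == image_id]
        cells = list(zip(cdf["x"].astype(float), cdf["y"].astype(float)))
        ndf = nerves_df[nerves_df["image_id"] == image_id]
        polylines = []
        for _nid, g in ndf.groupby("nerve_id"):
            g = g.sort_values("vertex_index")
            polylines.append(np.column_stack([g["x"].to_numpy(), g["y"].to_numpy()]))
        out[image_id] = (cells, polylines)
    return out
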