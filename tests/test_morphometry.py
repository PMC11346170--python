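"""Morphometry: densities, nerve metrics, frame selection, detection."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from ivcm_dryeye.imaging import ImageSpec, render_frame
from ivcm_dryeye.morphometry import (
    FIELD_AREA_MM2,
    PIXEL_SIZE_UM,
    FrameMetrics,
    detect_cells,
    ic_density,
    nerve_metrics,
    polyline_length,
    reflectivity_index,
    select_sharpest,
    select_sharpest_indices,
    summarize_eye,
)


@pytest.mark.parametrize(
    "n,area,expected", [(12, 0.16, 75.0), (0, 0.16, 0.0), (16, 0.16, 100.0)]
)
def test_ic_density_examples(n, area, expected):
    assert ic_density(n, area) == expected


def test_ic_density_rejects_nonpositive_area():
    with pytest.raises(ValueError):
        ic_density(5, 0.0)


def test_ic_density_scale_invariance():
    assert ic_density(24, 0.16) == 2 * ic_density(12, 0.16)


def test_straight_spanning_nerve_metrics_exact():
    # 384 px * (400/384) um/px = 400 um = 0.4 mm
    polyline = np.array([[0.0, 100.0], [384.0, 100.0]])
    nfd, nfl, tort = nerve_metrics([polyline])
    assert nfl == pytest.approx(2.5, abs=1e-12)
    assert nfd == pytest.approx(6.25, abs=1e-12)
    assert tort == pytest.approx(1.0, abs=1e-12)


def test_empty_annotation_metrics():
    nfd, nfl, tort = nerve_metrics([])
    assert (nfd, nfl, tort) == (0.0, 0.0, 1.0)


def test_semicircle_tortuosity_near_half_pi():
    theta = np.linspace(0.0, np.pi, 200)
    arc = np.column_stack([150 + 100 * np.cos(theta), 150 + 100 * np.sin(theta)])
    _, _, tort = nerve_metrics([arc])
    assert tort == pytest.approx(np.pi / 2, rel=0.01)


def test_degenerate_polyline_excluded_with_warning():
    closed = np.array([[10.0, 10.0], [30.0, 10.0], [10.0, 10.0]])
    straight = np.array([[0.0, 0.0], [100.0, 0.0]])
    with pytest.warns(UserWarning, match="degenerate"):
        nfd, _nfl, tort = nerve_metrics([closed, straight])
    assert nfd == 2 / FIELD_AREA_MM2  # still counted for density
    assert tort == pytest.approx(1.0)


def test_unit_round_trip_is_lossless():
    length_px = 123.456
    mm = length_px * PIXEL_SIZE_UM / 1000.0
    assert mm * 1000.0 / PIXEL_SIZE_UM == pytest.approx(length_px, abs=1e-12)


def test_polyline_length_validates_shape():
    with pytest.raises(ValueError):
        polyline_length(np.array([[1.0, 2.0]]))


# --- frame selection -------------------------------------------------------

def test_select_sharpest_returns_all_when_few():
    frames = [np.random.default_rng(i).random((32, 32)) for i in range(3)]
    assert len(select_sharpest(frames, k=5)) == 3


def test_select_sharpest_rejects_blurred_copies():
    rng = np.random.default_rng(0)
    sharp = [rng.random((64, 64)) * 100 for _ in range(5)]
    blurred = [ndimage.gaussian_filter(sharp[i], 2.0) for i in range(2)]
    frames = [blurred[0]] + sharp[:3] + [blurred[1]] + sharp[3:]
    chosen = select_sharpest(frames, k=5)
    assert len(chosen) == 5
    for c in chosen:
        assert any(c is s for s in sharp)


def test_select_sharpest_stable_on_ties():
    frame = np.random.default_rng(1).random((32, 32))
    frames = [frame.copy() for _ in range(7)]
    assert select_sharpest_indices([0.5] * 7, k=5) == [0, 1, 2, 3, 4]
    chosen = select_sharpest(frames, k=5)
    assert all(np.array_equal(c, frame) for c in chosen)


def test_select_sharpest_empty_errors():
    with pytest.raises(ValueError):
        select_sharpest_indices([], k=5)


# --- reflectivity ----------------------------------------------------------

def test_reflectivity_uniform_image_is_one():
    img = np.full((100, 100), 80, dtype=np.uint8)
    polyline = np.array([[10.0, 50.0], [90.0, 50.0]])
    assert reflectivity_index(img, [polyline]) == pytest.approx(1.0)


def test_reflectivity_matches_planted_contrast_ratio():
    vals = []
    for seed in range(5):
        spec = ImageSpec(
            n_cells=0, n_nerves=3, nerve_contrast=100.0,
            background_level=50.0, noise_sd=0.0, seed=seed,
        )
        img, ann = render_frame(spec)
        vals.append(reflectivity_index(img, ann.nerves))
    assert np.mean(vals) == pytest.approx(3.0, rel=0.10)


def test_reflectivity_monotone_in_contrast():
    means = []
    for contrast in (60.0, 100.0, 140.0):
        vals = []
        for seed in range(20):
            spec = ImageSpec(
                n_cells=0, n_nerves=3, nerve_contrast=contrast,
                background_level=50.0, noise_sd=2.0, seed=seed,
            )
            img, ann = render_frame(spec)
            vals.append(reflectivity_index(img, ann.nerves))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_reflectivity_requires_nerves_and_background():
    img = np.zeros((50, 50), dtype=np.uint8)
    with pytest.raises(ValueError):
        reflectivity_index(img, [])
    polyline = np.array([[5.0, 25.0], [45.0, 25.0]])
    with pytest.raises(ValueError, match="background"):
        reflectivity_index(img, [polyline])


# --- automated cell detection ---------------------------------------------

def _match_within(truth, detected, radius=3.0):
    if len(detected) == 0:
        return 0
    t, d = np.asarray(truth), np.asarray(detected)
    dist = np.linalg.norm(t[:, None, :] - d[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(dist)
    return int(np.sum(dist[ri, ci] <= radius))


def test_detect_cells_blank_frame_empty():
    assert detect_cells(np.full((64, 64), 40, dtype=np.uint8)) == []


def test_detect_cells_noiseless_exact_recovery():
    for seed in range(5):
        spec = ImageSpec(n_cells=12, n_nerves=0, noise_sd=0.0, seed=seed)
        img, ann = render_frame(spec)
        detected = detect_cells(img)
        assert len(detected) == 12
        assert _match_within(ann.cells, detected) == 12


def test_detect_cells_noisy_recall():
    recalls = []
    for seed in range(20):
        spec = ImageSpec(n_cells=12, n_nerves=4, cell_contrast=80.0, noise_sd=5.0, seed=seed)
        img, ann = render_frame(spec)
        recalls.append(_match_within(ann.cells, detect_cells(img)) / 12)
    assert np.mean(recalls) >= 0.9


# --- per-eye summary -------------------------------------------------------

def _metrics(image_id, icd, sharp):
    return FrameMetrics(
        image_id=image_id, n_cells=int(icd * 0.16), ic_density=icd,
        nfd=25.0, nfl=2.0, mean_tortuosity=1.1, reflectivity_index=2.0,
        sharpness=sharp,
    )


def test_summarize_eye_simple_mean():
    frames = [_metrics("a", 60.0, 1.0), _metrics("b", 80.0, 2.0)]
    summary = summarize_eye(frames, eye_id="e")
    assert summary.mean_ic_density == pytest.approx(70.0)
    assert summary.n_images_used == 2


def test_summarize_eye_single_frame_identity():
    frame = _metrics("a", 55.0, 3.0)
    summary = summarize_eye([frame], eye_id="e")
    assert summary.mean_ic_density == frame.ic_density
    assert summary.mean_nfd == frame.nfd
    assert summary.mean_tortuosity == frame.mean_tortuosity


def test_summarize_eye_uses_only_five_sharpest():
    frames = [_metrics(f"f{i}", 10.0 * i, sharp=float(i)) for i in range(7)]
    summary = summarize_eye(frames, eye_id="e", k=5)
    # brute-force oracle: top five sharpness values are frames 2..6
    expected = np.mean([10.0 * i for i in range(2, 7)])
    assert summary.mean_ic_density == pytest.approx(expected)
    assert summary.n_images_used == 5


def test_summarize_eye_empty_errors():
    with pytest.raises(ValueError):
        summarize_eye([], eye_id="e")
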