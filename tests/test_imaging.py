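"""Microscopy quantification: activation scoring, intensities, conversions."""

import numpy as np
import pytest

import microtraj as mt
from microtraj.simulate import GenerationError, simulate_image_fixture


# ---------------------------------------------------------------------------
# percent activated
# ---------------------------------------------------------------------------

def test_no_puncta_means_zero_percent():
    fx = simulate_image_fixture(10, [])
    pct, table = mt.percent_activated(fx.label_mask, fx.puncta_image)
    assert pct == 0.0
    assert not table["activated"].any()


def test_four_of_ten_large_puncta_give_forty_percent():
    spec = [(c, 150, 200.0) for c in (1, 4, 7, 9)]
    fx = simulate_image_fixture(10, spec)
    pct, table = mt.percent_activated(fx.label_mask, fx.puncta_image)
    assert pct == pytest.approx(40.0)
    assert set(table.index[table["activated"]]) == {1, 4, 7, 9}


def test_punctum_just_below_threshold_not_activated():
    fx = simulate_image_fixture(3, [(2, 99, 180.0)])
    pct, table = mt.percent_activated(fx.label_mask, fx.puncta_image)
    assert pct == 0.0
    assert table.loc[2, "largest_within_cell_punctum_px"] == 99


def test_punctum_at_threshold_activates():
    fx = simulate_image_fixture(3, [(2, 100, 180.0)])
    pct, _ = mt.percent_activated(fx.label_mask, fx.puncta_image)
    assert pct == pytest.approx(100.0 / 3)


def test_straddling_punctum_counts_per_cell_areas():
    # two touching rectangular cells; a 120-px blob splits 60/60 across the
    # boundary, so neither cell reaches the 100-px threshold
    mask = np.zeros((20, 40), dtype=int)
    mask[:, :20] = 1
    mask[:, 20:] = 2
    puncta = np.zeros_like(mask, dtype=float)
    puncta[4:10, 10:30] = 50.0  # 6 x 20 = 120 px, 60 px in each cell
    pct, table = mt.percent_activated(mask, puncta)
    assert pct == 0.0
    assert table.loc[1, "largest_within_cell_punctum_px"] == 60
    assert table.loc[2, "largest_within_cell_punctum_px"] == 60


def test_percent_activated_monotone_in_min_particle_size():
    rng = np.random.default_rng(0)
    spec = [(c, int(s), 100.0) for c, s in
            zip(range(1, 9), rng.integers(40, 260, 8))]
    fx = simulate_image_fixture(8, spec)
    pcts = []
    for thr in (50, 100, 150, 250):
        cfg = mt.QuantConfig(min_particle_px=thr)
        pct, _ = mt.percent_activated(fx.label_mask, fx.puncta_image, cfg)
        pcts.append(pct)
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


def test_measures_invariant_under_joint_translation():
    fx = simulate_image_fixture(4, [(1, 120, 90.0), (3, 80, 50.0)])
    mask = np.pad(fx.label_mask, ((7, 0), (11, 0)))
    img = np.pad(fx.puncta_image, ((7, 0), (11, 0)))
    p0, _ = mt.percent_activated(fx.label_mask, fx.puncta_image)
    p1, _ = mt.percent_activated(mask, img)
    assert p0 == p1
    m0 = mt.mean_intensity_in_mask(fx.label_mask, fx.puncta_image.astype(float))
    m1 = mt.mean_intensity_in_mask(mask, img.astype(float))
    assert np.allclose(m0.values, m1.values)


# ---------------------------------------------------------------------------
# mean intensity
# ---------------------------------------------------------------------------

def test_uniform_image_means_equal_value():
    fx = simulate_image_fixture(5, [])
    img = np.full(fx.label_mask.shape, 37.0)
    means = mt.mean_intensity_in_mask(fx.label_mask, img)
    assert np.allclose(means.values, 37.0)
    assert list(means.index) == [1, 2, 3, 4, 5]


def test_mean_intensity_matches_pixel_loop():
    rng = np.random.default_rng(1)
    fx = simulate_image_fixture(4, [])
    img = rng.uniform(0, 255, fx.label_mask.shape)
    means = mt.mean_intensity_in_mask(fx.label_mask, img)
    for k in range(1, 5):
        sel = fx.label_mask == k
        assert means[k] == pytest.approx(img[sel].mean())


# ---------------------------------------------------------------------------
# puncta-normalized counts
# ---------------------------------------------------------------------------

def test_single_reference_identical_punctum_gives_one():
    fx = simulate_image_fixture(2, [(1, 100, 80.0)])
    counts = mt.rnascope_normalized_count(
        fx.label_mask, fx.puncta_image, reference_puncta=[80.0 * 100]
    )
    assert counts[1] == pytest.approx(1.0)


def test_silent_cell_scores_zero():
    fx = simulate_image_fixture(2, [(1, 100, 80.0)])
    counts = mt.rnascope_normalized_count(
        fx.label_mask, fx.puncta_image, reference_puncta=[8000.0]
    )
    assert counts[2] == 0.0


def test_double_intensity_puncta_score_two():
    # one punctum per cell at 2x the reference total intensity
    fx = simulate_image_fixture(5, [(c, 100, 60.0) for c in range(1, 6)])
    ref = [60.0 * 100 / 2]
    counts = mt.rnascope_normalized_count(fx.label_mask, fx.puncta_image, ref)
    assert np.allclose(counts.values, 2.0)


def test_zero_reference_intensity_raises():
    fx = simulate_image_fixture(2, [])
    with pytest.raises(ValueError):
        mt.rnascope_normalized_count(fx.label_mask, fx.puncta_image, [0.0])


# ---------------------------------------------------------------------------
# pixel-micron conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("px,res,expected", [
    (100, 0.312, 31.2),
    (0, 0.312, 0.0),
    (1, 0.312, 0.312),
])
def test_pixel_micron_conversion(px, res, expected):
    assert mt.px_area_to_um(px, res) == pytest.approx(expected)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        mt.px_area_to_um(-1, 0.312)
    with pytest.raises(ValueError):
        mt.px_area_to_um(10, 0.0)


# ---------------------------------------------------------------------------
# projection helper and fixture generator contracts
# ---------------------------------------------------------------------------

def test_max_intensity_projection():
    stack = np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0),
                      np.ones((4, 4))])
    assert np.array_equal(mt.max_intensity_projection(stack),
                          np.full((4, 4), 2.0))


def test_fixture_labels_contiguous_and_puncta_inside():
    fx = simulate_image_fixture(7, [(3, 200, 99.0)])
    labels = np.unique(fx.label_mask)
    assert np.array_equal(labels, np.arange(8))
    inside = fx.label_mask[fx.puncta_image > 0]
    assert np.all(inside == 3)


def test_oversized_punctum_rejected():
    with pytest.raises(GenerationError):
        simulate_image_fixture(2, [(1, 5000, 50.0)])


def test_zero_area_punctum_rejected():
    with pytest.raises(GenerationError):
        simulate_image_fixture(2, [(1, 0, 50.0)])
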