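"""Connected-deposit labeling, the 1% exclusion and the distribution indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqmap import (
    LipidMask,
    RoiMaskSet,
    VoxelGeometry,
    apply_small_exclusion,
    label_deposits,
    lai,
    lld_percent,
    rld_percent,
    slice_metrics,
    vessel_summary,
)
from plaqmap.lipidseg import slice_areas


# ----------------------------------------------------------------- labeling


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Brute-force component areas by explicit flood fill (oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack_ = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack_:
                    x, y = stack_.pop()
                    size += 1
                    for dx, dy in steps:
                        nx, ny = x + dx, y + dy
                        if (
                            0 <= nx < mask.shape[0]
                            and 0 <= ny < mask.shape[1]
                            and mask[nx, ny]
                            and not seen[nx, ny]
                        ):
                            seen[nx, ny] = True
                            stack_.append((nx, ny))
                areas.append(size)
    return areas


def test_diagonal_connectivity_definition():
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 0] = mask[1, 1] = True
    _, areas8 = label_deposits(mask, connectivity=8)
    _, areas4 = label_deposits(mask, connectivity=4)
    assert len(areas8) == 1
    assert len(areas4) == 2


def test_empty_slice_has_no_components():
    labels, areas = label_deposits(np.zeros((5, 5), dtype=bool))
    assert len(areas) == 0
    assert labels.sum() == 0


def test_labels_follow_raster_order():
    mask = np.zeros((5, 5), dtype=bool)
    mask[4, 0] = True  # late in raster order
    mask[0, 4] = True  # early
    labels, _ = label_deposits(mask)
    assert labels[0, 4] == 1
    assert labels[4, 0] == 2


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labeling_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(17)
    for _ in range(60):
        mask = rng.random((32, 32)) < rng.uniform(0.2, 0.6)
        _, areas = label_deposits(mask, connectivity)
        oracle = flood_fill_components(mask, connectivity)
        assert sorted(areas.tolist()) == sorted(oracle)


def test_bad_connectivity_rejected():
    with pytest.raises(ValueError):
        label_deposits(np.zeros((2, 2), dtype=bool), connectivity=6)


# ----------------------------------------------------------------- exclusion


def test_one_percent_exclusion_example():
    """Shares [50, 25, 15, 9.5, 0.5]%: only the 0.5% deposit is noise."""
    table = apply_small_exclusion(np.array([50.0, 25.0, 15.0, 9.5, 0.5]))
    assert table["retained"].tolist() == [True, True, True, True, False]
    pct = table.loc[table["retained"], "area_pct"]
    assert pct.iloc[0] == pytest.approx(100 * 50 / 99.5)
    assert pct.sum() == pytest.approx(100.0, abs=1e-9)
    assert np.isnan(table.loc[4, "area_pct"])


def test_exclusion_boundary_is_inclusive():
    """1/101 is ~0.99% <= 1%, so the single-voxel deposit is excluded."""
    table = apply_small_exclusion(np.array([100.0, 1.0]))
    assert table["retained"].tolist() == [True, False]
    assert int(table["retained"].sum()) == 1
    # a deposit at exactly 1% is also excluded
    exact = apply_small_exclusion(np.array([99.0, 1.0]))
    assert exact["retained"].tolist() == [True, False]


def test_equal_deposits_are_all_retained():
    table = apply_small_exclusion(np.full(5, 20.0))
    assert table["retained"].all()


def test_nonpositive_areas_rejected():
    with pytest.raises(ValueError):
        apply_small_exclusion(np.array([5.0, 0.0]))


# ----------------------------------------------------------------- indices


def dep_table(areas) -> pd.DataFrame:
    return apply_small_exclusion(np.asarray(areas, dtype=float))


def s1_scheme(areas):
    """Independent transcription of the index arithmetic: exclude <=1% of
    the pre-total, then largest-over-retained, mean of the rest, ratio."""
    areas = np.asarray(areas, dtype=float)
    keep = areas > 0.01 * areas.sum()
    kept = areas[keep]
    if kept.size == 0:
        return np.nan, np.nan, np.nan
    lld_frac = kept.max() / kept.sum()
    if kept.size < 2:
        return 100 * lld_frac, np.nan, np.nan
    rld = 100 * (1 - lld_frac) / (kept.size - 1)
    return 100 * lld_frac, rld, 100 * lld_frac / rld


def test_index_hand_cases():
    t = dep_table([50.0, 25.0, 15.0, 10.0])
    assert lld_percent(t) == pytest.approx(50.0)
    assert rld_percent(t) == pytest.approx(100 * 0.5 / 3)
    assert lai(t) == pytest.approx(3.0)

    t = dep_table([90.0, 5.0, 3.0, 2.0])
    assert lld_percent(t) == pytest.approx(90.0)
    assert rld_percent(t) == pytest.approx(100 * 0.1 / 3)
    assert lai(t) == pytest.approx(27.0)


def test_single_and_equal_deposit_cases():
    single = dep_table([42.0])
    assert lld_percent(single) == pytest.approx(100.0)
    assert np.isnan(rld_percent(single))
    assert np.isnan(lai(single))

    two_equal = dep_table([7.0, 7.0])
    assert lld_percent(two_equal) == pytest.approx(50.0)
    assert rld_percent(two_equal) == pytest.approx(50.0)
    assert lai(two_equal) == pytest.approx(1.0)


@pytest.mark.parametrize("n", range(2, 51))
def test_equal_deposits_have_unit_lai(n):
    assert lai(dep_table(np.full(n, 3.0))) == pytest.approx(1.0, abs=1e-12)


def test_indices_match_independent_transcription():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = rng.integers(1, 12)
        areas = rng.uniform(0.2, 50.0, size=n)
        t = dep_table(areas)
        lld_o, rld_o, lai_o = s1_scheme(areas)
        assert lld_percent(t) == pytest.approx(lld_o, nan_ok=True, rel=1e-12)
        assert rld_percent(t) == pytest.approx(rld_o, nan_ok=True, rel=1e-12)
        assert lai(t) == pytest.approx(lai_o, nan_ok=True, rel=1e-12)


@given(
    st.lists(st.floats(min_value=0.5, max_value=100.0), min_size=2, max_size=12)
)
@settings(max_examples=200, deadline=None)
def test_lai_identity(areas):
    """LAI == lld_frac*(n-1)/(1-lld_frac) on retained deposits."""
    t = dep_table(areas)
    n_ret = int(t["retained"].sum())
    if n_ret < 2:
        assert np.isnan(lai(t))
        return
    lld_frac = lld_percent(t) / 100.0
    expected = lld_frac * (n_ret - 1) / (1 - lld_frac)
    assert lai(t) == pytest.approx(expected, rel=1e-12)


def test_retained_percentages_close_to_100():
    rng = np.random.default_rng(31)
    for _ in range(50):
        t = dep_table(rng.uniform(0.01, 10.0, size=rng.integers(1, 15)))
        if t["retained"].any():
            assert t.loc[t["retained"], "area_pct"].sum() == pytest.approx(
                100.0, abs=1e-9
            )


def test_lai_monotone_in_lld_fraction():
    """With n fixed, LAI strictly increases as the largest share grows."""
    n = 5
    prev = -np.inf
    for big in np.linspace(30, 90, 13):
        rest = (100 - big) / (n - 1)
        val = lai(dep_table([big] + [rest] * (n - 1)))
        assert val > prev
        prev = val


def test_merging_deposits_never_decreases_lld():
    rng = np.random.default_rng(37)
    for _ in range(100):
        areas = rng.uniform(1.0, 20.0, size=rng.integers(3, 10))
        before = lld_percent(dep_table(areas))
        i, j = rng.choice(len(areas), size=2, replace=False)
        merged = np.delete(areas, [i, j]).tolist() + [areas[i] + areas[j]]
        after = lld_percent(dep_table(merged))
        assert after >= before - 1e-9


# ----------------------------------------------------------------- vessel level


def metrics_frame(lipid_mm3, lipid_pct=None, wall_empty=None, n=None):
    k = len(lipid_mm3)
    return pd.DataFrame(
        {
            "slice": np.arange(k),
            "lipid_mm3": lipid_mm3,
            "wall_mm3": np.full(k, 50.0),
            "lipid_pct": lipid_pct if lipid_pct is not None else np.full(k, 10.0),
            "wall_empty": wall_empty if wall_empty is not None else np.zeros(k, bool),
            "n_deposits_retained": n if n is not None else np.full(k, 3),
            "lld_pct": np.full(k, 50.0),
            "rld_pct": np.full(k, 25.0),
            "lai": np.full(k, 2.0),
        }
    )


def test_constant_volumes_tie_break_to_first_slice():
    summary = vessel_summary(metrics_frame([4.0] * 10), bifurcation_slice=4)
    assert summary.max_slice == 0
    assert summary.mean_lipid_mm3 == pytest.approx(4.0)
    assert not summary.bifurcation_is_max


def test_max_slice_and_mean():
    summary = vessel_summary(metrics_frame([0.0] * 9 + [5.0]), bifurcation_slice=9)
    assert summary.max_slice == 9
    assert summary.mean_lipid_mm3 == pytest.approx(0.5)
    assert summary.bifurcation_is_max


def test_five_slice_vessel_averages_over_five():
    summary = vessel_summary(metrics_frame([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert summary.n_slices == 5
    assert summary.mean_lipid_mm3 == pytest.approx(3.0)


def test_lipid_free_vessel_has_undefined_max():
    summary = vessel_summary(metrics_frame([0.0] * 10), bifurcation_slice=4)
    assert summary.max_slice is None
    assert np.isnan(summary.max_slice_lai)
    assert summary.mean_lipid_mm3 == 0.0
    assert not summary.bifurcation_is_max


def test_all_slices_empty_raises():
    frame = metrics_frame([1.0, 2.0], wall_empty=np.array([True, True]))
    with pytest.raises(ValueError, match="wall"):
        vessel_summary(frame)


def test_end_to_end_indices_from_truth_labels(rendered_vessel, acq_default):
    """Indices computed from a noiseless mask equal the share arithmetic."""
    _, truth = rendered_vessel
    geom = acq_default.geometry
    lipid = LipidMask(mask=truth.labels > 0, threshold_ms=42.0, geometry=geom)
    rois = RoiMaskSet(wall=truth.wall, geometry=geom)
    metrics = slice_metrics(lipid, rois)
    summary = vessel_summary(metrics, bifurcation_slice=4)
    assert summary.max_slice == 4
    # three separated deposits, all well above 1%
    assert summary.max_slice_n_deposits == 3
    counts = [
        (truth.labels[:, :, 4] == k).sum() for k in (1, 2, 3)
    ]
    assert summary.max_slice_lld_pct == pytest.approx(
        100.0 * max(counts) / sum(counts)
    )
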