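"""Phantom rendering, Rician noise, cohort sampling and calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from plaqmap import (
    AcquisitionConfig,
    CohortSpec,
    DepositSpec,
    MultiEchoStack,
    TissueModel,
    add_rician_noise,
    calibrate_to_paper,
    fit_t2_map,
    generate_cohort,
    render_echo_stack,
    sample_cohort_truth,
)

from conftest import make_vessel


# ------------------------------------------------------------------ rendering


def test_forward_model_matches_closed_form(acq_default):
    """Noiseless wall signal is PD * exp(-TE/T2) exactly."""
    tissue = TissueModel(t2_fibrous=(50.0, 50.0), pd_wall=1000.0)
    vessel = make_vessel(shares=(), deposit_t2=(), f_max=0.0)
    stack, truth = render_echo_stack(vessel, acq_default, tissue)
    wall_signal = stack.data[0][truth.wall]
    assert np.allclose(wall_signal, 1000.0 * np.exp(-9.0 / 50.0))
    assert wall_signal[0] == pytest.approx(835.27, abs=0.01)


def test_lumen_fully_suppressed_when_fraction_zero(acq_default):
    tissue = TissueModel(lumen_signal_fraction=0.0)
    vessel = make_vessel()
    stack, truth = render_echo_stack(vessel, acq_default, tissue)
    assert np.all(stack.data[:, truth.lumen] == 0.0)


def test_disc_deposit_area_matches_pixel_counting(acq_default, tissue_default):
    """A 1.5 mm-radius deposit rasterises to pi*r^2 voxels within a ring."""
    radius = 1.5
    r_in, r_out = 2.5, 6.0  # wall thick enough that the capsule is a disc
    wall_area = np.pi * (r_out**2 - r_in**2)
    f_max = np.pi * radius**2 / wall_area
    vessel = make_vessel(
        shares=(1.0,), deposit_t2=(30.0,), f_max=f_max,
        lumen_radius=r_in, outer_radius=r_out,
    )
    _, truth = render_echo_stack(vessel, acq_default, tissue_default)
    count = (truth.labels[:, :, vessel.max_slice] == 1).sum()
    expected = np.pi * (radius / acq_default.in_plane_voxel) ** 2
    ring = 2 * np.pi * radius / acq_default.in_plane_voxel
    assert abs(count - expected) <= ring


def test_geometry_outside_fov_rejected(acq_default, tissue_default):
    vessel = make_vessel(outer_radius=30.0)
    with pytest.raises(ValueError, match="field of view"):
        render_echo_stack(vessel, acq_default, tissue_default)


def test_ground_truth_labels_inside_wall_and_counts(rendered_vessel):
    _, truth = rendered_vessel
    assert not np.any((truth.labels > 0) & ~truth.wall)
    assert np.array_equal(
        truth.slice_lipid_voxels, (truth.labels > 0).sum(axis=(0, 1))
    )
    frac = truth.slice_lipid_fraction
    assert np.all((frac >= 0) & (frac <= 1))


def test_forward_inverse_consistency(rendered_vessel):
    """Fitting the noiseless phantom recovers true T2 within 0.1% everywhere."""
    stack, truth = rendered_vessel
    result = fit_t2_map(stack, fit_mask=truth.wall)
    rel = np.abs(result.t2[truth.wall] - truth.t2[truth.wall]) / truth.t2[truth.wall]
    assert result.converged[truth.wall].all()
    assert rel.max() < 1e-3


def test_tissue_model_rejects_overlapping_supports():
    with pytest.raises(ValueError, match="threshold"):
        TissueModel(t2_lipid=(20.0, 45.0))
    with pytest.raises(ValueError, match="threshold"):
        TissueModel(t2_fibrous=(40.0, 90.0))
    TissueModel(t2_lipid=(20.0, 45.0), allow_overlap=True)  # explicit opt-in


# ------------------------------------------------------------------ noise


def test_rician_infinite_snr_is_identity(rendered_vessel):
    stack, _ = rendered_vessel
    noisy = add_rician_noise(stack, snr=1e12, seed=0)
    assert np.allclose(noisy.data, stack.data, rtol=1e-6, atol=1e-6)


def test_rician_zero_signal_has_rayleigh_mean():
    """At S=0 the magnitude is Rayleigh with mean sigma*sqrt(pi/2)."""
    zero = MultiEchoStack(
        data=np.zeros((1, 200, 500, 1)), echo_times=np.array([10.0])
    )
    sigma = 2.5
    noisy = add_rician_noise(zero, snr=100.0, seed=4, reference=sigma * 100.0)
    expected = sigma * np.sqrt(np.pi / 2)
    observed = noisy.data.mean()
    se = sigma * np.sqrt((2 - np.pi / 2) / noisy.data.size)
    assert abs(observed - expected) < 5 * se


def test_rician_noise_is_reproducible(rendered_vessel):
    stack, _ = rendered_vessel
    a = add_rician_noise(stack, snr=40.0, seed=77)
    b = add_rician_noise(stack, snr=40.0, seed=77)
    c = add_rician_noise(stack, snr=40.0, seed=78)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_rician_rejects_bad_snr(rendered_vessel):
    stack, _ = rendered_vessel
    with pytest.raises(ValueError):
        add_rician_noise(stack, snr=0.0, seed=0)


# ------------------------------------------------------------------ cohort


def test_default_cohort_structure():
    spec = CohortSpec(seed=1)
    table = sample_cohort_truth(spec)
    assert len(table) == 100
    assert table["patient"].nunique() == 50
    assert int(table["symptomatic_vessel"].sum()) == 34
    assert int(table["patient_symptomatic"].sum()) == 68  # 34 patients x 2


def test_bifurcation_probability_one_forces_placement():
    spec = CohortSpec(bifurcation_max_probability=1.0, seed=2)
    table = sample_cohort_truth(spec)
    assert table["max_is_bifurcation"].all()
    assert (table["max_slice"] == spec.bifurcation_slice).all()


def test_perfect_copula_gives_rank_identical_fractions():
    """With latent correlation 1 and shared margins, left/right f_max agree."""
    spec = CohortSpec(lipid_copula_rho=1.0, n_symptomatic=0, seed=3)
    table = sample_cohort_truth(spec, n_patients=200)
    left = table.loc[table["side"] == "left", "f_max"].to_numpy()
    right = table.loc[table["side"] == "right", "f_max"].to_numpy()
    assert stats.spearmanr(left, right).statistic == pytest.approx(1.0)


def test_copula_spearman_matches_closed_form():
    """Gaussian-copula rank correlation is (6/pi) asin(rho/2) at large n."""
    rho = 0.6
    spec = CohortSpec(lipid_copula_rho=rho, n_symptomatic=0, seed=4)
    table = sample_cohort_truth(spec, n_patients=50000)
    left = table.loc[table["side"] == "left", "f_max"].to_numpy()
    right = table.loc[table["side"] == "right", "f_max"].to_numpy()
    expected = 6 / np.pi * np.arcsin(rho / 2)
    assert stats.spearmanr(left, right).statistic == pytest.approx(
        expected, abs=0.02
    )


def test_generate_cohort_is_bit_reproducible():
    spec = CohortSpec(n_patients=2, n_symptomatic=1, seed=9)
    first = list(generate_cohort(spec))
    second = list(generate_cohort(spec))
    for (v1, s1, t1, r1), (v2, s2, t2, r2) in zip(first, second):
        assert v1.seed == v2.seed
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.labels, t2.labels)
        assert r1 == r2


def test_rendered_deposit_count_matches_spec(acq_default, tissue_default):
    """Capsule deposits stay separated and connected on the max slice."""
    from plaqmap.deposits import label_deposits

    spec = CohortSpec(n_patients=3, n_symptomatic=2, seed=21)
    for vessel, stack, truth, record in generate_cohort(spec):
        s = vessel.max_slice
        rasterized = len(np.unique(truth.labels[:, :, s])) - 1
        _, areas = label_deposits(truth.labels[:, :, s] > 0)
        assert len(areas) == rasterized  # no fragmentation, no merging


def test_slice_count_override(acq_default, tissue_default):
    """Vessels can be rendered with the reduced 5-slice acquisition."""
    acq5 = dataclasses.replace(acq_default, n_slices=5)
    vessel = make_vessel(n_slices=5, max_slice=2)
    stack, truth = render_echo_stack(vessel, acq5, tissue_default)
    assert stack.n_slices == 5
    assert truth.labels.shape[2] == 5


# ------------------------------------------------------------------ calibration


@pytest.fixture(scope="module")
def calibrated():
    from plaqmap import paper_cohort

    return paper_cohort()  # cached calibrated configuration


def test_calibration_empty_request_returns_template():
    template = CohortSpec(seed=5)
    assert calibrate_to_paper(targets={}, template=template) == template


def test_calibration_matches_lognormal_median_exactly(calibrated):
    """The log-normal family hits a requested median by construction."""
    assert calibrated.fmax_symptomatic.median == pytest.approx(0.308)
    assert calibrated.fmax_asymptomatic.median == pytest.approx(0.215)


def test_calibrated_truth_statistics(calibrated):
    """Ground-truth cohort statistics land on the calibration targets."""
    table = sample_cohort_truth(calibrated, n_patients=20000)
    sym = table["symptomatic_vessel"]
    assert np.median(table.loc[sym, "max_slice_lipid_pct"]) == pytest.approx(
        30.8, rel=0.03
    )
    assert np.median(table.loc[~sym, "max_slice_lipid_pct"]) == pytest.approx(
        21.5, rel=0.03
    )
    assert np.median(table.loc[sym, "mean_lipid_pct"]) == pytest.approx(18.0, rel=0.05)
    assert np.median(table.loc[~sym, "mean_lipid_pct"]) == pytest.approx(13.0, rel=0.05)


def test_bilateral_correlation_converges_at_large_cohort(calibrated):
    """Achieved lipid rank correlation approaches the calibrated target."""
    table = sample_cohort_truth(calibrated, n_patients=500)
    left = table.loc[table["side"] == "left", "lipid_volume_mm3"].to_numpy()
    right = table.loc[table["side"] == "right", "lipid_volume_mm3"].to_numpy()
    r = stats.spearmanr(left, right).statistic
    assert r == pytest.approx(calibrated.bilateral_lipid_correlation, abs=0.08)


def test_infeasible_calibration_raises():
    with pytest.raises(ValueError, match="cannot match"):
        calibrate_to_paper(targets={"lai_median": 5000.0})
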