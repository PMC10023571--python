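"""Puncta segmentation, colocalization, kinetics and plate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixsub.fluor import (
    ChannelStack,
    ec50,
    growth_slope,
    halftime,
    manders,
    max_project,
    pearson,
    segment_puncta,
    size_gate,
    synth_cell_images,
    vacuolar_enrichment,
)


class TestSynthGenerator:
    def test_full_overlap_identical_positions(self):
        ch1, ch2, truth = synth_cell_images(
            {"overlap_fraction": 1.0, "noise_sigma": 0.0}, seed=0
        )
        assert np.array_equal(ch1.data > 50, ch2.data > 50)
        assert set(truth["kind"]) == {"shared"}

    def test_zero_overlap_disjoint_supports(self):
        ch1, ch2, _ = synth_cell_images(
            {"overlap_fraction": 0.0, "noise_sigma": 0.0}, seed=1
        )
        assert not np.any((ch1.data > 50) & (ch2.data > 50))

    def test_requested_diameter_recovered(self):
        # z sampling fine enough to resolve the sphere (quantization at the
        # default 500-nm confocal z step would dominate a 400-nm object)
        ch1, _, _ = synth_cell_images(
            {"overlap_fraction": 1.0, "noise_sigma": 0.0, "psf_sigma_nm": 50.0,
             "diameter_nm": (400.0, 400.0), "n_puncta": 6, "shape": (24, 96, 96),
             "voxel_size_nm": (100.0, 100.0, 100.0)}, seed=2
        )
        puncta = segment_puncta(ch1, threshold_policy=50.0, min_voxels=2)
        assert len(puncta) == 6
        # equivalent diameter within one voxel (100 nm) of the request
        assert np.all(np.abs(puncta.table["equiv_diameter_nm"] - 400.0) <= 100.0)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth_cell_images({"overlap_fraction": 1.5}, seed=0)

    def test_seeded_reproducible(self):
        a1, a2, at = synth_cell_images(seed=5)
        b1, b2, bt = synth_cell_images(seed=5)
        assert np.array_equal(a1.data, b1.data)
        assert at.equals(bt)


class TestMaxProject:
    def test_single_slice_range_returns_slice(self):
        stack = ChannelStack(np.random.default_rng(0).random((6, 8, 8)),
                             (500.0, 100.0, 100.0))
        assert np.array_equal(max_project(stack, (2, 3)), stack.data[2])

    def test_projection_dominates_every_slice(self):
        stack = ChannelStack(np.random.default_rng(1).random((6, 8, 8)),
                             (500.0, 100.0, 100.0))
        proj = max_project(stack, (1, 5))
        for z in range(1, 5):
            assert np.all(proj >= stack.data[z])

    def test_empty_range_rejected(self):
        stack = ChannelStack(np.zeros((4, 4, 4)), (500.0, 100.0, 100.0))
        with pytest.raises(ValueError, match="range"):
            max_project(stack, (3, 3))


class TestSegmentPuncta:
    def _sphere_stack(self, r_nm=300.0, center=(6, 24, 24)):
        shape = (12, 48, 48)
        vz, vy, vx = 200.0, 100.0, 100.0
        zz, yy, xx = np.indices(shape)
        d2 = (((zz - center[0]) * vz) ** 2 + ((yy - center[1]) * vy) ** 2
              + ((xx - center[2]) * vx) ** 2)
        data = np.where(d2 <= r_nm**2, 100.0, 0.0)
        return ChannelStack(data, (vz, vy, vx))

    def test_sphere_volume_recovered(self):
        stack = self._sphere_stack(400.0)
        puncta = segment_puncta(stack, threshold_policy=50.0)
        assert len(puncta) == 1
        expected = 4.0 / 3.0 * np.pi * 0.4**3  # µm³
        assert puncta.table["volume_um3"].iloc[0] == pytest.approx(expected, rel=0.15)

    def test_two_separated_spheres_are_two_objects(self):
        a = self._sphere_stack(200.0, (3, 12, 12)).data
        b = self._sphere_stack(200.0, (9, 36, 36)).data
        stack = ChannelStack(a + b, (200.0, 100.0, 100.0))
        assert len(segment_puncta(stack, threshold_policy=50.0)) == 2

    def test_all_zero_stack_empty_set(self):
        stack = ChannelStack(np.zeros((4, 8, 8)), (200.0, 100.0, 100.0))
        assert len(segment_puncta(stack, threshold_policy=10.0)) == 0


class TestSizeGate:
    def test_partition_around_cutoff(self):
        ch1, _, _ = synth_cell_images(
            {"diameter_nm": (300.0, 700.0), "n_puncta": 10, "noise_sigma": 0.0,
             "overlap_fraction": 1.0}, seed=3
        )
        puncta = segment_puncta(ch1, threshold_policy=50.0)
        small, large = size_gate(puncta, 500.0)
        assert len(small) + len(large) == len(puncta)
        if len(small):
            assert small.table["equiv_diameter_nm"].max() < 500.0
        if len(large):
            assert large.table["equiv_diameter_nm"].min() >= 500.0

    def test_empty_input_two_empty_sets(self):
        stack = ChannelStack(np.zeros((4, 8, 8)), (200.0, 100.0, 100.0))
        puncta = segment_puncta(stack, threshold_policy=10.0)
        small, large = size_gate(puncta)
        assert len(small) == 0 and len(large) == 0

    def test_zero_cutoff_sends_all_to_large(self):
        ch1, _, _ = synth_cell_images({"noise_sigma": 0.0}, seed=4)
        puncta = segment_puncta(ch1, threshold_policy=50.0)
        small, large = size_gate(puncta, 0.0)
        assert len(small) == 0 and len(large) == len(puncta)


class TestPearsonManders:
    def test_identical_channels_give_unity(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 16, 16))
        assert pearson(a, a) == pytest.approx(1.0)
        m1, m2 = manders(a + 0.1, a + 0.1, 0.5, 0.5)
        assert m1 == pytest.approx(1.0) and m2 == pytest.approx(1.0)

    def test_anticorrelated_channels(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 16, 16))
        assert pearson(a, -a + 2.0) == pytest.approx(-1.0)

    def test_disjoint_supports_zero_manders(self):
        a = np.zeros((2, 8, 8))
        b = np.zeros((2, 8, 8))
        a[0, :4] = 1.0
        b[1, 4:] = 1.0
        m1, m2 = manders(a, b, 0.5, 0.5)
        assert m1 == 0.0 and m2 == 0.0

    def test_nested_support_asymmetry(self):
        a = np.zeros((1, 8, 8))
        b = np.zeros((1, 8, 8))
        a[0, 2:4, 2:4] = 1.0
        b[0, 1:6, 1:6] = 1.0  # strictly contains a's support
        m1, m2 = manders(a, b, 0.5, 0.5)
        assert m1 == pytest.approx(1.0)
        assert m2 < 1.0

    def test_zero_variance_error_names_channel(self):
        a = np.ones((2, 4, 4))
        b = np.random.default_rng(2).random((2, 4, 4))
        with pytest.raises(ValueError, match="channel 1"):
            pearson(a, b)

    def test_coefficients_monotone_in_overlap(self):
        """PC and both MCs rise monotonically with the generated ground-truth
        overlap fraction (Spearman > 0.95 across a 5-level sweep)."""
        from scipy.stats import spearmanr

        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        pcs, m1s = [], []
        for frac in levels:
            ch1, ch2, _ = synth_cell_images(
                {"overlap_fraction": frac, "noise_sigma": 1.0, "n_puncta": 12},
                seed=11,
            )
            pcs.append(pearson(ch1.data, ch2.data))
            m1, _ = manders(ch1.data, ch2.data, 50.0, 50.0)
            m1s.append(m1)
        assert spearmanr(levels, pcs).statistic > 0.95
        assert spearmanr(levels, m1s).statistic > 0.95
        assert pcs[0] < 0.2 and pcs[-1] > 0.9

    def test_size_gated_colocalization_pattern(self):
        """When only large puncta colocalize, the large-class Pearson far
        exceeds the small-class Pearson."""
        large1, large2, _ = synth_cell_images(
            {"overlap_fraction": 1.0, "diameter_nm": (650.0, 750.0),
             "n_puncta": 6, "noise_sigma": 1.0}, seed=21,
        )
        small1, small2, _ = synth_cell_images(
            {"overlap_fraction": 0.0, "diameter_nm": (250.0, 350.0),
             "n_puncta": 6, "noise_sigma": 1.0}, seed=22,
        )
        ch1 = ChannelStack(np.clip(large1.data + small1.data - 5.0, 0, None),
                           large1.voxel_size_nm)
        ch2 = ChannelStack(np.clip(large2.data + small2.data - 5.0, 0, None),
                           large2.voxel_size_nm)
        puncta = segment_puncta(ch1, threshold_policy=50.0)
        small_set, large_set = size_gate(puncta, 500.0)
        pc_small = pearson(ch1.data, ch2.data, small_set.labels > 0)
        pc_large = pearson(ch1.data, ch2.data, large_set.labels > 0)
        assert pc_large > pc_small + 0.3


class TestVacuolarEnrichment:
    def test_equal_means_zero(self):
        img = np.ones((16, 16))
        mem = np.zeros((16, 16), bool)
        cyt = np.zeros((16, 16), bool)
        mem[2:4] = True
        cyt[10:12] = True
        assert vacuolar_enrichment(img, mem, cyt) == 0.0

    def test_offset_recovered(self):
        img = np.ones((16, 16))
        mem = np.zeros((16, 16), bool)
        cyt = np.zeros((16, 16), bool)
        mem[2:4] = True
        cyt[10:12] = True
        img[mem] += 3.5
        assert vacuolar_enrichment(img, mem, cyt) == pytest.approx(3.5)

    def test_decaying_enrichment_tracked(self):
        """A simulated shaving time-course with enrichment decaying by half is
        estimated within 10% at every time point."""
        rng = np.random.default_rng(0)
        mem = np.zeros((32, 32), bool)
        cyt = np.zeros((32, 32), bool)
        mem[10:12] = True
        cyt[20:26] = True
        for true_e in [8.0, 6.0, 4.0]:
            img = 2.0 + rng.normal(0, 0.05, (32, 32))
            img[mem] += true_e
            est = vacuolar_enrichment(img, mem, cyt)
            assert est == pytest.approx(true_e, rel=0.10)

    def test_overlapping_masks_rejected(self):
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="overlap"):
            vacuolar_enrichment(np.ones((8, 8)), m, m)


class TestHalftime:
    def test_linear_ramp(self):
        t = np.linspace(0, 10, 21)
        assert halftime(t, t / 10.0) == pytest.approx(5.0)

    def test_exponential_saturation_gives_tau_ln2(self):
        tau = 7.0 / np.log(2)  # half-time 7 minutes
        t = np.linspace(0, 100, 1000)  # long enough to reach the plateau
        y = 1.0 - np.exp(-t / tau)
        assert halftime(t, y) == pytest.approx(tau * np.log(2), rel=0.01)

    def test_decreasing_trace_crosses_downward(self):
        t = np.linspace(0, 10, 21)
        assert halftime(t, 1.0 - t / 10.0) == pytest.approx(5.0)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            halftime(np.arange(5.0), np.ones(5))


class TestGrowthSlope:
    def test_equal_intensities_zero_slope(self):
        assert growth_slope([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_exact_line(self):
        assert growth_slope([4.0, 3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_constant_offset_invariant(self):
        a = growth_slope([4.0, 3.0, 2.5, 1.0])
        b = growth_slope([14.0, 13.0, 12.5, 11.0])
        assert a == pytest.approx(b)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="4"):
            growth_slope([1.0, 2.0, 3.0])


class TestEc50:
    def _dose_response(self, mid, hill=1.5, conc=None):
        conc = conc if conc is not None else np.logspace(-1, 2, 8)
        y = 0.1 + (1.0 - 0.1) / (1.0 + (conc / mid) ** hill)
        return conc, y

    def test_noiseless_recovery_within_one_percent(self):
        conc, y = self._dose_response(mid=3.7)
        value, fitted = ec50(conc, y)
        assert fitted
        assert value == pytest.approx(3.7, rel=0.01)

    def test_scaling_responses_leaves_ec50_unchanged(self):
        conc, y = self._dose_response(mid=2.2)
        v1, _ = ec50(conc, y)
        v2, _ = ec50(conc, 5.0 * y)
        assert v2 == pytest.approx(v1, rel=1e-6)

    def test_noisy_monte_carlo_median_within_15_percent(self):
        conc, y = self._dose_response(mid=5.0)
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(100):
            noisy = y * (1.0 + rng.normal(0, 0.10, y.shape))
            try:
                estimates.append(ec50(conc, noisy)[0])
            except ValueError:
                continue
        assert np.median(estimates) == pytest.approx(5.0, rel=0.15)

    def test_non_spanning_data_rejected(self):
        conc = np.array([0.001, 0.002, 0.004, 0.008])
        y = np.array([1.0, 0.99, 1.01, 0.995])
        with pytest.raises(ValueError, match="range"):
            ec50(conc, y)


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_coefficients_respect_ranges_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((3, 12, 12)) + 1e-3
    b = rng.random((3, 12, 12)) + 1e-3
    assert -1.0 <= pearson(a, b) <= 1.0
    m1, m2 = manders(a, b, 0.5, 0.5)
    assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0
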