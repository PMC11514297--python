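"""Processing chain, Virtual Echo transform and quadrant projectors."""

import numpy as np
import pytest

from echorecon import (ExponentialParams, ProcessingOptions, SimConfig,
                       echo_spectrum, from_virtual_echo, generate_pairs,
                       nus_corrupt, process_spectrum, quadrant_weights,
                       synthesize_fid, to_virtual_echo, zero_quadrants)
from echorecon.hypercomplex import time_sign
from echorecon.simulate import HypercomplexFID, scaled_config


def _peak_fid(w1, w2, k=16, l=32, tau=np.inf):
    cfg = SimConfig(n_indirect=k, n_direct=l, snr=np.inf)
    return synthesize_fid(
        [ExponentialParams(1.0, w1, w2, decay_indirect=tau, decay_direct=tau)],
        cfg), cfg


class TestProcessSpectrum:
    def test_zero_fid_gives_zero_spectrum(self):
        fid = HypercomplexFID(np.zeros((4, 8)), np.zeros((4, 8)))
        assert np.array_equal(process_spectrum(fid), np.zeros((8, 16)))

    @pytest.mark.parametrize("w1,w2", [(0.25, -0.125), (0.0, 0.25),
                                       (-0.25, 0.375), (0.125, 0.0)])
    def test_peak_position_matches_dft_convention(self, w1, w2):
        fid, _ = _peak_fid(w1, w2)
        spec = process_spectrum(fid, ProcessingOptions(apodization="none"))
        idx = np.unravel_index(np.argmax(spec), spec.shape)
        expected = (int(round(w1 * 32)) % 32, int(round(w2 * 64)) % 64)
        assert idx == expected

    def test_shape_is_doubled_grid(self):
        fid, _ = _peak_fid(0.1, 0.1, k=8, l=16)
        assert process_spectrum(fid).shape == (16, 32)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            HypercomplexFID(np.zeros((4, 8)), np.zeros((4, 9)))


class TestVirtualEcho:
    def test_round_trip_identity(self, single_peak_spectrum):
        s = single_peak_spectrum
        back = from_virtual_echo(to_virtual_echo(s))
        assert np.abs(back - s).max() <= 1e-10 * np.abs(s).max()

    def test_conjugate_symmetry(self, single_peak_spectrum):
        ve = to_virtual_echo(single_peak_spectrum)
        n1, n2 = ve.shape
        mirrored = ve[(-np.arange(n1)) % n1][:, (-np.arange(n2)) % n2]
        assert np.abs(ve - np.conj(mirrored)).max() <= 1e-10 * np.abs(ve).max()

    def test_single_peak_populates_all_four_quadrants(self, single_peak_spectrum):
        ve = to_virtual_echo(single_peak_spectrum)
        s1 = time_sign(ve.shape[0])[:, None]
        s2 = time_sign(ve.shape[1])[None, :]
        for q in (+1, -1):
            for r in (+1, -1):
                quadrant = ve[(s1 == q) * (s2 == r)]
                assert np.abs(quadrant).max() > 1e-6 * np.abs(ve).max()

    def test_complex_input_rejected(self):
        with pytest.raises(ValueError):
            to_virtual_echo(np.zeros((4, 4), dtype=complex))

    def test_zero_ve_gives_zero_spectrum(self):
        assert np.array_equal(from_virtual_echo(np.zeros((4, 6))),
                              np.zeros((4, 6)))


class TestQuadrantProjectors:
    def test_partition_of_identity(self, single_peak_spectrum):
        ve = to_virtual_echo(single_peak_spectrum)
        both = zero_quadrants(ve, "N_side") + zero_quadrants(ve, "P_side")
        assert np.abs(both - ve).max() <= 1e-12 * np.abs(ve).max()

    def test_idempotent_on_interior(self, single_peak_spectrum):
        ve = to_virtual_echo(single_peak_spectrum)
        once = zero_quadrants(ve, "N_side")
        twice = zero_quadrants(once, "N_side")
        interior = (quadrant_weights(ve.shape, "P_side") == 1.0)
        assert np.array_equal(once[interior], twice[interior])

    def test_mask_enumeration_on_8x8(self):
        # independent oracle: walk every index pair through the index->time
        # map and assign the quadrant by the signs of (t1, t2)
        def t_of(i, n=8):
            return None if i in (0, n // 2) else (i if i < n // 2 else i - n)

        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                t1, t2 = t_of(i), t_of(j)
                if t1 is None or t2 is None:
                    expected[i, j] = 0.5
                elif (t1 > 0) != (t2 > 0):  # N or N~ quadrant
                    expected[i, j] = 1.0
        assert np.array_equal(quadrant_weights((8, 8), "N_side"), expected)

    def test_unknown_selector_rejected(self):
        with pytest.raises(ValueError):
            quadrant_weights((4, 4), "Q_side")


class TestEchoSpectrum:
    def test_phase_twist_has_negative_lobes(self, single_peak_spectrum):
        se = echo_spectrum(single_peak_spectrum, "echo")
        assert single_peak_spectrum.min() > -0.05 * single_peak_spectrum.max()
        assert se.min() < -0.1 * se.max()

    def test_flavors_sum_to_input_exactly(self, single_peak_spectrum):
        s = single_peak_spectrum
        total = echo_spectrum(s, "echo") + echo_spectrum(s, "anti_echo")
        assert np.abs(total - s).max() <= 1e-10 * np.abs(s).max()

    def test_zero_spectrum_maps_to_zero(self):
        assert np.array_equal(echo_spectrum(np.zeros((8, 8)), "echo"),
                              np.zeros((8, 8)))

    def test_projected_ve_transforms_to_real(self, single_peak_spectrum):
        ve = zero_quadrants(to_virtual_echo(single_peak_spectrum), "N_side")
        spec = np.fft.fft2(ve)
        assert np.abs(spec.imag).max() <= 1e-10 * np.abs(spec).max()

    def test_random_synthetic_partition(self):
        ds = generate_pairs(scaled_config(), 3, "echo", master_seed=77)
        for s in ds.references:
            total = echo_spectrum(s, "echo") + echo_spectrum(s, "anti_echo")
            assert np.abs(total - s).max() <= 1e-10 * np.abs(s).max()


class TestNusCorrupt:
    def test_full_schedule_is_identity(self):
        fid, _ = _peak_fid(0.2, -0.3, k=8, l=8, tau=12.0)
        full = np.arange(8)
        assert np.allclose(nus_corrupt(fid, full), process_spectrum(fid))

    def test_fid_and_spectrum_routes_agree(self, small_config):
        from echorecon.simulate import sample_params
        fid = synthesize_fid(sample_params(small_config, 3), small_config)
        sched = np.array([0, 2, 3, 5, 6])
        via_fid = nus_corrupt(fid, sched)
        via_spec = nus_corrupt(process_spectrum(fid), sched)
        scale = np.abs(via_spec).max()
        assert np.abs(via_fid - via_spec).max() <= 1e-10 * scale

    def test_half_schedule_zeroes_half_the_rows(self):
        fid, _ = _peak_fid(0.1, 0.1, k=8, l=8, tau=10.0)
        sched = np.array([0, 1, 3, 5])
        spec = nus_corrupt(fid, sched)
        ve = to_virtual_echo(spec)
        zeroed = [r for r in range(16)
                  if np.abs(ve[r]).max() <= 1e-12 * np.abs(ve).max()]
        # rows 2,4,6,7 and their mirrors 14,12,10,9, plus the (empty) Nyquist
        assert set(zeroed) == {2, 4, 6, 7, 8, 9, 10, 12, 14}

    def test_energy_never_increases(self, single_peak_spectrum):
        sched = np.array([0, 1, 2, 5, 9, 12])
        corrupted = nus_corrupt(single_peak_spectrum, sched)
        assert (corrupted ** 2).sum() <= (single_peak_spectrum ** 2).sum()

    def test_out_of_range_schedule_rejected(self, single_peak_spectrum):
        with pytest.raises(ValueError, match="range"):
            nus_corrupt(single_peak_spectrum, np.array([0, 99]))
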