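"""Synthetic FID generator: parameter sampling, the exponential model,
noise statistics, and P/N imbalance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echorecon import (ExponentialParams, SimConfig, add_noise,
                       apply_imbalance, generate_pairs, process_spectrum,
                       rmsd, sample_params, synthesize_fid)


class TestSampleParams:
    def test_defaults_draw_512_sets_within_ranges(self):
        cfg = SimConfig()
        params = sample_params(cfg, seed=42)
        assert len(params) == 512
        for p in params:
            assert cfg.amp_range[0] <= p.amplitude <= cfg.amp_range[1]
            assert cfg.freq_range[0] <= p.freq_indirect <= cfg.freq_range[1]
            assert cfg.freq_range[0] <= p.freq_direct <= cfg.freq_range[1]
            assert -3.0 <= p.phase_indirect <= 3.0
            assert -3.0 <= p.phase_direct <= 3.0
            assert 256.0 <= p.decay_indirect <= 1280.0
            assert 12.8 <= p.decay_direct <= 128.0

    def test_zero_exponentials_gives_empty_list(self):
        assert sample_params(SimConfig(n_exponentials=0), seed=0) == []

    def test_reproducible_for_fixed_seed(self):
        cfg = SimConfig(n_exponentials=16)
        assert sample_params(cfg, seed=7) == sample_params(cfg, seed=7)
        assert sample_params(cfg, seed=7) != sample_params(cfg, seed=8)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="amp_range"):
            SimConfig(amp_range=(1.0, -0.2))


class TestSynthesizeFid:
    def test_zero_frequency_identity(self):
        cfg = SimConfig(n_indirect=4, n_direct=8)
        fid = synthesize_fid([ExponentialParams(1.0, 0.0, 0.0)], cfg)
        assert np.allclose(fid.p_data, 1.0)
        assert np.allclose(fid.n_data, 1.0)

    def test_direct_formula_evaluation(self):
        # one exponential at w1=0.25: X_P(t1=1, t2=0) = e^{i pi/2} = i
        cfg = SimConfig(n_indirect=4, n_direct=8)
        fid = synthesize_fid([ExponentialParams(1.0, 0.25, 0.0)], cfg)
        assert fid.p_data[1, 0] == pytest.approx(1j)
        assert fid.n_data[1, 0] == pytest.approx(-1j)

    def test_linearity_in_parameter_union(self, rng):
        cfg = SimConfig(n_indirect=6, n_direct=10, n_exponentials=3)
        a = sample_params(cfg, seed=1)
        b = sample_params(cfg, seed=2)
        combined = synthesize_fid(a + b, cfg)
        summed_p = synthesize_fid(a, cfg).p_data + synthesize_fid(b, cfg).p_data
        assert np.allclose(combined.p_data, summed_p, atol=1e-12)

    @given(scale=st.sampled_from([0.5, 2.0, 4.0, 8.0]))
    def test_amplitude_scaling_is_exact(self, scale):
        cfg = SimConfig(n_indirect=4, n_direct=6)
        base = [ExponentialParams(0.5, 0.1, -0.2, 1.0, -1.0, 30.0, 10.0)]
        scaled = [dataclasses.replace(base[0], amplitude=0.5 * scale)]
        f1 = synthesize_fid(base, cfg)
        f2 = synthesize_fid(scaled, cfg)
        assert np.array_equal(f2.p_data, scale * f1.p_data)

    def test_pn_conjugation_for_zero_phase_real_direct_factor(self):
        cfg = SimConfig(n_indirect=8, n_direct=8)
        fid = synthesize_fid(
            [ExponentialParams(1.0, 0.3, 0.0, decay_indirect=12.0)], cfg)
        assert np.allclose(fid.n_data, np.conj(fid.p_data))

    def test_literal_growth_flag_flips_envelope(self):
        p = [ExponentialParams(1.0, 0.0, 0.0, decay_indirect=4.0)]
        decay = synthesize_fid(p, SimConfig(n_indirect=4, n_direct=4))
        grow = synthesize_fid(
            p, SimConfig(n_indirect=4, n_direct=4, literal_indirect_growth=True))
        assert np.abs(decay.p_data[3, 0]) < 1 < np.abs(grow.p_data[3, 0])


class TestAddNoise:
    def test_infinite_snr_is_identity(self):
        cfg = SimConfig(n_indirect=4, n_direct=4)
        fid = synthesize_fid([ExponentialParams(1.0, 0.1, 0.2)], cfg)
        noisy = add_noise(fid, np.inf, seed=0)
        assert np.array_equal(noisy.p_data, fid.p_data)

    def test_noise_std_matches_snr_500(self):
        # >= 1e5 samples: a 128x256 grid gives 4*32768 noise components
        cfg = SimConfig(n_exponentials=0)
        clean = synthesize_fid([], cfg)
        noisy = add_noise(clean, 500.0, seed=9)
        comps = np.concatenate([
            noisy.p_data.real.ravel(), noisy.p_data.imag.ravel(),
            noisy.n_data.real.ravel(), noisy.n_data.imag.ravel()])
        assert comps.size >= 10 ** 5
        assert np.std(comps) == pytest.approx(1.0 / 500.0, rel=0.05)

    def test_seeds_differ_but_mean_converges_to_clean(self):
        cfg = SimConfig(n_indirect=4, n_direct=8)
        fid = synthesize_fid([ExponentialParams(1.0, 0.1, -0.3)], cfg)
        draws = [add_noise(fid, 5.0, seed=s).p_data for s in range(400)]
        assert not np.array_equal(draws[0], draws[1])
        assert np.allclose(np.mean(draws, axis=0), fid.p_data, atol=0.05)

    def test_invalid_snr_rejected(self):
        fid = synthesize_fid([], SimConfig(n_indirect=2, n_direct=2))
        with pytest.raises(ValueError):
            add_noise(fid, 0.0, seed=0)


class TestImbalance:
    def test_ten_percent_deficit_scales_p_exactly(self):
        cfg = SimConfig(n_indirect=8, n_direct=8, snr=np.inf)
        fid = synthesize_fid([ExponentialParams(1.0, 0.2, 0.1,
                                                decay_indirect=16.0,
                                                decay_direct=8.0)], cfg)
        out = apply_imbalance(fid, 0.10)
        ratio = np.abs(out.p_data).max() / np.abs(out.n_data).max()
        assert ratio == pytest.approx(0.9, abs=1e-12)

    def test_zero_deficit_is_identity(self):
        fid = synthesize_fid([ExponentialParams(1.0, 0.1, 0.1)],
                             SimConfig(n_indirect=4, n_direct=4))
        out = apply_imbalance(fid, 0.0)
        assert np.array_equal(out.p_data, fid.p_data)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 2.0])
    def test_deficit_out_of_range_rejected(self, bad):
        fid = synthesize_fid([], SimConfig(n_indirect=2, n_direct=2))
        with pytest.raises(ValueError):
            apply_imbalance(fid, bad)

    def test_imbalanced_reference_shows_residual_twist(self):
        cfg = SimConfig(n_indirect=16, n_direct=16, snr=np.inf)
        fid = synthesize_fid([ExponentialParams(1.0, 0.2, -0.1,
                                                decay_indirect=20.0,
                                                decay_direct=8.0)], cfg)
        balanced = process_spectrum(fid)
        imbalanced = process_spectrum(apply_imbalance(fid, 0.10))
        assert rmsd(imbalanced, balanced) > 0
        resid = imbalanced / np.abs(imbalanced).max() - \
            balanced / np.abs(balanced).max()
        # residual twist has a dispersive (sign-changing) component
        assert resid.min() < -1e-4 and resid.max() > 1e-4


class TestGeneratePairs:
    def test_count_and_reference_construction(self, small_config):
        ds = generate_pairs(small_config, 3, "echo", master_seed=4)
        assert len(ds) == 3
        assert ds.inputs.shape == (3, 16, 32)

    def test_single_pair_reference_is_processed_fid(self, small_config):
        from echorecon.simulate import (pair_seed, sample_params as sp,
                                        synthesize_fid as sf)
        ds = generate_pairs(small_config, 1, "echo", master_seed=11)
        s = pair_seed(11, 0)
        fid = add_noise(sf(sp(small_config, s), small_config),
                        small_config.snr, s + 1)
        assert np.array_equal(ds.references[0], process_spectrum(fid))

    def test_pairs_distinct_and_deterministic(self, small_config):
        ds1 = generate_pairs(small_config, 4, "echo", master_seed=5)
        ds2 = generate_pairs(small_config, 4, "echo", master_seed=5)
        assert np.array_equal(ds1.inputs, ds2.inputs)
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.abs(ds1.inputs[i] - ds1.inputs[j]).max() > 0

    def test_nus_mode_and_unknown_mode(self, small_config):
        ds = generate_pairs(small_config, 2, "nus", master_seed=1)
        assert ds.mode == "nus"
        with pytest.raises(ValueError, match="mode"):
            generate_pairs(small_config, 1, "sideways", master_seed=1)
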