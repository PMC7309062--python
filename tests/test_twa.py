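"""Beat matrix construction and the three alternans estimators."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgist as e
from ecgist.twa import TWAConfig, build_beat_matrix, mma_method, spectral_method, temporal_method

FS = 2048.0
N = int(0.3 * FS)  # 614


def t_wave(amp=100.0):
    t = np.arange(N) / FS
    return amp * np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)


def alternating_matrix(m, delta, base_amp=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base, g = t_wave(base_amp), t_wave(1.0)
    rows = [base + (delta if i % 2 else -delta) * g
            + noise * rng.standard_normal(N) for i in range(m)]
    return build_beat_matrix(np.stack(rows), FS)


class TestBuildBeatMatrix:
    def test_even_count_kept(self):
        mat = build_beat_matrix(np.zeros((8, N)), FS)
        assert mat.M.shape == (8, N)

    def test_odd_count_drops_last(self):
        rows = np.arange(9)[:, None] * np.ones((9, N))
        mat = build_beat_matrix(rows, FS)
        assert mat.M.shape == (8, N)
        assert mat.M[-1, 0] == 7.0

    def test_columns_are_beat_series(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(6, 10))
        mat = build_beat_matrix(rows, FS)
        np.testing.assert_array_equal(mat.M[:, 3], rows[:, 3])

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_beat_matrix(np.zeros((1, N)), FS)


class TestSpectralMethod:
    def test_pure_alternation_peaks_at_half_cycle(self):
        mat = alternating_matrix(32, delta=50.0)
        res = spectral_method(mat)
        assert res.freqs[np.argmax(res.aggregate_psd)] == 0.5
        assert res.K_score > 3.0

    def test_constant_series_zero_alternans(self):
        rows = np.tile(t_wave(), (16, 1))
        res = spectral_method(build_beat_matrix(rows, FS))
        assert res.Valt_uV == 0.0

    def test_quarter_cycle_modulation_localized(self):
        """DFT oracle: beat-rate modulation at 0.25 cycles/beat shows a
        spectral peak at 0.25 and a small K at 0.5."""
        m = 32
        g = t_wave(1.0)
        rng = np.random.default_rng(0)
        rows = np.stack([t_wave() + 40.0 * np.cos(2 * np.pi * 0.25 * i) * g
                         + 1.0 * rng.standard_normal(N)
                         for i in range(m)])
        res = spectral_method(build_beat_matrix(rows, FS))
        assert res.freqs[np.argmax(res.aggregate_psd)] == pytest.approx(0.25)
        assert res.K_score < 3.0

    def test_periodogram_magnitude_matches_dft_oracle(self):
        """For +-a alternation of a single column, P(0.5) = M * a^2."""
        m, a = 16, 7.0
        rows = np.stack([np.full(N, a if i % 2 else -a) for i in range(m)])
        res = spectral_method(build_beat_matrix(rows, FS))
        assert res.aggregate_psd[-1] == pytest.approx(m * a ** 2, rel=1e-9)

    def test_zero_noise_sd_inf_sentinel(self):
        # 8 beats -> a single bin in [0.33, 0.49): noise SD is zero
        mat = alternating_matrix(8, delta=30.0)
        res = spectral_method(mat)
        assert np.isinf(res.K_score)

    def test_empty_noise_band_rejected(self):
        mat = alternating_matrix(16, delta=10.0)
        with pytest.raises(ValueError, match="noise band"):
            spectral_method(mat, TWAConfig(noise_band=(0.40, 0.41)))


class TestMMAMethod:
    def test_identical_beats_zero_magnitudes(self):
        rows = np.tile(t_wave(), (8, 1))
        res = mma_method(build_beat_matrix(rows, FS))
        assert res.max_magnitude_uV == 0.0

    def test_stationary_alternation_unlimited_equals_2delta(self):
        mat = alternating_matrix(12, delta=25.0)
        res = mma_method(mat, TWAConfig(mma_limiting="none"))
        # 2*delta scaled by the alternans wave's on-grid peak value
        expected = 2 * 25.0 * t_wave(1.0).max()
        np.testing.assert_allclose(res.magnitudes, expected, rtol=1e-12)

    def test_standard_limiting_converges_to_2delta(self):
        """Simulation oracle: with noise, the limited estimator reaches
        within 20% of the even/odd running-mean answer after burn-in."""
        delta, sigma = 40.0, 8.0
        mat = alternating_matrix(64, delta=delta, noise=sigma, seed=3)
        res = mma_method(mat, TWAConfig(mma_limiting="standard"))
        late = res.magnitudes[-8:]
        assert np.median(late) == pytest.approx(2 * delta, rel=0.2)

    def test_fewer_than_four_beats_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            mma_method(build_beat_matrix(np.zeros((2, N)), FS))

    def test_unknown_limiting_rejected(self):
        mat = alternating_matrix(8, delta=1.0)
        with pytest.raises(ValueError, match="limiting"):
            mma_method(mat, TWAConfig(mma_limiting="soft"))


class TestTemporalMethod:
    def test_single_sample_offset_recovers_delta(self):
        rows = np.tile(t_wave(), (8, 1))
        rows[1::2, 100] += 2 * 30.0  # odd beats raised by 2*delta at one sample
        res = temporal_method(build_beat_matrix(rows, FS))
        assert res.Valt_uV == pytest.approx(30.0)

    def test_identical_rows_zero(self):
        res = temporal_method(build_beat_matrix(np.tile(t_wave(), (6, 1)), FS))
        assert res.Valt_uV == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6), st.integers(2, 6))
    def test_matches_brute_force_oracle(self, seed, half_m):
        """Direct recomputation with explicit loops over even/odd rows."""
        rng = np.random.default_rng(seed)
        rows = rng.normal(size=(2 * half_m, 20))
        res = temporal_method(build_beat_matrix(rows, FS))
        even = sum(rows[2 * l] for l in range(half_m)) / half_m
        odd = sum(rows[2 * l + 1] for l in range(half_m)) / half_m
        expected = 0.5 * max(abs(o - v) for o, v in zip(odd, even))
        assert res.Valt_uV == pytest.approx(expected, rel=1e-12)


def test_mma_tm_consistency_on_stationary_alternation():
    """max V_l = 2 x Valt(TM) when limiting is disabled."""
    mat = alternating_matrix(16, delta=33.0)
    tm = temporal_method(mat)
    mma = mma_method(mat, TWAConfig(mma_limiting="none"))
    assert mma.max_magnitude_uV == pytest.approx(2 * tm.Valt_uV, rel=1e-12)


@pytest.fixture(scope="module")
def alternans_study(small_mesh, small_layout):
    cfg = e.SynthConfig(node_count=120, n_beats=16, rng_seed=5,
                        noise_sd_uV=5.0, drift_amp_mV=0.1)
    rec, ann = e.synthesize_recording(small_mesh, small_layout, cfg)
    patch = small_layout.nodes_of("scar")
    rec = e.inject_alternans(rec, ann, 40.0, node_subset=patch)
    rec = e.add_artifacts(rec, cfg)
    clean, ann = e.preprocess_recording(rec, annotation=ann)
    return small_mesh, cfg, clean, ann, patch


class TestTwaMap:
    def test_map_length_is_node_count(self, alternans_study):
        mesh, cfg, clean, ann, patch = alternans_study
        result = e.twa_map(clean, ann, mesh, "tm")
        assert result.markers.size == mesh.node_count

    @pytest.mark.parametrize("method", ["tm", "sm", "mma"])
    def test_injected_patch_dominates_markers(self, alternans_study, method):
        """Ground-truth patch oracle: markers inside the injected patch
        exceed the outside noise floor for every estimator."""
        mesh, cfg, clean, ann, patch = alternans_study
        result = e.twa_map(clean, ann, mesh, method)
        inside = np.isin(np.arange(mesh.node_count), patch)
        assert np.median(result.markers[inside]) > \
            np.quantile(result.markers[~inside], 0.9)

    def test_top_decile_concentrates_in_patch(self, alternans_study):
        mesh, cfg, clean, ann, patch = alternans_study
        result = e.twa_map(clean, ann, mesh, "tm")
        n_top = max(1, mesh.node_count // 10)
        top = np.argsort(-result.markers)[:n_top]
        assert np.isin(top, patch).mean() >= 0.8

    def test_zero_alternans_low_markers(self, small_study):
        mesh, layout, cfg, rec, ann = small_study
        clean, ann2 = e.preprocess_recording(rec, annotation=ann)
        result = e.twa_map(clean, ann2, mesh, "tm")
        assert np.nanmax(result.markers) < 5.0  # uV-scale numerical floor

    def test_unknown_method_rejected(self, small_study):
        mesh, layout, cfg, rec, ann = small_study
        with pytest.raises(ValueError, match="method"):
            e.twa_map(rec, ann, mesh, "wavelet")
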