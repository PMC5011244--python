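"""Core EMD: extrema, envelopes, sifting, full decomposition."""

import numpy as np
import pytest

from specmode import (Decomposition, SiftConfig, emd, emd_mode, find_extrema,
                      local_mean, sift_imf, simulated_signal)


def t_grid(n=1024):
    return np.arange(n) / n


class TestFindExtrema:
    def test_single_oscillation(self):
        mx_i, mx_v, mn_i, mn_v = find_extrema([0, 1, 0, -1, 0])
        assert list(mx_i) == [1] and list(mn_i) == [3]
        assert mx_v[0] == 1 and mn_v[0] == -1

    def test_monotone_has_no_interior_extrema(self):
        mx_i, _, mn_i, _ = find_extrema([1, 2, 3, 4, 5])
        assert mx_i.size == 0 and mn_i.size == 0

    def test_two_cycle_cosine_counts(self):
        # cos(4*pi*t) on [0,1): 2 cycles -> 1 interior max (t=0.5 region
        # peaks at endpoints don't count) and 2 interior minima
        x = np.cos(4 * np.pi * t_grid())
        mx_i, _, mn_i, _ = find_extrema(x)
        assert mx_i.size == 1 and mn_i.size == 2

    def test_plateau_resolved_to_middle(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, 0.0])
        mx_i, _, mn_i, _ = find_extrema(x)
        assert list(mx_i) == [2] and list(mn_i) == [5]

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([1.0, 2.0, 1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([0.0, np.nan, 0.0, 1.0])


class TestLocalMean:
    def test_pure_tone_mean_near_zero(self):
        x = np.cos(15 * np.pi * t_grid())
        m = local_mean(x)
        inner = slice(50, -50)
        assert np.max(np.abs(m[inner])) < 0.05

    def test_offset_shifts_mean(self):
        x = np.cos(15 * np.pi * t_grid()) + 5.0
        m = local_mean(x)
        assert np.max(np.abs(m[50:-50] - 5.0)) < 0.05

    def test_slow_component_is_local_mean_of_fast(self):
        t = t_grid()
        y = np.cos(4 * np.pi * t) + np.sin(15 * np.pi * t)
        m = local_mean(y)
        central = slice(102, 922)  # central 80%
        dev = np.sqrt(np.mean((m[central] - np.cos(4 * np.pi * t[central])) ** 2))
        assert dev < 0.1

    def test_no_extrema_raises(self):
        with pytest.raises(ValueError):
            local_mean(np.linspace(0, 1, 64))


class TestSiftImf:
    def test_pure_tone_is_already_an_imf(self):
        x = np.sin(15 * np.pi * t_grid())
        imf, converged = sift_imf(x)
        assert converged
        assert np.corrcoef(imf, x)[0, 1] > 0.999

    def test_constant_returned_unchanged(self):
        x = np.full(64, 3.14)
        imf, converged = sift_imf(x)
        assert not converged
        np.testing.assert_array_equal(imf, x)

    def test_first_imf_of_two_tone_signal(self):
        t = t_grid()
        y = np.cos(4 * np.pi * t) + np.sin(15 * np.pi * t)
        imf, _ = sift_imf(y)
        assert np.corrcoef(imf, np.sin(15 * np.pi * t))[0, 1] > 0.95


class TestEmd:
    def test_two_tone_separation(self):
        t = t_grid()
        y = simulated_signal(1024)
        dec = emd(y)
        assert dec.n_modes >= 2
        assert np.corrcoef(dec.imfs[0], np.sin(15 * np.pi * t))[0, 1] > 0.95
        slow = dec.imfs[1:].sum(axis=0) + dec.residue
        assert np.corrcoef(slow, np.cos(4 * np.pi * t))[0, 1] > 0.95

    def test_linear_ramp_is_all_residue(self):
        x = np.linspace(-1, 1, 128)
        dec = emd(x)
        assert dec.n_modes == 0
        np.testing.assert_allclose(dec.residue, x)

    @pytest.mark.parametrize("seed", range(10))
    def test_completeness(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(512)
        dec = emd(x)
        scale = np.max(np.abs(x))
        np.testing.assert_allclose(dec.reconstruct(), x, atol=1e-10 * scale)

    @pytest.mark.parametrize("seed", range(100))
    def test_zero_crossings_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(256)
        dec = emd(x)
        zc = [int(np.sum(np.diff(np.sign(imf + 1e-300)) != 0))
              for imf in dec.imfs]
        assert all(a >= b for a, b in zip(zc[:-1], zc[1:]))

    def test_offset_changes_only_residue(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(512)
        d0 = emd(x)
        d1 = emd(x + 7.5)
        assert d0.n_modes == d1.n_modes
        np.testing.assert_allclose(d0.imfs, d1.imfs, atol=1e-6)
        np.testing.assert_allclose(d1.residue - d0.residue, 7.5, atol=1e-6)

    def test_max_imfs_caps_mode_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        dec = emd(x, SiftConfig(max_imfs=3))
        assert dec.n_modes == 3
        np.testing.assert_allclose(dec.reconstruct(), x, atol=1e-10)


class TestEmdMode:
    def test_first_mode_of_pure_tone(self):
        x = np.sin(15 * np.pi * t_grid())
        e1 = emd_mode(x, 1)
        assert np.corrcoef(e1, x)[0, 1] > 0.999

    def test_out_of_range_mode_is_zero(self):
        y = simulated_signal(512)
        n_modes = emd(y).n_modes
        assert np.all(emd_mode(y, n_modes + 1) == 0.0)

    def test_noise_first_mode_has_smaller_variance(self):
        rng = np.random.default_rng(42)
        w = rng.standard_normal(1024)
        assert np.var(emd_mode(w, 1)) < np.var(w)

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            emd_mode([0.0, 1.0, 0.0, -1.0, 0.0], 0)


class TestDecompositionContainer:
    def test_reconstruct_subset_and_bounds(self):
        y = simulated_signal(512)
        dec = emd(y)
        np.testing.assert_allclose(dec.reconstruct([1]), dec.imfs[0])
        with pytest.raises(IndexError):
            dec.reconstruct([dec.n_modes + 1])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SiftConfig(max_siftings=0)
        with pytest.raises(ValueError):
            SiftConfig(stop_threshold=0.0)
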