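"""Spectral estimation and selection-criterion contracts.

The single-trial PSD is checked against two independent oracles: the
closed-form coherent gain of a Hamming-windowed on-bin sinusoid, and
Parseval's identity relating the summed density to windowed signal energy.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal.windows import hamming

from premovement.preprocess import EpochSet
from premovement.spectral import (
    DB_FLOOR,
    EPOCH_SAMPLES,
    FS_ANALYSIS,
    SelectedBand,
    SpectralContrast,
    average_psd,
    band_frequencies,
    bootstrap_selection_null,
    canonical_band_overlap,
    compute_contrast,
    compute_trial_psd,
    periodogram,
    select_bands,
)

from conftest import epochs_from_dataset


def make_contrast(diff_db, channel_labels=None, freqs=None):
    """Build a contrast with a prescribed between-class difference."""
    diff_db = np.atleast_2d(np.asarray(diff_db, dtype=float))
    if freqs is None:
        freqs = band_frequencies()
    if channel_labels is None:
        channel_labels = [f"c{i}" for i in range(diff_db.shape[0])]
    base = np.full_like(diff_db, -10.0)
    return SpectralContrast(
        freqs=freqs,
        psd_a_db=base + diff_db,
        psd_b_db=base,
        class_a="hand",
        class_b="elbow",
        channel_labels=channel_labels,
    )


class TestPeriodogram:
    def test_on_bin_sinusoid_matches_hamming_coherent_gain(self):
        # closed form: an on-bin unit sinusoid through a Hamming window has
        # peak linear density 2*(sum(w)/2)^2 / (fs * sum(w^2))
        fs, f0 = FS_ANALYSIS, 20.0
        n = EPOCH_SAMPLES
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)
        w = hamming(n, sym=False)
        expected_db = 10 * np.log10(2 * (w.sum() / 2) ** 2 / (fs * np.sum(w**2)))
        ps = compute_trial_psd(x)
        k_peak = int(np.argmax(ps.psd_db))
        assert ps.freqs[k_peak] == pytest.approx(f0)
        assert ps.psd_db[k_peak] == pytest.approx(expected_db, abs=0.1)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=EPOCH_SAMPLES)
        freqs, psd = periodogram(x)
        df = freqs[1] - freqs[0]
        w = hamming(EPOCH_SAMPLES, sym=False)
        windowed_energy = np.sum((x * w) ** 2) / np.sum(w**2)
        assert np.sum(psd) * df == pytest.approx(windowed_energy, rel=1e-6)

    def test_all_zero_epoch_is_floored_not_infinite(self):
        ps = compute_trial_psd(np.zeros(EPOCH_SAMPLES))
        assert np.all(ps.psd_db == DB_FLOOR)

    def test_wrong_epoch_length_rejected(self, rng):
        with pytest.raises(ValueError, match="400"):
            compute_trial_psd(rng.normal(size=300))

    def test_grid_is_half_hz_from_one_to_eighty(self):
        f = band_frequencies()
        assert f[0] == 1.0 and f[-1] == 80.0
        assert np.allclose(np.diff(f), 0.5)

    def test_disjoint_white_noise_trial_sets_agree(self, rng):
        a = [compute_trial_psd(rng.normal(size=EPOCH_SAMPLES)) for _ in range(100)]
        b = [compute_trial_psd(rng.normal(size=EPOCH_SAMPLES)) for _ in range(100)]
        diff = average_psd(a).psd_db - average_psd(b).psd_db
        assert np.mean(np.abs(diff)) < 1.0


class TestAveragePsd:
    def test_identical_trials_average_to_any_single_trial(self, rng):
        ps = compute_trial_psd(rng.normal(size=EPOCH_SAMPLES))
        avg = average_psd([ps, ps, ps])
        np.testing.assert_allclose(avg.psd_db, ps.psd_db, atol=1e-9)
        assert avg.n_trials == 3

    def test_linear_domain_averaging(self):
        freqs = band_frequencies()
        p = np.full(freqs.size, 2.0)
        from premovement.spectral import PowerSpectrum

        s1 = PowerSpectrum(freqs=freqs, psd_db=10 * np.log10(p))
        s2 = PowerSpectrum(freqs=freqs, psd_db=10 * np.log10(3 * p))
        avg = average_psd([s1, s2])
        np.testing.assert_allclose(10 ** (avg.psd_db / 10), 2 * p, rtol=1e-12)

    def test_masked_outlier_has_zero_influence(self, rng):
        trials = [compute_trial_psd(rng.normal(size=EPOCH_SAMPLES)) for _ in range(5)]
        outlier = compute_trial_psd(1e6 * rng.normal(size=EPOCH_SAMPLES))
        mask = np.array([True] * 5 + [False])
        avg_with = average_psd(trials + [outlier], mask)
        avg_without = average_psd(trials)
        np.testing.assert_allclose(avg_with.psd_db, avg_without.psd_db, atol=1e-12)

    def test_fewer_than_two_trials_rejected(self, rng):
        ps = compute_trial_psd(rng.normal(size=EPOCH_SAMPLES))
        with pytest.raises(ValueError, match="at least 2"):
            average_psd([ps])

    def test_mismatched_grids_rejected(self, rng):
        from premovement.spectral import PowerSpectrum

        ps = compute_trial_psd(rng.normal(size=EPOCH_SAMPLES))
        other = PowerSpectrum(freqs=ps.freqs + 0.5, psd_db=ps.psd_db)
        with pytest.raises(ValueError, match="grid"):
            average_psd([ps, other])


class TestSelectBands:
    def test_null_contrast_selects_nothing(self):
        assert select_bands(make_contrast(np.zeros(159))) == []

    def test_narrow_strong_contrast_fails_width_gate(self):
        freqs = band_frequencies()
        diff = np.zeros(freqs.size)
        diff[(freqs >= 20) & (freqs <= 22)] = 5.0  # 2 Hz wide, 5 dB
        assert select_bands(make_contrast(diff)) == []

    def test_nine_bins_span_four_hz_and_pass(self):
        freqs = band_frequencies()
        diff = np.zeros(freqs.size)
        diff[(freqs >= 20) & (freqs <= 24)] = 5.0  # 9 bins, 4.0 Hz edge-to-edge
        bands = select_bands(make_contrast(diff))
        assert len(bands) == 1
        assert (bands[0].f_lo, bands[0].f_hi) == (20.0, 24.0)
        assert bands[0].favored_class == "hand"

    def test_negative_contrast_favors_other_class(self):
        freqs = band_frequencies()
        diff = np.zeros(freqs.size)
        diff[(freqs >= 10) & (freqs <= 18)] = -6.0
        bands = select_bands(make_contrast(diff))
        assert len(bands) == 1
        assert bands[0].favored_class == "elbow"
        assert bands[0].peak_diff_db == pytest.approx(6.0)

    def test_planted_effect_recovered_on_correct_channel(self, beta_effect_epochs):
        con = compute_contrast(beta_effect_epochs, class_a="hand", class_b="elbow")
        bands = select_bands(con)
        assert {b.channel for b in bands} == {"ch04"}
        (band,) = bands
        assert 13.0 <= band.f_lo <= band.f_hi <= 27.0
        assert band.favored_class == "hand"

    def test_peak_mode_is_more_permissive_than_strict(self):
        freqs = band_frequencies()
        diff = np.zeros(freqs.size)
        # 3.5 dB peak inside a broad 2 dB region: fails strict, passes peak mode
        region = (freqs >= 14) & (freqs <= 26)
        diff[region] = 2.0
        diff[(freqs >= 19) & (freqs <= 21)] = 3.5
        con = make_contrast(diff)
        assert select_bands(con, mode="strict") == []
        bands = select_bands(con, mode="peak")
        assert len(bands) == 1 and bands[0].f_lo == 14.0 and bands[0].f_hi == 26.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_swapping_class_roles_flips_favored_class(self, seed):
        rng = np.random.default_rng(seed)
        # smooth random contrast so runs of both signs occur
        raw = rng.normal(0, 4, size=159)
        kernel = np.ones(7) / 7
        diff = np.convolve(raw, kernel, mode="same")
        con = make_contrast(diff)
        fwd = select_bands(con)
        rev = select_bands(con.swapped())
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert (a.channel, a.f_lo, a.f_hi, a.peak_diff_db) == (
                b.channel, b.f_lo, b.f_hi, b.peak_diff_db)
            assert a.favored_class != b.favored_class

    def test_grid_mismatch_rejected(self):
        con = make_contrast(np.zeros(159))
        con.freqs = con.freqs[:-1]
        with pytest.raises(ValueError, match="grid"):
            select_bands(con)

    def test_selected_set_grows_with_planted_magnitude(self):
        from premovement.synthetic import PlantedEffect, SyntheticConfig, generate_dataset

        for seed in (0, 1, 2):
            prev: set[str] = set()
            for mag in (0.0, 3.0, 6.0, 10.0):
                cfg = SyntheticConfig(
                    n_channels=4, trials_per_session_per_class=30,
                    interval_mean=6.0, interval_sd=0.4,
                    planted_effects=[PlantedEffect(
                        channel=2, f_lo=15, f_hi=25,
                        class_with_higher_power="hand", magnitude_db=mag)],
                    rng_seed=seed,
                )
                es = epochs_from_dataset(generate_dataset(cfg))
                con = compute_contrast(es, class_a="hand", class_b="elbow")
                selected = {b.channel for b in select_bands(con)}
                assert prev <= selected
                prev = selected
            assert "ch02" in prev  # 10 dB effect is always found


class TestCanonicalBands:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (15.0, 25.0, {"beta"}),
            (10.0, 20.0, {"alpha", "beta"}),
            (2.0, 7.0, {"delta", "theta"}),
            (35.0, 45.0, {"gamma"}),
            (13.0, 30.0, {"beta"}),  # boundary-touching neighbours excluded
            (5.0, 40.0, {"theta", "alpha", "beta", "gamma"}),
        ],
    )
    def test_overlap(self, lo, hi, expected):
        band = SelectedBand(channel="c", area="", f_lo=lo, f_hi=hi,
                            peak_diff_db=5.0, favored_class="hand")
        assert canonical_band_overlap(band) == expected


class TestBootstrapNull:
    def test_observed_zero_gives_p_one(self, zero_effect_dataset):
        from premovement.preprocess import downsample_to_200, exclude_channels

        rec = exclude_channels(downsample_to_200(zero_effect_dataset.recordings[0]), ["EMG"])
        boot = bootstrap_selection_null(rec, (10, 10), observed_count=0, n_iter=50, seed=0)
        assert boot.p_value == 1.0

    def test_strong_effect_not_matched_by_null(self, beta_effect_dataset):
        from premovement.preprocess import downsample_to_200, exclude_channels

        rec = exclude_channels(downsample_to_200(beta_effect_dataset.recordings[0]), ["EMG"])
        boot = bootstrap_selection_null(rec, (40, 40), observed_count=1, n_iter=50, seed=0)
        assert np.max(boot.null_counts) == 0
        assert boot.p_value == pytest.approx(1 / 51)

    def test_seeded_determinism(self, zero_effect_dataset):
        from premovement.preprocess import downsample_to_200, exclude_channels

        rec = exclude_channels(downsample_to_200(zero_effect_dataset.recordings[0]), ["EMG"])
        a = bootstrap_selection_null(rec, (10, 10), observed_count=1, n_iter=20, seed=7)
        b = bootstrap_selection_null(rec, (10, 10), observed_count=1, n_iter=20, seed=7)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_short_recording_falls_back_to_overlapping_draws(self, rng):
        from premovement.preprocess import Recording

        rec = Recording(signal=rng.normal(size=(2, 2400)), fs=200.0,
                        channel_labels=["a", "b"])
        with pytest.warns(UserWarning, match="overlapping"):
            boot = bootstrap_selection_null(rec, (5, 5), observed_count=0,
                                            n_iter=5, seed=0)
        assert boot.n_iterations == 5


class TestNullCalibration:
    def test_false_selection_rate_decreases_with_trials(self):
        """With no planted effect, chance selections get rarer as trials grow."""
        from premovement.synthetic import SyntheticConfig, generate_dataset

        def rate(n_trials, seeds):
            hits = total = 0
            for seed in seeds:
                cfg = SyntheticConfig(n_channels=4, trials_per_session_per_class=n_trials,
                                      interval_mean=6.0, interval_sd=0.4, rng_seed=seed)
                es = epochs_from_dataset(generate_dataset(cfg))
                con = compute_contrast(es, class_a="hand", class_b="elbow")
                hits += len({b.channel for b in select_bands(con)})
                total += 4
            return hits / total

        seeds = range(8)
        assert rate(80, seeds) <= rate(20, seeds)
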