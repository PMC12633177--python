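"""Wavelet coherence, permutation bin selection and the IBS statistic."""

import warnings

import numpy as np
import pytest

from dyadsync.ibs import (
    CohortCoherence,
    WTCAnalyzer,
    build_null,
    compute_ibs,
    cwt_morlet,
    select_bins,
    time_average,
    wtc,
)
from helpers import brute_force_wtc

FS = 2.0


def _noise(rng, n=256):
    return rng.standard_normal(n)


# ---------------------------------------------------------------------------
# continuous wavelet transform
# ---------------------------------------------------------------------------

class TestCWT:
    def test_sinusoid_localised_at_its_frequency(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 0.25 * t)
        w, freqs, coi = cwt_morlet(x, FS, fmin=0.1, fmax=0.5, voices=12)
        power = np.where(coi, np.abs(w) ** 2, 0.0).sum(axis=1)
        assert abs(freqs[np.argmax(power)] - 0.25) <= 0.25 * (2 ** (1 / 12) - 1)

    def test_zero_signal_zero_coefficients(self):
        w, _, _ = cwt_morlet(np.zeros(256), FS, fmin=0.1, fmax=0.5)
        assert np.allclose(w, 0.0)

    def test_linearity_in_amplitude(self, rng):
        x = _noise(rng)
        w1, _, _ = cwt_morlet(x, FS, fmin=0.1, fmax=0.5)
        w3, _, _ = cwt_morlet(3.0 * x, FS, fmin=0.1, fmax=0.5)
        assert np.allclose(w3, 3.0 * w1, atol=1e-12)

    def test_frequencies_strictly_decreasing(self, small_analyzer):
        assert np.all(np.diff(small_analyzer.freqs) < 0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            WTCAnalyzer(fs=2.0, fmin=0.1, fmax=1.5)


# ---------------------------------------------------------------------------
# wavelet transform coherence
# ---------------------------------------------------------------------------

class TestWTC:
    def test_self_coherence_is_one_inside_coi(self, rng):
        x = _noise(rng, 512)
        m = wtc(x, x, FS, fmin=0.1, fmax=0.5, voices=8)
        assert np.all(m.coherence[m.coi] > 1 - 1e-3)

    def test_symmetry_in_arguments(self, rng):
        x, y = _noise(rng, 300), _noise(rng, 300)
        a = wtc(x, y, FS, fmin=0.1, fmax=0.5, voices=8)
        b = wtc(y, x, FS, fmin=0.1, fmax=0.5, voices=8)
        assert np.allclose(a.coherence, b.coherence, atol=1e-6)

    def test_bounds(self, rng):
        x, y = _noise(rng, 300), _noise(rng, 300)
        m = wtc(x, y, FS, fmin=0.1, fmax=0.5, voices=8)
        assert np.all((m.coherence >= 0) & (m.coherence <= 1))

    def test_matches_brute_force_oracle(self, rng, small_analyzer):
        """FFT implementation equals explicit-convolution WTC to 1e-6."""
        x, y = _noise(rng, 96), _noise(rng, 96)
        fast = small_analyzer.coherence(x, y).coherence
        slow = brute_force_wtc(x, y, small_analyzer)
        assert np.max(np.abs(fast - slow)) < 1e-6

    def test_delayed_copy_keeps_high_coherence(self):
        rng = np.random.default_rng(5)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [0.2, 0.3], "bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(2048))
        lag = 2  # samples; a fraction of the ~4 s period at 0.25 Hz
        y = np.roll(x, lag)
        m = wtc(x, y, FS, fmin=0.15, fmax=0.4, voices=8)
        band = (m.freqs >= 0.2) & (m.freqs <= 0.3)
        vals = m.coherence[band][:, m.coi[band].all(axis=0)]
        assert np.mean(vals) > 0.9

    def test_independent_noise_below_shuffled_null(self, rng):
        xs = [_noise(rng, 512) for _ in range(6)]
        ys = [_noise(rng, 512) for _ in range(6)]
        an = WTCAnalyzer(FS, 0.1, 0.5, voices=8)
        cohort = CohortCoherence(an, xs, ys)
        real = np.nanmean(cohort.real_spectra())
        null = cohort.null_spectra(100, rng).spectra
        null_means = np.nanmean(null, axis=1)
        assert real < np.percentile(null_means, 95)

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            wtc(_noise(rng, 100), _noise(rng, 101), FS, fmin=0.1, fmax=0.5)


# ---------------------------------------------------------------------------
# time averaging
# ---------------------------------------------------------------------------

class TestTimeAverage:
    def test_constant_matrix_returns_constant(self, rng):
        x = _noise(rng, 256)
        m = wtc(x, x, FS, fmin=0.1, fmax=0.5, voices=8)
        m.coherence[:] = 0.37
        spec = time_average(m)
        assert np.allclose(spec[~np.isnan(spec)], 0.37)

    def test_window_restricts_average(self, rng):
        x = _noise(rng, 512)
        m = wtc(x, x, FS, fmin=0.2, fmax=0.5, voices=8)
        # mark the first half with a distinct value
        m.coherence[:, :256] = 0.2
        m.coherence[:, 256:] = 0.8
        early = time_average(m, window=(0.0, 128.0))
        late = time_average(m, window=(128.0, 256.0))
        assert np.nanmean(late) > np.nanmean(early)

    def test_fully_masked_window_warns_and_returns_missing(self, rng):
        x = _noise(rng, 400)
        m = wtc(x, x, FS, fmin=0.1, fmax=0.5, voices=8)
        m.coi[:] = False
        with pytest.warns(UserWarning, match="cone of influence"):
            spec = time_average(m)
        assert np.all(np.isnan(spec))

    def test_empty_window_rejected(self, rng):
        x = _noise(rng, 256)
        m = wtc(x, x, FS, fmin=0.1, fmax=0.5, voices=8)
        with pytest.raises(ValueError, match="empty"):
            time_average(m, window=(10.0, 10.0))


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

class TestPermutationNull:
    def test_null_never_pairs_true_partners(self, rng):
        xs = [_noise(rng, 256) for _ in range(5)]
        ys = [_noise(rng, 256) for _ in range(5)]
        null = build_null(xs, ys, FS, n_perm=200, seed=3,
                          analyzer=WTCAnalyzer(FS, 0.1, 0.5, voices=8))
        assert np.all(null.pairings[:, 0] != null.pairings[:, 1])

    def test_two_dyads_single_pairing_with_multiplicity(self, rng):
        xs = [_noise(rng, 256) for _ in range(2)]
        ys = [_noise(rng, 256) for _ in range(2)]
        null = build_null(xs, ys, FS, n_perm=50, seed=0,
                          analyzer=WTCAnalyzer(FS, 0.1, 0.5, voices=8))
        assert set(null.multiplicity) == {(0, 1), (1, 0)}
        assert sum(null.multiplicity.values()) == 50

    def test_deterministic_per_seed(self, rng):
        xs = [_noise(rng, 256) for _ in range(4)]
        ys = [_noise(rng, 256) for _ in range(4)]
        an = WTCAnalyzer(FS, 0.1, 0.5, voices=8)
        a = build_null(xs, ys, FS, n_perm=64, seed=11, analyzer=an)
        b = build_null(xs, ys, FS, n_perm=64, seed=11, analyzer=an)
        assert np.array_equal(a.pairings, b.pairings)
        assert np.array_equal(a.spectra, b.spectra)

    def test_single_dyad_rejected(self, rng):
        with pytest.raises(ValueError, match="2 dyads"):
            build_null([_noise(rng, 64)], [_noise(rng, 64)], FS, n_perm=10,
                       analyzer=WTCAnalyzer(FS, 0.1, 0.5, voices=8))


# ---------------------------------------------------------------------------
# bin selection and IBS
# ---------------------------------------------------------------------------

class TestSelectBins:
    def test_identical_real_and_null_selects_nothing(self, rng):
        data = rng.uniform(0.2, 0.6, size=(40, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sel = select_bins(data[:20], data, alpha=0.05)
        # same pool on both sides: t ~ 0, selections at most sporadic
        assert sel.mask.sum() <= 1

    def test_elevated_bins_selected(self, rng):
        null = rng.normal(0.3, 0.05, size=(200, 12))
        real = rng.normal(0.3, 0.05, size=(20, 12))
        real[:, 4:7] += 0.2
        sel = select_bins(real, null, alpha=0.05)
        assert sel.mask[4:7].all()
        assert sel.mask.sum() <= 5

    def test_missing_bins_never_selected(self, rng):
        null = rng.normal(0.3, 0.05, size=(100, 5))
        real = rng.normal(0.6, 0.05, size=(10, 5))
        real[:, 2] = np.nan
        sel = select_bins(real, null)
        assert not sel.mask[2] and np.isnan(sel.pvals[2])

    def test_fewer_than_two_real_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="2 real samples"):
            select_bins(rng.random((1, 4)), rng.random((50, 4)))


class TestComputeIBS:
    def test_zero_coherence_gives_zero(self):
        assert compute_ibs(np.zeros(6), np.ones(6, dtype=bool)) == 0.0

    def test_half_coherence_closed_form(self):
        spec = np.full(8, 0.5)
        mask = np.zeros(8, dtype=bool)
        mask[2:5] = True
        assert compute_ibs(spec, mask) == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_unit_coherence_clipped_finite(self):
        z = compute_ibs(np.ones(4), np.ones(4, dtype=bool))
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-6))

    def test_empty_mask_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="empty"):
            z = compute_ibs(np.full(4, 0.5), np.zeros(4, dtype=bool))
        assert np.isnan(z)


# ---------------------------------------------------------------------------
# recovery property
# ---------------------------------------------------------------------------

class TestCouplingRecovery:
    def test_ibs_monotone_in_coupling_strength(self):
        """Band-averaged WTC grows with injected coupling strength."""
        from dyadsync.preprocessing import beer_lambert, intensity_to_od
        from dyadsync.synthetic import DyadSpec, generate_dyad

        an = WTCAnalyzer(7.81, 0.03, 0.3, voices=8)
        band = (an.freqs >= 0.05) & (an.freqs <= 0.1)
        grid = [0.0, 0.3, 0.6, 0.9]
        means = []
        for strength in grid:
            vals = []
            for seed in range(5):
                spec = DyadSpec(
                    n_channels_long=1,
                    n_channels_short=1,
                    duration_s=240.0,
                    coupling_strength=strength,
                    artifact_rate=0.0,
                    seed=1000 + seed,
                )
                rec, _ = generate_dyad(spec)
                sigs = {}
                for subj in ("child", "mother"):
                    od = intensity_to_od(rec.subjects[subj].intensity[0])
                    sigs[subj], _ = beer_lambert(od, 3.0)
                m = an.coherence(sigs["child"], sigs["mother"])
                vals.append(np.nanmean(time_average(m)[band]))
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)
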