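"""Wavelet-transform-coherence inter-brain synchrony (IBS).

For each dyadic channel pair the continuous wavelet transforms of the two
subjects' hemodynamic signals are combined into wavelet transform coherence
(WTC): the squared magnitude of the smoothed cross-spectrum normalised by
the smoothed auto-spectra, smoothed in time (scale-dependent Gaussian) and
in scale (fixed-octave boxcar).  Coherence is averaged over the task window
inside the cone of influence (COI), yielding one coherence value per
frequency bin ("WTC spectrum") per dyad.

Task-related frequency bins are selected by comparing, bin by bin, the real
dyads' spectra against spectra of permuted (non-partner) pairings with
independent two-sample t-tests.  The Fisher z transform of the mean
coherence over the selected bins is the IBS strength of the channel pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.fft import irfft, next_fast_len, rfft
from scipy.ndimage import uniform_filter1d

__all__ = [
    "WTCAnalyzer",
    "WTCMatrix",
    "PermutationNull",
    "BinSelection",
    "CohortCoherence",
    "cwt_morlet",
    "wtc",
    "time_average",
    "build_null",
    "select_bins",
    "compute_ibs",
]

#: coherence is clipped here before the Fisher z transform so z stays finite
COHERENCE_CAP = 1.0 - 1e-6


@dataclass
class WTCMatrix:
    """Coherence in [0, 1] on a (frequency bin) x (time sample) grid."""

    coherence: np.ndarray
    freqs: np.ndarray  # Hz, strictly decreasing with scale index
    coi: np.ndarray  # True where the cell is inside the cone of influence
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.coherence.shape[1]) / self.fs


@dataclass
class PermutationNull:
    """Null WTC spectra from shuffled non-partner pairings."""

    spectra: np.ndarray  # (n_perm, n_bins)
    pairings: np.ndarray  # (n_perm, 2) indices (subject-1 dyad, subject-2 dyad)
    multiplicity: dict  # ordered pairing -> number of times drawn
    seed: int | None = None
    scheme: str = "shuffled-nonpartner"


@dataclass
class BinSelection:
    mask: np.ndarray  # boolean per frequency bin
    pvals: np.ndarray
    alpha: float
    alternative: str


class WTCAnalyzer:
    """Morlet wavelet-coherence engine for one sampling rate and band.

    Parameters
    ----------
    fs : sampling rate in Hz.
    fmin, fmax : analysed frequency range in Hz.  The default band
        (0.01-0.7 Hz) covers the slow hemodynamic fluctuations driving
        interpersonal coupling while excluding the cardiac band.
    voices : frequency bins per octave (geometric scale spacing).
    omega0 : Morlet centre frequency (non-dimensional); 6 is the common
        compromise between time and frequency resolution.
    scale_smooth_octaves : width of the boxcar smoothing across scales.

    Wavelet and smoothing kernels are cached per signal length, so reusing
    one analyzer across a cohort amortises the setup cost.
    """

    def __init__(
        self,
        fs: float,
        fmin: float = 0.01,
        fmax: float = 0.7,
        voices: int = 12,
        omega0: float = 6.0,
        scale_smooth_octaves: float = 0.6,
    ) -> None:
        if fmax >= fs / 2:
            raise ValueError(
                f"fmax={fmax} Hz is at/beyond the Nyquist frequency {fs / 2} Hz"
            )
        if not 0 < fmin < fmax:
            raise ValueError("need 0 < fmin < fmax")
        self.fs = float(fs)
        self.omega0 = float(omega0)
        self.voices = int(voices)
        n_bins = int(np.floor(np.log2(fmax / fmin) * voices)) + 1
        #: frequencies, strictly decreasing as scale grows
        self.freqs = fmax * 2.0 ** (-np.arange(n_bins) / voices)
        # Fourier factor converting scale to equivalent Fourier period
        self.fourier_factor = 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))
        #: wavelet scales in seconds
        self.scales = 1.0 / (self.fourier_factor * self.freqs)
        self.scale_smooth_octaves = float(scale_smooth_octaves)
        self._scale_box = max(1, int(round(scale_smooth_octaves * voices)))
        self._cache: dict[int, tuple] = {}

    # -- kernels ----------------------------------------------------------
    def _kernels(self, n: int):
        """FFT-domain Morlet bank and time-smoothing kernels for length n."""
        if n in self._cache:
            return self._cache[n]
        dt = 1.0 / self.fs
        m = next_fast_len(2 * n)
        omega = 2 * np.pi * np.fft.fftfreq(m, dt)
        s = self.scales[:, None]
        with np.errstate(under="ignore"):
            psi_hat = np.where(
                omega[None, :] > 0,
                np.exp(-0.5 * (s * omega[None, :] - self.omega0) ** 2),
                0.0,
            )
        psi_hat *= np.sqrt(2 * np.pi * s / dt) * np.pi**-0.25

        # zero-phase Gaussian time-smoothing kernel per scale (circular grid)
        tg = np.arange(m) * dt
        tg = np.minimum(tg, m * dt - tg)
        with np.errstate(under="ignore"):
            g = np.exp(-0.5 * (tg[None, :] / s) ** 2)
        g_hat = rfft(g, axis=1)
        # normalisation: kernel mass actually inside the signal support
        ones = np.zeros(m)
        ones[:n] = 1.0
        norm = irfft(rfft(ones)[None, :] * g_hat, m, axis=1)[:, :n]
        self._cache[n] = (m, psi_hat, g_hat, norm)
        return self._cache[n]

    # -- transforms -------------------------------------------------------
    def transform(self, x: np.ndarray) -> np.ndarray:
        """Continuous wavelet transform, shape (n_scales, n_samples)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("transform expects a single time series")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite samples")
        n = x.size
        m, psi_hat, _, _ = self._kernels(n)
        xf = np.fft.fft(x, m)
        return np.fft.ifft(xf[None, :] * psi_hat, axis=1)[:, :n]

    def coi_mask(self, n: int) -> np.ndarray:
        """True where a cell is unaffected by edges (e-folding criterion)."""
        t = np.arange(n) / self.fs
        total = (n - 1) / self.fs
        efold = np.sqrt(2) * self.scales
        return (t[None, :] >= efold[:, None]) & (
            (total - t[None, :]) >= efold[:, None]
        )

    def _smooth(self, f: np.ndarray) -> np.ndarray:
        """Scale-dependent time smoothing then boxcar scale smoothing.

        Accepts real or complex arrays of shape (..., n_scales, n_samples);
        edge effects are renormalised so a constant field stays constant.
        """
        if np.iscomplexobj(f):
            return self._smooth(f.real) + 1j * self._smooth(f.imag)
        n = f.shape[-1]
        m, _, g_hat, norm = self._kernels(n)
        out = irfft(rfft(f, m, axis=-1) * g_hat, m, axis=-1)[..., :n]
        out = out / norm
        if self._scale_box > 1:
            out = uniform_filter1d(out, self._scale_box, axis=-2, mode="nearest")
        return out

    def smoothed_power(self, w: np.ndarray) -> np.ndarray:
        """Smoothed, scale-normalised auto-spectrum of a transform."""
        return self._smooth(np.abs(w) ** 2 / self.scales[:, None])

    def coherence_from_transforms(
        self, wx: np.ndarray, wy: np.ndarray, sx: np.ndarray, sy: np.ndarray
    ) -> np.ndarray:
        cross = self._smooth(wx * np.conj(wy) / self.scales[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.abs(cross) ** 2 / (sx * sy)
        return np.clip(np.nan_to_num(r2), 0.0, 1.0)

    def coherence(self, x: np.ndarray, y: np.ndarray) -> WTCMatrix:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("signals must have equal length")
        wx, wy = self.transform(x), self.transform(y)
        r2 = self.coherence_from_transforms(
            wx, wy, self.smoothed_power(wx), self.smoothed_power(wy)
        )
        return WTCMatrix(r2, self.freqs.copy(), self.coi_mask(x.size), self.fs)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def cwt_morlet(
    x: np.ndarray,
    fs: float,
    fmin: float = 0.01,
    fmax: float = 0.7,
    voices: int = 12,
    omega0: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic-Morlet CWT of one signal.

    Returns ``(coefficients, freqs, coi_mask)`` with geometrically spaced
    frequencies (decreasing) and the e-folding cone-of-influence mask.
    """
    an = WTCAnalyzer(fs, fmin, fmax, voices, omega0)
    w = an.transform(x)
    return w, an.freqs.copy(), an.coi_mask(np.asarray(x).size)


def wtc(x: np.ndarray, y: np.ndarray, fs: float, **kwargs) -> WTCMatrix:
    """Wavelet transform coherence of two equally sampled signals."""
    return WTCAnalyzer(fs, **kwargs).coherence(x, y)


def time_average(
    matrix: WTCMatrix, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Per-bin mean coherence over in-window, in-COI cells.

    ``window`` is ``(start, end)`` in seconds, half-open; ``None`` averages
    the whole recording.  Bins with no valid cell are NaN (missing); if the
    whole window lies outside the COI a warning is emitted.
    """
    n = matrix.coherence.shape[1]
    valid = matrix.coi.copy()
    if window is not None:
        t0, t1 = window
        idx0, idx1 = int(np.ceil(t0 * matrix.fs)), int(np.floor(t1 * matrix.fs))
        idx0, idx1 = max(idx0, 0), min(idx1, n)
        if idx1 <= idx0:
            raise ValueError(f"empty task window {window}")
        keep = np.zeros(n, dtype=bool)
        keep[idx0:idx1] = True
        valid &= keep[None, :]
    counts = valid.sum(axis=1)
    if not counts.any():
        warnings.warn(
            "task window entirely outside the cone of influence: "
            "all frequency bins missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        spec = np.where(
            counts > 0,
            np.where(valid, matrix.coherence, 0.0).sum(axis=1) / np.maximum(counts, 1),
            np.nan,
        )
    return spec


# ---------------------------------------------------------------------------
# cohort-level machinery: cached transforms, permutation null
# ---------------------------------------------------------------------------

class CohortCoherence:
    """WTC spectra for one channel pair across a cohort of dyads.

    Per-subject wavelet transforms and smoothed auto-spectra are computed
    once; real-pair and permuted-pair spectra then only require the (much
    cheaper) smoothed cross-spectrum, which makes 10^2-10^3 permutation
    samples tractable.  All signals must share length and sampling rate.
    """

    def __init__(
        self,
        analyzer: WTCAnalyzer,
        signals_child: list[np.ndarray],
        signals_mother: list[np.ndarray],
        window: tuple[float, float] | None = None,
    ) -> None:
        if len(signals_child) != len(signals_mother):
            raise ValueError("need one signal per subject per dyad")
        self.an = analyzer
        self.n_dyads = len(signals_child)
        lengths = {np.asarray(s).size for s in signals_child + signals_mother}
        if len(lengths) != 1:
            raise ValueError("all signals must share the same length")
        self.n_samples = lengths.pop()
        self._wc = [analyzer.transform(s) for s in signals_child]
        self._wm = [analyzer.transform(s) for s in signals_mother]
        self._sc = [analyzer.smoothed_power(w) for w in self._wc]
        self._sm = [analyzer.smoothed_power(w) for w in self._wm]
        valid = analyzer.coi_mask(self.n_samples)
        if window is not None:
            t0, t1 = window
            idx0 = max(int(np.ceil(t0 * analyzer.fs)), 0)
            idx1 = min(int(np.floor(t1 * analyzer.fs)), self.n_samples)
            if idx1 <= idx0:
                raise ValueError(f"empty task window {window}")
            keep = np.zeros(self.n_samples, dtype=bool)
            keep[idx0:idx1] = True
            valid = valid & keep[None, :]
        self._valid = valid
        self._counts = valid.sum(axis=1)
        self._pair_cache: dict[tuple[int, int], np.ndarray] = {}

    @property
    def freqs(self) -> np.ndarray:
        return self.an.freqs

    def spectrum(self, i: int, j: int) -> np.ndarray:
        """Time-averaged WTC spectrum of child i paired with mother j."""
        key = (i, j)
        if key not in self._pair_cache:
            r2 = self.an.coherence_from_transforms(
                self._wc[i], self._wm[j], self._sc[i], self._sm[j]
            )
            with np.errstate(invalid="ignore"):
                spec = np.where(
                    self._counts > 0,
                    np.where(self._valid, r2, 0.0).sum(axis=1)
                    / np.maximum(self._counts, 1),
                    np.nan,
                )
            self._pair_cache[key] = spec
        return self._pair_cache[key]

    def real_spectra(self) -> np.ndarray:
        """Spectra of the true pairings, shape (n_dyads, n_bins)."""
        return np.array([self.spectrum(i, i) for i in range(self.n_dyads)])

    def null_spectra(
        self, n_perm: int = 1000, seed: int | np.random.Generator | None = None
    ) -> PermutationNull:
        """Spectra of shuffled non-partner pairings.

        Each sample pairs a child signal with a uniformly drawn *non-partner*
        mother signal.  Distinct pairings are computed once and duplicates
        are recorded in ``multiplicity`` (with few dyads the number of
        distinct non-partner pairings, n*(n-1), can be below ``n_perm``).
        """
        if self.n_dyads < 2:
            raise ValueError("permutation null requires at least 2 dyads")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        child = rng.integers(0, self.n_dyads, size=n_perm)
        offset = rng.integers(1, self.n_dyads, size=n_perm)
        mother = (child + offset) % self.n_dyads
        pairings = np.column_stack([child, mother])
        spectra = np.array([self.spectrum(i, j) for i, j in pairings])
        mult: dict[tuple[int, int], int] = {}
        for i, j in pairings:
            mult[(int(i), int(j))] = mult.get((int(i), int(j)), 0) + 1
        return PermutationNull(
            spectra=spectra,
            pairings=pairings,
            multiplicity=mult,
            seed=None if isinstance(seed, np.random.Generator) else seed,
        )


def build_null(
    signals_child: list[np.ndarray],
    signals_mother: list[np.ndarray],
    fs: float,
    n_perm: int = 1000,
    seed: int | None = None,
    window: tuple[float, float] | None = None,
    analyzer: WTCAnalyzer | None = None,
) -> PermutationNull:
    """Permutation null of WTC spectra for one channel pair of a cohort."""
    an = analyzer or WTCAnalyzer(fs)
    cohort = CohortCoherence(an, signals_child, signals_mother, window)
    return cohort.null_spectra(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# frequency-bin selection and the IBS statistic
# ---------------------------------------------------------------------------

def select_bins(
    real_spectra: np.ndarray,
    null_spectra: np.ndarray | PermutationNull,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> BinSelection:
    """Identify task-related frequency bins.

    Per frequency bin, a two-sample Welch t-test compares the real dyads'
    coherence values against the permutation samples; bins where the real
    coherence exceeds the null at ``p < alpha`` are selected.  The default
    is one-sided ("task-related" means *elevated* coherence); pass
    ``alternative="two-sided"`` for the symmetric test.  Bins that are
    missing (NaN) on either side are never selected.  An empty selection
    returns an all-False mask with a warning, not an error.
    """
    if isinstance(null_spectra, PermutationNull):
        null_spectra = null_spectra.spectra
    real = np.atleast_2d(np.asarray(real_spectra, dtype=float))
    null = np.atleast_2d(np.asarray(null_spectra, dtype=float))
    if real.shape[0] < 2:
        raise ValueError("need at least 2 real samples per bin")
    if real.shape[1] != null.shape[1]:
        raise ValueError("real and null spectra must share frequency bins")
    n_bins = real.shape[1]
    pvals = np.full(n_bins, np.nan)
    ok = ~(np.isnan(real).any(axis=0) | np.isnan(null).any(axis=0))
    if ok.any():
        res = stats.ttest_ind(
            real[:, ok], null[:, ok], axis=0, equal_var=False, alternative=alternative
        )
        pvals[ok] = res.pvalue
    mask = np.where(np.isnan(pvals), False, pvals < alpha)
    if not mask.any():
        warnings.warn("no frequency bin selected at alpha=%g" % alpha, stacklevel=2)
    return BinSelection(mask=mask.astype(bool), pvals=pvals, alpha=alpha,
                        alternative=alternative)


def compute_ibs(spectrum: np.ndarray, mask: np.ndarray | BinSelection) -> float:
    """Fisher-z IBS: ``z = atanh(mean coherence over selected bins)``.

    Coherence is clipped at ``1 - 1e-6`` before the transform so the value
    is always finite.  An empty mask (or all-missing selected bins) yields
    NaN with a warning naming the reason.
    """
    if isinstance(mask, BinSelection):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    spectrum = np.asarray(spectrum, dtype=float)
    if mask.shape != spectrum.shape:
        raise ValueError("mask and spectrum must align")
    if not mask.any():
        warnings.warn("empty bin mask: IBS undefined", stacklevel=2)
        return float("nan")
    vals = spectrum[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("all selected bins missing: IBS undefined", stacklevel=2)
        return float("nan")
    return float(np.arctanh(np.clip(np.mean(vals), 0.0, COHERENCE_CAP)))
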