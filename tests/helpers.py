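"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (explicit loops and DFT
sums, no FFT shortcuts, no shared code with the package) so that agreement
with the package is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# brute-force wavelet transform coherence
# ---------------------------------------------------------------------------

def brute_force_wtc(x, y, analyzer):
    """WTC by explicit circular convolution, mirroring ``analyzer``'s grid.

    Uses the same analytic-Morlet frequency sampling, scale grid, Gaussian
    time smoothing and boxcar scale smoothing as the package, but computes
    every convolution as an explicit O(N*M) sum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    m, psi_hat, _, _ = analyzer._kernels(n)
    dt = 1.0 / analyzer.fs
    scales = analyzer.scales

    # wavelet impulse responses: inverse DFT of the sampled frequency response
    k = np.arange(m)
    # (m x m) DFT matrix applied per scale is too big; do per-scale explicit sums
    def idft_row(row):
        out = np.empty(m, dtype=complex)
        for t in range(m):
            out[t] = np.sum(row * np.exp(2j * np.pi * k * t / m)) / m
        return out

    def circ_conv(sig, kern):
        out = np.empty(m, dtype=complex)
        for t in range(m):
            acc = 0.0 + 0.0j
            for tau in range(n):  # sig is zero beyond n
                acc += sig[tau] * kern[(t - tau) % m]
            out[t] = acc
        return out

    wx = np.empty((len(scales), n), dtype=complex)
    wy = np.empty((len(scales), n), dtype=complex)
    for si in range(len(scales)):
        kern = idft_row(psi_hat[si])
        wx[si] = circ_conv(x, kern)[:n]
        wy[si] = circ_conv(y, kern)[:n]

    # Gaussian time smoothing on the circular m-grid, renormalised to the
    # kernel mass inside the signal support
    tg = np.arange(m) * dt
    tg = np.minimum(tg, m * dt - tg)

    def smooth_time(field):
        out = np.empty((len(scales), n), dtype=field.dtype)
        for si, s in enumerate(scales):
            g = np.exp(-0.5 * (tg / s) ** 2)
            for t in range(n):
                num = 0.0
                den = 0.0
                for tau in range(n):
                    w = g[(t - tau) % m]
                    num += field[si, tau] * w
                    den += w
                out[si, t] = num / den
        return out

    def smooth_scale(field):
        box = analyzer._scale_box
        if box <= 1:
            return field
        half = box // 2
        ns = field.shape[0]
        out = np.empty_like(field)
        for si in range(ns):
            acc = 0.0
            for j in range(si - half, si - half + box):
                acc += field[min(max(j, 0), ns - 1)]  # replicate edges
            out[si] = acc / box
        return out

    def smooth(field):
        if np.iscomplexobj(field):
            return smooth(field.real) + 1j * smooth(field.imag)
        return smooth_scale(smooth_time(field))

    sx = smooth(np.abs(wx) ** 2 / scales[:, None])
    sy = smooth(np.abs(wy) ** 2 / scales[:, None])
    sxy = smooth(wx * np.conj(wy) / scales[:, None])
    return np.clip(np.abs(sxy) ** 2 / (sx * sy), 0.0, 1.0)


# ---------------------------------------------------------------------------
# brute-force Benjamini-Hochberg
# ---------------------------------------------------------------------------

def brute_force_bh(pvals, alpha=0.05):
    """Step-up BH by direct definition.

    Rejects H_(1)..H_(k) where k = max{i : p_(i) <= i/m * alpha}; adjusted
    values are q_(i) = min_{j>=i} (m/j) p_(j).
    """
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k = 0
    for i in range(1, m + 1):
        if ps[i - 1] <= i / m * alpha:
            k = i
    reject_sorted = np.arange(m) < k
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m / (i + 1) * ps[i])
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    reject = np.empty(m, dtype=bool)
    q[order] = q_sorted
    reject[order] = reject_sorted
    return q, reject


# ---------------------------------------------------------------------------
# brute-force Kendall tau-b
# ---------------------------------------------------------------------------

def brute_force_kendall(x, y):
    """Tau-b by O(n^2) enumeration of concordant/discordant/tied pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


# ---------------------------------------------------------------------------
# closed-form two-sample t-test power (known sigma approximation)
# ---------------------------------------------------------------------------

def normal_approx_power(delta, sigma, n, alpha=0.05):
    """Two-sided two-sample z-test power for mean shift ``delta``."""
    from scipy.stats import norm

    se = sigma * np.sqrt(2.0 / n)
    crit = norm.ppf(1 - alpha / 2)
    lam = delta / se
    return float(norm.cdf(-crit + lam) + norm.cdf(-crit - lam))
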