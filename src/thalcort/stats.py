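"""Group-level statistics and control analyses.

Paired non-parametric comparisons across subjects (one-tailed Wilcoxon
signed-rank, exact for small n), a subjects-as-Bernoulli-trials binomial
test, the Tort modulation index for phase-amplitude coupling, Lempel-Ziv
complexity of binarized signals, the bi-symmetric log transform for plotting
signed quantities spanning decades, a permutation ANCOVA (Freedman-Lane
residual permutation), and per-subject baseline normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats as sps

__all__ = [
    "PairedSample",
    "wilcoxon_one_tailed",
    "binomial_subjects",
    "modulation_index",
    "lempel_ziv",
    "bisymlog",
    "perm_ancova",
    "normalize_to_baseline",
]


@dataclass
class PairedSample:
    """Per-subject baseline (waking) and altered-state values."""

    subjects: list
    baseline: np.ndarray
    condition: np.ndarray

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.condition = np.asarray(self.condition, dtype=float)
        if not (len(self.subjects) == self.baseline.size == self.condition.size):
            raise ValueError("subjects, baseline, condition must align")


def wilcoxon_one_tailed(sample: PairedSample, direction: str = "less") -> float:
    """One-tailed Wilcoxon signed-rank p for condition vs baseline.

    ``direction='less'`` tests whether condition values are shifted below
    baseline.  For n <= 25 without ties the null is enumerated exactly, so
    all-subjects-one-way p-values are the dyadic rationals 1/2^n (0.002 at
    n = 9, 0.0078 at n = 7, 0.0312 at n = 5).  Ties in |differences| force
    the normal approximation, with a warning.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    d = sample.condition - sample.baseline
    if d.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    absd = np.abs(d[d != 0])
    has_ties = len(np.unique(absd)) < absd.size
    method = "approx" if (has_ties or d.size > 25) else "exact"
    if has_ties:
        warnings.warn("tied |differences|: falling back to the normal "
                      "approximation", stacklevel=2)
    res = sps.wilcoxon(d, alternative=direction, method=method)
    return float(res.pvalue)


def binomial_subjects(successes: int, n: int, p0: float = 0.05) -> float:
    """One-sided P(X >= successes) for X ~ Binomial(n, p0).

    Treats each subject as a Bernoulli trial whose "success" is a
    significant within-subject result under the null rate ``p0``.
    """
    if not (0 <= successes <= n):
        raise ValueError("need 0 <= successes <= n")
    return float(sps.binomtest(successes, n, p0, alternative="greater").pvalue)


def modulation_index(phase_src, amp_src, fs: float,
                     phase_band=(1.0, 13.0), amp_band=(52.0, 104.0),
                     n_bins: int = 18) -> float:
    """Tort modulation index of phase-amplitude coupling.

    Phase of the slow band of ``phase_src`` (analytic signal) is binned; the
    mean fast-band amplitude envelope of ``amp_src`` per bin, normalized to
    a distribution, gives MI = (ln n_bins - H) / ln n_bins in [0, 1]: 0 for
    amplitude independent of phase, 1 when all amplitude concentrates in a
    single phase bin.
    """
    x = np.asarray(phase_src, dtype=float)
    y = np.asarray(amp_src, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share length")
    sos_p = signal.butter(4, phase_band, btype="bandpass", fs=fs, output="sos")
    sos_a = signal.butter(4, amp_band, btype="bandpass", fs=fs, output="sos")
    ph = np.angle(signal.hilbert(signal.sosfiltfilt(sos_p, x)))
    amp = np.abs(signal.hilbert(signal.sosfiltfilt(sos_a, y)))
    if np.all(amp == 0):
        return 0.0
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
    mean_amp = np.array([amp[which == b].mean() if np.any(which == b) else 0.0
                         for b in range(n_bins)])
    total = mean_amp.sum()
    if total == 0:
        return 0.0
    p = mean_amp / total
    nz = p > 0
    H = -np.sum(p[nz] * np.log(p[nz]))
    return float((np.log(n_bins) - H) / np.log(n_bins))


def lempel_ziv(series) -> float:
    """Normalized Lempel-Ziv (LZ76) complexity of the median-binarized series.

    The LZ76 phrase count c(n) is normalized by its random-sequence
    asymptote n / log2(n), so white noise scores near 1 and constant or
    strictly periodic sequences near 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(x) == 0:
        return 0.0
    bits = (x > np.median(x)).astype(np.uint8)
    s = bits.tobytes()
    n = len(s)
    # LZ76 parsing: count exhaustive phrases
    i, c, k, l = 0, 1, 1, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return float(c * np.log2(n) / n)


def bisymlog(x, C: float = 1.0):
    """Bi-symmetric log transform: sign(x) * log10(1 + |x|/C).

    Odd, monotone, linear near zero and logarithmic in both tails; used to
    display signed quantities spanning several orders of magnitude.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.log10(1.0 + np.abs(x) / C)
    return out if out.ndim else float(out)


def perm_ancova(values, state_labels, covariates=None, n_perm: int = 10000,
                seed: int = 0) -> float:
    """Permutation ANCOVA for a state effect adjusted for covariates.

    The observed F statistic for the state factor comes from an OLS fit of
    ``values`` on state dummies plus covariates; the null distribution uses
    Freedman-Lane permutation of the covariate-only residuals.  p honors
    the permutation floor 1/(n_perm + 1).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(state_labels)
    states = np.unique(labels)
    if states.size < 2:
        raise ValueError("need at least two states")
    n = y.size
    dummies = np.column_stack([(labels == s).astype(float)
                               for s in states[1:]])
    Z = np.column_stack([np.ones(n)])
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n:
            cov = cov.T
        Z = np.column_stack([Z, cov.T])
    X_full = np.column_stack([Z, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix")

    def f_stat(yy):
        bz, *_ = np.linalg.lstsq(Z, yy, rcond=None)
        rss0 = float(np.sum((yy - Z @ bz) ** 2))
        bf, *_ = np.linalg.lstsq(X_full, yy, rcond=None)
        rss1 = float(np.sum((yy - X_full @ bf) ** 2))
        df1 = dummies.shape[1]
        df2 = n - X_full.shape[1]
        return ((rss0 - rss1) / df1) / (rss1 / df2)

    bz, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ bz
    resid = y - fitted
    f_obs = f_stat(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        y_perm = fitted + rng.permutation(resid)
        if f_stat(y_perm) >= f_obs:
            count += 1
    return float((1 + count) / (1 + n_perm))


def normalize_to_baseline(values, baseline: float):
    """Divide a subject's values by their waking-baseline median."""
    if baseline == 0:
        raise ValueError("zero baseline")
    return np.asarray(values, dtype=float) / baseline
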