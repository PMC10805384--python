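"""Seeded synthetic generators with known ground truth for every estimator.

Three families:

* ``gen_coupled_pair`` -- a paired signal in which the low band (1-13 Hz) of
  the sender modulates the high-gamma (52-104 Hz at 416 Hz) amplitude of the
  receiver at a fixed delay: ground truth for band-pair directed transfer.
* ``gen_chaos_suite`` -- canonical chaotic/periodic/stochastic series with
  known labels for the 0-1 test.
* ``gen_var_pair`` -- a linear-Gaussian bivariate autoregressive pair whose
  transfer entropy has a closed form (half the log ratio of restricted to
  full one-step prediction error), computed here by an internal regression
  oracle independent of the kNN estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "CoupledBandSpec",
    "gen_coupled_pair",
    "gen_chaos_suite",
    "gen_var_pair",
    "logistic_map",
]


@dataclass(frozen=True)
class CoupledBandSpec:
    """Parameters of the cross-frequency coupled benchmark pair."""

    fs: float = 416.0
    duration: float = 10.0
    carrier_hz: float = 78.0
    slow_hz: float = 6.0
    depth: float = 0.8
    delay: int = 10           # samples at fs
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.depth <= 1):
            raise ValueError("depth must lie in [0, 1]")
        if not (self.fs / 8 < self.carrier_hz <= self.fs / 4):
            raise ValueError(
                f"carrier {self.carrier_hz} Hz outside the level-2 dyadic band "
                f"({self.fs / 8:.0f}-{self.fs / 4:.0f} Hz) at fs={self.fs}")
        if not (self.fs / 512 < self.slow_hz <= self.fs / 32):
            raise ValueError(
                f"slow drive {self.slow_hz} Hz outside the level 5-8 bands at "
                f"fs={self.fs}")


def gen_coupled_pair(spec: CoupledBandSpec = CoupledBandSpec()):
    """Low-band sender whose delayed waveform modulates the receiver's carrier.

    X carries the slow drive (plus broadband noise); Y carries a high-gamma
    carrier whose amplitude envelope is 1 + depth * slow(t - delay), plus an
    *independent* slow component and noise, so the only directed coupling is
    X -> Y from the low band into the high band at the given sample delay.
    Returns ``(X, Y, truth_dict)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    # slightly irregular slow drive: jittered phase keeps it band-limited but
    # non-deterministic, so the envelope carries information
    phase_noise = np.cumsum(rng.standard_normal(n)) * 0.05
    slow = np.sin(2 * np.pi * spec.slow_hz * t + phase_noise)
    x = slow + spec.noise_sd * rng.standard_normal(n)

    slow_del = np.roll(slow, spec.delay)
    carrier = np.sin(2 * np.pi * spec.carrier_hz * t + rng.uniform(0, 2 * np.pi))
    slow_indep = np.sin(2 * np.pi * spec.slow_hz * t
                        + np.cumsum(rng.standard_normal(n)) * 0.05
                        + rng.uniform(0, 2 * np.pi))
    y = ((1.0 + spec.depth * slow_del) * carrier + slow_indep
         + spec.noise_sd * rng.standard_normal(n))
    truth = {
        "direction": "X->Y",
        "send_band_hz": (1.0, 13.0),
        "recv_band_hz": (spec.fs / 8, spec.fs / 4),
        "send_levels": (5, 6, 7, 8),
        "recv_levels": (2,),
        "delay_samples": spec.delay,
        "depth": spec.depth,
        **asdict(spec),
    }
    return x, y, truth


def logistic_map(r: float, n: int, x0: float = 0.4, burn: int = 100) -> np.ndarray:
    x = x0
    out = np.empty(n)
    for i in range(n + burn):
        x = r * x * (1.0 - x)
        if i >= burn:
            out[i - burn] = x
    return out


def gen_chaos_suite(seed: int = 0, n: int = 5000):
    """Labeled benchmark series for the 0-1 chaos test.

    Logistic maps at r = 3.2 (period-2), 3.99 and 4.0 (chaotic, Lyapunov
    exponent ln 2 at r = 4), a noisy sine, and Gaussian white noise.  The
    'stochastic' label marks series outside the deterministic scope of the
    test.  Returns ``{name: (series, label)}``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    suite = {
        "logistic_r3.2": (logistic_map(3.2, n, x0=rng.uniform(0.2, 0.8)),
                          "periodic"),
        "logistic_r3.99": (logistic_map(3.99, n, x0=rng.uniform(0.2, 0.8)),
                           "chaotic"),
        "logistic_r4.0": (logistic_map(4.0, n, x0=rng.uniform(0.2, 0.8)),
                          "chaotic"),
        "noisy_sine": (np.sin(2 * np.pi * 0.05 * t)
                       + 0.2 * rng.standard_normal(n), "stochastic"),
        "white_noise": (rng.standard_normal(n), "stochastic"),
    }
    return suite


def gen_var_pair(coeffs: dict | None = None, n: int = 4096, seed: int = 0,
                 u: int = 1):
    """Bivariate linear-Gaussian AR pair plus its closed-form TE.

    ``Y_t = a*Y_{t-1} + c*X_{t-u} + e_y``; ``X_t = b*X_{t-1} + e_x``.  For a
    linear-Gaussian system transfer entropy equals Granger causality / 2:
    TE = 0.5 * ln(var(restricted residual)/var(full residual)), which an
    internal OLS oracle computes on the realized series.  Returns
    ``(X, Y, te_analytic_nats)``.
    """
    c = dict(a=0.5, b=0.5, c=0.4, sx=1.0, sy=1.0)
    if coeffs:
        c.update(coeffs)
    if abs(c["a"]) >= 1 or abs(c["b"]) >= 1:
        raise ValueError("unstable autoregressive coefficients")
    rng = np.random.default_rng(seed)
    burn = 200
    m = n + burn
    ex = c["sx"] * rng.standard_normal(m)
    ey = c["sy"] * rng.standard_normal(m)
    x = np.zeros(m)
    y = np.zeros(m)
    for t in range(1, m):
        x[t] = c["b"] * x[t - 1] + ex[t]
        y[t] = c["a"] * y[t - 1] + (c["c"] * x[t - u] if t - u >= 0 else 0.0) \
            + ey[t]
    x, y = x[burn:], y[burn:]

    # regression oracle: restricted (own past) vs full (own past + source)
    t0 = max(1, u)
    yt = y[t0:]
    yp = y[t0 - 1:-1]
    xp = x[t0 - u:len(x) - u]
    Zr = np.column_stack([np.ones_like(yp), yp])
    Zf = np.column_stack([np.ones_like(yp), yp, xp])
    br, *_ = np.linalg.lstsq(Zr, yt, rcond=None)
    bf, *_ = np.linalg.lstsq(Zf, yt, rcond=None)
    var_r = float(np.mean((yt - Zr @ br) ** 2))
    var_f = float(np.mean((yt - Zf @ bf) ** 2))
    te = 0.5 * float(np.log(var_r / var_f))
    return x, y, te
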