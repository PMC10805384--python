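"""Parameter search for the mean-field model's brain-state configurations.

A scalar fitness encodes each state's target dynamics -- waking: firing
rates inside physiological ranges, an alpha-band spectral peak, low LFP
amplitude, weak chaoticity; anesthesia: minimal cortical firing with
information-poor, strongly chaotic, delta-dominated LFPs and little power
above 60 Hz; seizure: periodic, information-poor 2-8 Hz oscillations.  A
seeded tournament-selection genetic search optimizes bounded parameter
vectors against these criteria.  (The shipped optimizer is a plain genetic
search; the fitness criteria are the full specification of each state.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meanfield import SimulationResult, lfp
from .preprocess import welch_psd
from .stats import lempel_ziv

__all__ = ["FitnessSpec", "fitness", "genetic_search", "TARGET_RATE_RANGES"]

#: Empirical firing-rate ranges (s^-1) per population, unions across the
#: mammalian species with printed values.
TARGET_RATE_RANGES = {
    "cortex_excitatory": (1.0, 20.0),
    "striatum_D1": (1.0, 7.0),
    "striatum_D2": (1.0, 7.0),
    "GPi_SNr": (15.0, 90.0),
    "GPe": (1.0, 115.0),
    "STN": (8.0, 30.0),
    "relay_nuclei": (5.0, 25.0),
    "TRN": (4.0, 64.0),
}


@dataclass(frozen=True)
class FitnessSpec:
    state: str                                   # waking | anesthesia | seizure
    rate_ranges: dict = field(default_factory=lambda: dict(TARGET_RATE_RANGES))
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.state not in ("waking", "anesthesia", "seizure"):
            raise ValueError(f"unknown state {self.state!r}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if any(hi <= lo for lo, hi in self.rate_ranges.values()):
            raise ValueError("empty rate range")

    def weight(self, name: str, default: float = 1.0) -> float:
        return float(self.weights.get(name, default))


def _band_power(f, p, lo, hi):
    m = (f >= lo) & (f < hi)
    return float(np.trapezoid(p[m], f[m])) if np.any(m) else 0.0


def _rate_penalty(sim: SimulationResult, ranges: dict, burn_in: float) -> float:
    keep = sim.t >= burn_in
    pen = 0.0
    for i, lab in enumerate(sim.populations):
        if lab not in ranges:
            continue
        lo, hi = ranges[lab]
        r = float(sim.Q[i, keep].mean())
        mid = 0.5 * (lo + hi)
        if r < lo:
            pen += (lo - r) / mid
        elif r > hi:
            pen += (r - hi) / mid
    return pen


def fitness(sim: SimulationResult, spec: FitnessSpec, *, lle: float | None = None,
            te_strength: float | None = None, burn_in: float = 5.0) -> float:
    """Score a simulation against a brain-state's target dynamics.

    Deterministic given the simulation.  ``lle`` (twin-run Lyapunov
    exponent) and ``te_strength`` (cross-frequency TE strength) are costly
    side measurements the caller may supply; their criteria are skipped when
    absent.  Higher is better.
    """
    if sim.t[-1] - burn_in < 10.0 - 1e-9:
        raise ValueError("need >= 10 s of post-burn-in simulation")
    keep = sim.t >= burn_in
    ctx = lfp(sim, "cortex_excitatory")[keep]
    if ctx.size == 0:
        raise ValueError("missing cortical series")
    ctx_rate = float(sim.Q[sim.populations.index("cortex_excitatory"), keep].mean())
    f, p = welch_psd(ctx - ctx.mean(), fs=sim.fs)
    total = _band_power(f, p, 0.5, min(200.0, f[-1])) + 1e-30

    score = 0.0
    if spec.state == "waking":
        score -= spec.weight("rates", 3.0) * _rate_penalty(sim, spec.rate_ranges,
                                                           burn_in)
        alpha_frac = _band_power(f, p, 8, 13) / total
        score += spec.weight("alpha_peak") * alpha_frac
        # low-amplitude LFPs: soft penalty above ~1 mV fluctuation
        score -= spec.weight("amplitude", 0.5) * max(
            0.0, np.log10(ctx.std() / 1e-3 + 1e-30))
        if lle is not None:
            # weakly chaotic: reward small positive exponents
            score += spec.weight("weak_chaos") * float(np.exp(-abs(lle - 0.5)))
        if te_strength is not None:
            score += spec.weight("te") * float(np.tanh(10.0 * te_strength))
        # envelope correlation between cortical rate and 60-200 Hz LFP amplitude
        hf = _band_power(f, p, 60, min(200.0, f[-1])) / total
        score += spec.weight("broadband", 0.2) * float(hf > 1e-4)
    elif spec.state == "anesthesia":
        score -= spec.weight("cortical_rate", 1.0) * ctx_rate / 10.0
        delta_frac = _band_power(f, p, 0.5, 4) / total
        hi_frac = _band_power(f, p, 60, min(200.0, f[-1])) / total
        score += spec.weight("delta") * delta_frac
        score -= spec.weight("high_freq") * hi_frac
        try:
            score -= spec.weight("information", 0.5) * lempel_ziv(ctx)
        except ValueError:
            pass
        if lle is not None:
            score += spec.weight("strong_chaos") * float(np.tanh(lle / 2.0))
    else:  # seizure
        band_frac = _band_power(f, p, 2, 8) / total
        score += spec.weight("spike_wave", 2.0) * band_frac
        try:
            score -= spec.weight("information", 0.5) * lempel_ziv(ctx)
        except ValueError:
            pass
        if lle is not None:
            score += spec.weight("periodic") * float(np.tanh(-lle / 2.0))
    return float(score)


def genetic_search(objective, bounds, population_size: int = 16,
                   generations: int = 20, seed: int = 0, *,
                   tournament: int = 3, mutation_sd: float = 0.15,
                   crossover_p: float = 0.5):
    """Seeded elitist genetic search over a box-bounded parameter vector.

    ``objective(x) -> float`` is maximized.  Tournament selection, uniform
    crossover, Gaussian mutation (``mutation_sd`` as a fraction of each
    bound's span) clipped to the bounds.  The single best individual is
    carried over unchanged each generation, so the best-so-far trace is
    non-decreasing.  Returns ``(best_x, best_f, history)`` with ``history``
    the per-generation best fitness.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be (n_params, 2)")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(seed)
    pop = lo + span * rng.random((population_size, bounds.shape[0]))
    fit = np.array([objective(x) for x in pop])
    history = []
    for _ in range(generations):
        best = int(np.argmax(fit))
        new = [pop[best].copy()]
        while len(new) < population_size:
            idx1 = rng.choice(population_size, tournament, replace=False)
            idx2 = rng.choice(population_size, tournament, replace=False)
            p1 = pop[idx1[np.argmax(fit[idx1])]]
            p2 = pop[idx2[np.argmax(fit[idx2])]]
            mask = rng.random(bounds.shape[0]) < crossover_p
            child = np.where(mask, p1, p2)
            child = child + mutation_sd * span * rng.standard_normal(len(child)) \
                * (rng.random(len(child)) < 0.3)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = np.array([objective(x) for x in pop])
        history.append(float(fit.max()))
    best = int(np.argmax(fit))
    # elitism guarantees monotonicity; enforce under objective noise as well
    history = list(np.maximum.accumulate(history))
    return pop[best].copy(), float(fit[best]), history
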