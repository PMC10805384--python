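"""Mean-field model of the basal ganglia-thalamo-cortical system.

Nine neural populations (cortical excitatory and inhibitory, striatal D1 and
D2, GPi/SNr treated as one output structure, GPe, STN, thalamic relay nuclei,
and the thalamic reticular nucleus) are coupled by delayed projections.  Each
population fires at a sigmoidal rate of its mean soma potential; each afferent
projection contributes a dendritic potential governed by a second-order
synaptic operator whose impulse response is rescaled so that its *peak* (not
its area) is fixed at H = 31.5 s^-1 for every rise/decay pair -- slowing the
decay rate then prolongs the response and increases the transferred charge,
which is how GABAergic anesthesia is represented.  Outgoing mean fields obey
a damped wave equation reduced to its spatially uniform mode (the Laplacian
term is dropped; the model carries no spatial structure).

A "dose" D interpolates every parameter geometrically between a waking set
P0 and an altered-state set P1: P = P0 * (P1/P0)**D, which preserves signs
and saturates as D grows.

Local field potentials are modeled as the sum of the absolute values of a
population's dendritic potentials (superposition of synaptic currents).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "POPULATION_LABELS",
    "SYNAPTIC_PEAK",
    "Population",
    "Projection",
    "ExternalInput",
    "ModelConfig",
    "DoseSpec",
    "SimulationResult",
    "SimulationBlowUpError",
    "firing_rate",
    "synaptic_peak_unscaled",
    "synaptic_response",
    "synaptic_time_to_peak",
    "interpolate_dose",
    "interpolate_config",
    "fixed_point",
    "integrate",
    "lfp",
    "dose_sweep",
]

#: Fixed peak of the rescaled synaptic response (s^-1).
SYNAPTIC_PEAK = 31.5

POPULATION_LABELS = (
    "cortex_excitatory",
    "cortex_inhibitory",
    "striatum_D1",
    "striatum_D2",
    "GPi_SNr",
    "GPe",
    "STN",
    "relay_nuclei",
    "TRN",
)

#: Source populations whose projections must be inhibitory (GABAergic).
INHIBITORY_SOURCES = frozenset(
    {"cortex_inhibitory", "striatum_D1", "striatum_D2", "GPi_SNr", "GPe", "TRN"}
)


class SimulationBlowUpError(RuntimeError):
    """Raised when the integration produces a non-finite state."""

    def __init__(self, population: str, t: float):
        self.population = population
        self.t = t
        super().__init__(
            f"simulation diverged: population '{population}' became non-finite "
            f"at t = {t:.4f} s"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One neural mass.

    Parameters
    ----------
    label : str
        One of :data:`POPULATION_LABELS`.
    Q_max : float
        Maximum firing rate (s^-1).
    theta : float
        Mean firing threshold potential (V).
    sigma_prime : float
        Spread of cell-body potentials relative to threshold (V).
    alpha, beta : float
        Decay and rise rates of the dendritic response (s^-1); the receptor-
        side defaults for afferent synapses onto this population.
    """

    label: str
    Q_max: float
    theta: float
    sigma_prime: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.label not in POPULATION_LABELS:
            raise ValueError(f"unknown population label {self.label!r}")
        if self.Q_max <= 0:
            raise ValueError("Q_max must be positive")
        if self.sigma_prime <= 0:
            raise ValueError("sigma_prime must be positive")
        if not (0 < self.alpha <= self.beta):
            raise ValueError("need 0 < alpha <= beta (decay no faster than rise)")


@dataclass(frozen=True)
class Projection:
    """A delayed synaptic projection between two populations.

    ``coupling_strength`` is the synaptic coupling nu_ab in V*s (negative for
    inhibitory sources).  ``damping`` is the temporal damping coefficient
    gamma_ab = v_ab / r_ab of the field equation, where v_ab is the axonal
    conduction velocity (distinct from the synaptic coupling, despite the
    shared symbol in some notations) and r_ab the axonal range; ``math.inf``
    marks a short-range projection whose field is treated as instantaneous
    (phi_ab = Q_b).  ``alpha``/``beta`` override the target population's
    receptor-side synaptic rates for this projection only.
    """

    source: str
    target: str
    coupling_strength: float
    delay: float
    axonal_range: float = 1e-3
    damping: float = math.inf
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self):
        for lab in (self.source, self.target):
            if lab not in POPULATION_LABELS:
                raise ValueError(f"unknown population label {lab!r}")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.axonal_range <= 0:
            raise ValueError("axonal_range must be positive")
        if self.damping <= 0:
            raise ValueError("damping must be positive")
        sign_ok = (
            self.coupling_strength <= 0
            if self.source in INHIBITORY_SOURCES
            else self.coupling_strength >= 0
        )
        if not sign_ok:
            kind = "inhibitory" if self.source in INHIBITORY_SOURCES else "excitatory"
            raise ValueError(
                f"projection {self.source}->{self.target}: sign of "
                f"coupling_strength contradicts {kind} source neurochemistry"
            )


@dataclass(frozen=True)
class ExternalInput:
    """Constant external drive (V) plus white-noise amplitude (V*s^1/2)."""

    drive: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class ModelConfig:
    populations: tuple[Population, ...]
    projections: tuple[Projection, ...]
    external: dict[str, ExternalInput] = field(default_factory=dict)
    dt: float = 1e-4
    record_rate: float = 1000.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        known = set(labels)
        for pr in self.projections:
            if pr.source not in known or pr.target not in known:
                raise ValueError(
                    f"projection {pr.source}->{pr.target} references an "
                    "absent population"
                )
        min_delay = min((pr.delay for pr in self.projections), default=math.inf)
        if self.projections and self.dt > min_delay / 4:
            raise ValueError(
                f"dt = {self.dt} too coarse for minimum delay {min_delay} "
                "(need dt <= delay/4)"
            )
        if self.record_rate > 1 / self.dt:
            raise ValueError("record_rate must not exceed 1/dt")

    def population(self, label: str) -> Population:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)


@dataclass(frozen=True)
class DoseSpec:
    """Endpoint parameter vectors and a dose for geometric interpolation."""

    P0: np.ndarray
    P1: np.ndarray
    D: float

    def __post_init__(self):
        P0 = np.asarray(self.P0, dtype=float)
        P1 = np.asarray(self.P1, dtype=float)
        if P0.shape != P1.shape:
            raise ValueError("P0 and P1 must have identical layout")
        if np.any(np.sign(P0) * np.sign(P1) < 0):
            raise ValueError("corresponding entries of P0 and P1 must share sign")
        if self.D < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class SimulationResult:
    """Recorded firing rates, dendritic potentials, and derived LFPs."""

    Q: np.ndarray                      # (n_pop, T) firing rates, s^-1
    V_afferent: np.ndarray             # (n_afferent, T) dendritic potentials, V
    afferents: list[tuple[str, str]]   # (target, source); source may be "external"
    populations: list[str]
    t: np.ndarray
    fs: float
    seed: int
    dose: float | None = None

    def lfp(self, region: str) -> np.ndarray:
        return lfp(self, region)


# ---------------------------------------------------------------------------
# Elementary responses
# ---------------------------------------------------------------------------


def firing_rate(V, pop: Population):
    """Sigmoidal population firing rate Q(V) (s^-1).

    Q = Q_max / (1 + exp(-(V - theta)/sigma')); strictly increasing in V,
    saturating at 0 and Q_max.
    """
    V = np.asarray(V, dtype=float)
    x = -(V - pop.theta) / pop.sigma_prime
    # exp overflow-safe on both tails
    out = np.where(
        x > 0,
        pop.Q_max * np.exp(-np.logaddexp(0.0, np.minimum(x, 1e9))),
        pop.Q_max / (1.0 + np.exp(np.minimum(x, 0.0))),
    )
    return out if out.ndim else float(out)


def synaptic_peak_unscaled(alpha: float, beta: float) -> float:
    """Peak eta(alpha, beta) of the unit-gain synaptic impulse response."""
    if alpha == beta:
        return alpha / math.e
    tp = math.log(beta / alpha) / (beta - alpha)
    return alpha * beta / (beta - alpha) * (math.exp(-alpha * tp) - math.exp(-beta * tp))


def synaptic_time_to_peak(alpha: float, beta: float) -> float:
    if alpha == beta:
        return 1.0 / alpha
    return math.log(beta / alpha) / (beta - alpha)


def synaptic_response(alpha: float, beta: float, t):
    """Peak-normalized synaptic impulse response h(t) (s^-1).

    h(t) = H * hbar(t) / eta(alpha, beta) with hbar the bi-exponential
    Green's function of the dendritic operator and H = 31.5 s^-1, so that
    max_t h(t) = H for every (alpha, beta): anesthetic prolongation of the
    response changes its duration and area, never its peak.  The confluent
    limit alpha == beta uses the analytic alpha^2 t e^(-alpha t) form.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if alpha == beta:
        hbar = alpha * alpha * t * np.exp(-alpha * t)
    else:
        hbar = alpha * beta / (beta - alpha) * (np.exp(-alpha * t) - np.exp(-beta * t))
    out = SYNAPTIC_PEAK * hbar / synaptic_peak_unscaled(alpha, beta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Dose interpolation
# ---------------------------------------------------------------------------


def interpolate_dose(P0, P1, D: float) -> np.ndarray:
    """Element-wise geometric interpolation P = P0 * (P1/P0)**D.

    D = 0 returns P0, D = 1 returns P1; no element ever changes sign, and
    changes saturate with increasing D.  Entries that are zero in both
    vectors stay zero; a zero P0 entry with nonzero P1 is undefined.
    """
    P0 = np.asarray(P0, dtype=float)
    P1 = np.asarray(P1, dtype=float)
    spec = DoseSpec(P0, P1, D)  # validates layout, sign, dose
    P0, P1 = spec.P0, spec.P1
    bad = (P0 == 0) & (P1 != 0)
    if np.any(bad):
        raise ValueError(
            f"P0 is zero where P1 is not (indices {np.flatnonzero(bad)[:5]}): "
            "the ratio P1/P0 is undefined"
        )
    out = np.zeros_like(np.asarray(P0, dtype=float))
    nz = P0 != 0
    out[nz] = P0[nz] * np.abs(P1[nz] / P0[nz]) ** D
    return out


def _config_vector(cfg: ModelConfig) -> np.ndarray:
    """Flatten the dose-interpolated parameters of a config."""
    vals: list[float] = []
    for p in cfg.populations:
        vals += [p.Q_max, p.theta, p.sigma_prime, p.alpha, p.beta]
    for pr in cfg.projections:
        a = pr.alpha if pr.alpha is not None else 0.0
        b = pr.beta if pr.beta is not None else 0.0
        vals += [pr.coupling_strength, pr.delay, a, b]
    for p in cfg.populations:
        ext = cfg.external.get(p.label, ExternalInput())
        vals += [ext.drive, ext.noise_sd]
    return np.array(vals, dtype=float)


def _config_from_vector(cfg: ModelConfig, vec: np.ndarray) -> ModelConfig:
    vec = list(map(float, vec))
    it = iter(vec)
    pops = tuple(
        replace(p, Q_max=next(it), theta=next(it), sigma_prime=next(it),
                alpha=next(it), beta=next(it))
        for p in cfg.populations
    )
    projs = []
    for pr in cfg.projections:
        nu, delay, a, b = next(it), next(it), next(it), next(it)
        projs.append(replace(pr, coupling_strength=nu, delay=delay,
                             alpha=a or None, beta=b or None))
    ext = {}
    for p in cfg.populations:
        d, s = next(it), next(it)
        ext[p.label] = ExternalInput(d, s)
    return replace(cfg, populations=pops, projections=tuple(projs), external=ext)


def interpolate_config(waking: ModelConfig, altered: ModelConfig,
                       D: float) -> ModelConfig:
    """Apply the geometric dose rule to every parameter of two configs.

    The two configs must share population ordering and projection lists;
    structural fields (dt, record rate, damping, axonal range) come from
    ``waking``.
    """
    lab0 = [p.label for p in waking.populations]
    lab1 = [p.label for p in altered.populations]
    e0 = [(pr.source, pr.target) for pr in waking.projections]
    e1 = [(pr.source, pr.target) for pr in altered.projections]
    if lab0 != lab1 or e0 != e1:
        raise ValueError("waking and altered configs differ in structure")
    if D == 0:
        return waking
    vec = interpolate_dose(_config_vector(waking), _config_vector(altered), D)
    return _config_from_vector(waking, vec)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def fixed_point(cfg: ModelConfig, n_iter: int = 500, relax: float = 0.5):
    """Damped fixed-point iteration for the steady soma potentials and rates.

    Returns ``(V, Q)`` dicts keyed by population label.  At the fixed point
    V_a = ext_a + sum_b G_ab * nu_ab * Q_b with G_ab = H/eta the DC gain of
    the peak-normalized synapse.
    """
    labels = [p.label for p in cfg.populations]
    idx = {lab: i for i, lab in enumerate(labels)}
    ext = np.array([cfg.external.get(lab, ExternalInput()).drive for lab in labels])
    V = ext.copy()
    for _ in range(n_iter):
        Q = np.array([firing_rate(V[i], p) for i, p in enumerate(cfg.populations)])
        V_new = ext.copy()
        for pr in cfg.projections:
            a = pr.alpha if pr.alpha is not None else cfg.population(pr.target).alpha
            b = pr.beta if pr.beta is not None else cfg.population(pr.target).beta
            gain = SYNAPTIC_PEAK / synaptic_peak_unscaled(a, b)
            V_new[idx[pr.target]] += gain * pr.coupling_strength * Q[idx[pr.source]]
        V = (1 - relax) * V + relax * V_new
    Q = np.array([firing_rate(V[i], p) for i, p in enumerate(cfg.populations)])
    return (dict(zip(labels, V)), dict(zip(labels, Q)))


# ---------------------------------------------------------------------------
# Integration kernel (RK4, ring-buffered delays)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rk4_kernel(n_steps, dt,
                # population params
                qmax, theta, sig,
                # synaptic afferents (projections then one external per pop)
                aff_tgt, aff_alpha, aff_beta,
                # projections
                prj_src, prj_drive, prj_delay, prj_wave, prj_gamma, prj_widx,
                # external input
                ext_drive, ext_noise, noise, noise_cols,
                # perturbation
                perturb_step, perturb_vec,
                # recording
                decim, Q_rec, V_rec):
    n_pop = qmax.shape[0]
    n_aff = aff_tgt.shape[0]
    n_prj = prj_src.shape[0]
    n_wave = prj_widx.max() + 1 if n_prj > 0 else 0

    V = np.zeros(n_aff)
    dV = np.zeros(n_aff)
    phi = np.zeros(n_wave)
    dphi = np.zeros(n_wave)

    Qh = np.zeros((n_steps + 1, n_pop))
    phih = np.zeros((n_steps + 1, n_wave))

    # initialize afferent potentials at the open-loop drive values
    for j in range(n_aff):
        if j >= n_prj:  # external afferent
            V[j] = ext_drive[j - n_prj]
    Vpop = np.zeros(n_pop)
    Q = np.zeros(n_pop)
    for a in range(n_pop):
        Vpop[a] = 0.0
    for j in range(n_aff):
        Vpop[aff_tgt[j]] += V[j]
    for a in range(n_pop):
        x = -(Vpop[a] - theta[a]) / sig[a]
        if x > 700.0:
            Q[a] = 0.0
        else:
            Q[a] = qmax[a] / (1.0 + math.exp(x))
    for p in range(n_prj):
        if prj_wave[p] == 1:
            phi[prj_widx[p]] = Q[prj_src[p]]
    Qh[0] = Q
    if n_wave > 0:
        phih[0] = phi

    sqdt = math.sqrt(dt)

    kV = np.zeros((4, n_aff))
    kdV = np.zeros((4, n_aff))
    kph = np.zeros((4, n_wave))
    kdph = np.zeros((4, n_wave))
    stage_c = np.array([0.0, 0.5, 0.5, 1.0])

    rec_i = 1
    for n in range(n_steps):
        for s in range(4):
            c = stage_c[s]
            if s == 0:
                Vs = V; dVs = dV; phs = phi; dphs = dphi
            elif s == 3:
                Vs = V + dt * kV[2]
                dVs = dV + dt * kdV[2]
                phs = phi + dt * kph[2]
                dphs = dphi + dt * kdph[2]
            else:
                Vs = V + 0.5 * dt * kV[s - 1]
                dVs = dV + 0.5 * dt * kdV[s - 1]
                phs = phi + 0.5 * dt * kph[s - 1]
                dphs = dphi + 0.5 * dt * kdph[s - 1]

            # soma potentials and rates at this stage
            for a in range(n_pop):
                Vpop[a] = 0.0
            for j in range(n_aff):
                Vpop[aff_tgt[j]] += Vs[j]
            for a in range(n_pop):
                x = -(Vpop[a] - theta[a]) / sig[a]
                if x > 700.0:
                    Q[a] = 0.0
                else:
                    Q[a] = qmax[a] / (1.0 + math.exp(x))

            # derivatives
            for j in range(n_aff):
                al = aff_alpha[j]
                be = aff_beta[j]
                if j < n_prj:
                    d = prj_delay[j]
                    # delayed drive at time (n + c - d) * dt, linear interp;
                    # before t=0 the history is the constant initial state
                    i0 = n - d
                    f = c
                    if i0 < 0:
                        i0 = 0
                        f = 0.0
                    if prj_wave[j] == 1:
                        w = prj_widx[j]
                        u = (1.0 - f) * phih[i0, w] + f * phih[i0 + 1, w]
                    else:
                        src = prj_src[j]
                        u = (1.0 - f) * Qh[i0, src] + f * Qh[i0 + 1, src]
                    u *= prj_drive[j]
                else:
                    a_ = j - n_prj
                    u = ext_drive[a_]
                    col = noise_cols[a_]
                    if col >= 0:
                        u += ext_noise[a_] * noise[n, col] / sqdt
                kV[s, j] = dVs[j]
                kdV[s, j] = al * be * (u - Vs[j]) - (al + be) * dVs[j]

            for p in range(n_prj):
                if prj_wave[p] == 1:
                    w = prj_widx[p]
                    g = prj_gamma[p]
                    kph[s, w] = dphs[w]
                    kdph[s, w] = g * g * (Q[prj_src[p]] - phs[w]) - 2.0 * g * dphs[w]

        V += dt / 6.0 * (kV[0] + 2 * kV[1] + 2 * kV[2] + kV[3])
        dV += dt / 6.0 * (kdV[0] + 2 * kdV[1] + 2 * kdV[2] + kdV[3])
        if n_wave > 0:
            phi += dt / 6.0 * (kph[0] + 2 * kph[1] + 2 * kph[2] + kph[3])
            dphi += dt / 6.0 * (kdph[0] + 2 * kdph[1] + 2 * kdph[2] + kdph[3])

        if n + 1 == perturb_step:
            for j in range(n_aff):
                V[j] += perturb_vec[j]

        # record histories at t_{n+1}
        for a in range(n_pop):
            Vpop[a] = 0.0
        for j in range(n_aff):
            Vpop[aff_tgt[j]] += V[j]
        ok = True
        for a in range(n_pop):
            v = Vpop[a]
            if not math.isfinite(v):
                return n + 1, a
            x = -(v - theta[a]) / sig[a]
            if x > 700.0:
                Qh[n + 1, a] = 0.0
            else:
                Qh[n + 1, a] = qmax[a] / (1.0 + math.exp(x))
        if n_wave > 0:
            phih[n + 1] = phi

        if (n + 1) % decim == 0 and rec_i < Q_rec.shape[0]:
            for a in range(n_pop):
                Q_rec[rec_i, a] = Qh[n + 1, a]
            for j in range(n_aff):
                V_rec[rec_i, j] = V[j]
        if (n + 1) % decim == 0:
            rec_i += 1

    return -1, -1


def _kernel_inputs(cfg: ModelConfig):
    labels = [p.label for p in cfg.populations]
    idx = {lab: i for i, lab in enumerate(labels)}
    n_pop = len(labels)
    n_prj = len(cfg.projections)

    qmax = np.array([p.Q_max for p in cfg.populations])
    theta = np.array([p.theta for p in cfg.populations])
    sig = np.array([p.sigma_prime for p in cfg.populations])

    aff_tgt = np.empty(n_prj + n_pop, dtype=np.int64)
    aff_alpha = np.empty(n_prj + n_pop)
    aff_beta = np.empty(n_prj + n_pop)
    prj_src = np.empty(n_prj, dtype=np.int64)
    prj_drive = np.empty(n_prj)
    prj_delay = np.empty(n_prj, dtype=np.int64)
    prj_wave = np.zeros(n_prj, dtype=np.int64)
    prj_gamma = np.zeros(n_prj)
    prj_widx = np.full(n_prj, -1, dtype=np.int64)

    w = 0
    for j, pr in enumerate(cfg.projections):
        tgt = cfg.population(pr.target)
        a = pr.alpha if pr.alpha is not None else tgt.alpha
        b = pr.beta if pr.beta is not None else tgt.beta
        gain = SYNAPTIC_PEAK / synaptic_peak_unscaled(a, b)
        aff_tgt[j] = idx[pr.target]
        aff_alpha[j] = a
        aff_beta[j] = b
        prj_src[j] = idx[pr.source]
        prj_drive[j] = gain * pr.coupling_strength
        d = int(round(pr.delay / cfg.dt))
        if d < 1:
            raise ValueError(
                f"projection {pr.source}->{pr.target}: delay must be >= dt"
            )
        prj_delay[j] = d
        if math.isfinite(pr.damping):
            prj_wave[j] = 1
            prj_gamma[j] = pr.damping
            prj_widx[j] = w
            w += 1
    for i, p in enumerate(cfg.populations):
        aff_tgt[n_prj + i] = i
        aff_alpha[n_prj + i] = p.alpha
        aff_beta[n_prj + i] = p.beta

    ext_drive = np.array(
        [cfg.external.get(lab, ExternalInput()).drive for lab in labels]
    )
    ext_noise = np.array(
        [cfg.external.get(lab, ExternalInput()).noise_sd for lab in labels]
    )
    return (labels, qmax, theta, sig, aff_tgt, aff_alpha, aff_beta,
            prj_src, prj_drive, prj_delay, prj_wave, prj_gamma, prj_widx,
            ext_drive, ext_noise)


def integrate(cfg: ModelConfig, dose: DoseSpec | None = None, *,
              seed: int | None = None,
              perturbation: np.ndarray | None = None,
              perturb_time: float | None = None) -> SimulationResult:
    """Integrate the model with a fixed-step RK4 scheme and delay buffers.

    Identical seed and config give bit-identical output.  ``perturbation``
    (one value per afferent dendritic potential, external afferents last)
    is added to the state at ``perturb_time`` -- the hook used by the
    twin-run Lyapunov procedure.

    Raises
    ------
    SimulationBlowUpError
        if any population potential becomes non-finite, naming the first
        diverging population.
    """
    if dose is not None:
        vec = interpolate_dose(dose.P0, dose.P1, dose.D)
        cfg = _config_from_vector(cfg, vec)
    (labels, qmax, theta, sig, aff_tgt, aff_alpha, aff_beta,
     prj_src, prj_drive, prj_delay, prj_wave, prj_gamma, prj_widx,
     ext_drive, ext_noise) = _kernel_inputs(cfg)

    n_steps = int(round(cfg.duration / cfg.dt))
    decim = int(round(1.0 / (cfg.dt * cfg.record_rate)))
    n_rec = n_steps // decim + 1
    n_aff = len(aff_tgt)

    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    noisy = np.flatnonzero(ext_noise > 0)
    noise_cols = np.full(len(labels), -1, dtype=np.int64)
    noise_cols[noisy] = np.arange(len(noisy))
    noise = rng.standard_normal((n_steps, max(len(noisy), 1)))

    if perturbation is not None:
        if perturb_time is None:
            raise ValueError("perturb_time required with a perturbation")
        perturb_vec = np.asarray(perturbation, dtype=float)
        if perturb_vec.shape != (n_aff,):
            raise ValueError(f"perturbation must have shape ({n_aff},)")
        perturb_step = int(round(perturb_time / cfg.dt))
    else:
        perturb_vec = np.zeros(n_aff)
        perturb_step = -1

    Q_rec = np.zeros((n_rec, len(labels)))
    V_rec = np.zeros((n_rec, n_aff))

    bad_step, bad_pop = _rk4_kernel(
        n_steps, cfg.dt, qmax, theta, sig,
        aff_tgt, aff_alpha, aff_beta,
        prj_src, prj_drive, prj_delay, prj_wave, prj_gamma, prj_widx,
        ext_drive, ext_noise, noise, noise_cols,
        perturb_step, perturb_vec, decim, Q_rec, V_rec,
    )
    if bad_step >= 0:
        raise SimulationBlowUpError(labels[bad_pop], bad_step * cfg.dt)

    # fill t=0 row
    V0 = np.zeros(n_aff)
    for i, lab in enumerate(labels):
        V0[len(cfg.projections) + i] = ext_drive[i]
    V_rec[0] = V0
    Vpop0 = np.zeros(len(labels))
    for j in range(n_aff):
        Vpop0[aff_tgt[j]] += V0[j]
    Q_rec[0] = [firing_rate(Vpop0[i], p) for i, p in enumerate(cfg.populations)]

    afferents = [(pr.target, pr.source) for pr in cfg.projections]
    afferents += [(lab, "external") for lab in labels]
    t = np.arange(n_rec) * decim * cfg.dt
    return SimulationResult(
        Q=Q_rec.T.copy(), V_afferent=V_rec.T.copy(), afferents=afferents,
        populations=labels, t=t, fs=cfg.record_rate / 1.0, seed=seed,
        dose=dose.D if dose is not None else None,
    )


def lfp(sim: SimulationResult, region: str) -> np.ndarray:
    """Local field potential of a region: sum of |dendritic potentials|.

    Absolute values superpose, so opposing afferent currents do not cancel.
    """
    rows = [i for i, (tgt, _) in enumerate(sim.afferents) if tgt == region]
    if not rows:
        raise ValueError(f"region {region!r} has no simulated afferents")
    return np.abs(sim.V_afferent[rows]).sum(axis=0)


# ---------------------------------------------------------------------------
# Dose sweep
# ---------------------------------------------------------------------------


def dose_sweep(waking: ModelConfig, altered: ModelConfig, doses: Sequence[float],
               n_runs: int = 10, seeds: Sequence[int] | None = None, *,
               burn_in: float = 5.0, n_surr: int = 5,
               sensor_noise: float = 0.05,
               te_kwargs: dict | None = None,
               lle_kwargs: dict | None = None) -> "pandas.DataFrame":
    """Sweep anesthetic/seizure dose, measuring chaoticity and band-pair TE.

    For each dose D the interpolated model is run ``n_runs`` times; each run
    yields a stochastic largest Lyapunov exponent (twin-run divergence), the
    0-1 test K-statistic of the 1-13 Hz filtered cortical/relay LFPs, and the
    low->high band-pair transfer-entropy strengths in both directions between
    cortical and relay LFPs.  ``sensor_noise`` adds seeded white measurement
    noise (as a fraction of each LFP's standard deviation) before the
    transfer-entropy step, emulating the recording noise that real
    electrodes always carry; the nearest-neighbor estimator needs that
    stochastic floor on otherwise noise-poor simulated series.  Returns a
    per-dose table of medians; runs whose integration blows up are flagged
    (``n_ok`` column), not fatal.
    """
    import pandas as pd

    from . import chaos as _chaos
    from . import spectral as _spectral
    from .preprocess import resample_series

    if seeds is None:
        seeds = list(range(n_runs))
    te_kwargs = dict(te_kwargs or {})
    lle_kwargs = dict(lle_kwargs or {})
    rows = []
    for D in doses:
        cfg = interpolate_config(waking, altered, D)
        lles, ks, s_ct, s_tc = [], [], [], []
        n_ok = 0
        for s in seeds[:n_runs]:
            try:
                est, sim, _ = _chaos.stochastic_lle(cfg, seed=int(s),
                                                    return_sims=True,
                                                    **lle_kwargs)
            except SimulationBlowUpError:
                continue
            n_ok += 1
            lles.append(est.Lambda)
            # TE on the unperturbed twin's final 10 s; the 0-1 test gets the
            # whole post-burn-in stretch (slow states need the extra extrema)
            keep = sim.t >= sim.t[-1] - 10.0
            keep_k = sim.t >= burn_in
            ctx = lfp(sim, "cortex_excitatory")
            thal = lfp(sim, "relay_nuclei")
            kk = []
            for x in (ctx[keep_k], thal[keep_k]):
                try:
                    r = _chaos.k_statistic(
                        _chaos.preprocess_for_chaos(x, fs=sim.fs), seed=int(s))
                    kk.append(r.K)
                except ValueError:
                    pass
            ctx = ctx[keep]
            thal = thal[keep]
            if kk:
                ks.append(float(np.median(kk)))
            x416 = resample_series(ctx - ctx.mean(), sim.fs, 416.0)
            y416 = resample_series(thal - thal.mean(), sim.fs, 416.0)
            if sensor_noise > 0:
                nrng = np.random.default_rng(int(s) + 65537)
                x416 = x416 + sensor_noise * x416.std() \
                    * nrng.standard_normal(x416.size)
                y416 = y416 + sensor_noise * y416.std() \
                    * nrng.standard_normal(y416.size)
            bp = _spectral.BandPair(send_levels=(5, 6, 7, 8), recv_levels=(2,))
            r_ct = _spectral.soso_test(x416, y416, bp, n_surr=n_surr,
                                       seed=int(s), **te_kwargs)
            r_tc = _spectral.soso_test(y416, x416, bp, n_surr=n_surr,
                                       seed=int(s) + 1, **te_kwargs)
            s_ct.append(r_ct.strength)
            s_tc.append(r_tc.strength)
        rows.append({
            "dose": D,
            "n_ok": n_ok,
            "lle": float(np.median(lles)) if lles else np.nan,
            "K": float(np.median(ks)) if ks else np.nan,
            "strength_ct": float(np.median(s_ct)) if s_ct else np.nan,
            "strength_tc": float(np.median(s_tc)) if s_tc else np.nan,
        })
    return pd.DataFrame(rows)
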