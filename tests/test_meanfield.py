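import math
from dataclasses import replace

import numpy as np
import pytest

from thalcort.meanfield import (
    DoseSpec, ExternalInput, ModelConfig, Population, Projection,
    SimulationBlowUpError, SYNAPTIC_PEAK, firing_rate, fixed_point, integrate,
    interpolate_config, interpolate_dose, lfp, synaptic_response,
    synaptic_time_to_peak,
)
from thalcort.presets import waking_config

from conftest import single_population_config


def _pop(**kw):
    base = dict(label="cortex_excitatory", Q_max=100.0, theta=0.013,
                sigma_prime=0.005, alpha=50.0, beta=200.0)
    base.update(kw)
    return Population(**base)


class TestFiringRate:
    def test_midpoint_and_saturation(self):
        pop = _pop()
        assert firing_rate(pop.theta, pop) == pytest.approx(50.0)
        assert firing_rate(-10.0, pop) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(+10.0, pop) == pytest.approx(100.0)

    def test_ln9_point(self):
        # V = theta + sigma' ln 9 puts the sigmoid at 0.9 of its maximum
        pop = _pop()
        V = pop.theta + pop.sigma_prime * np.log(9.0)
        assert firing_rate(V, pop) == pytest.approx(90.0, rel=1e-12)

    def test_strictly_increasing(self):
        pop = _pop()
        v = np.linspace(-0.05, 0.08, 1000)
        q = firing_rate(v, pop)
        assert np.all(np.diff(q) > 0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            _pop(Q_max=-1.0)
        with pytest.raises(ValueError):
            _pop(alpha=300.0, beta=200.0)  # decay faster than rise
        with pytest.raises(ValueError):
            Population("no_such_region", 100, 0.01, 0.004, 50, 200)


class TestSynapticResponse:
    @pytest.mark.parametrize("alpha,beta", [(50, 200), (20, 80), (10, 1000),
                                            (100, 101), (60, 60)])
    def test_peak_is_H(self, alpha, beta):
        t = np.linspace(0, 1.0, 200001)
        h = synaptic_response(alpha, beta, t)
        assert np.max(h) == pytest.approx(SYNAPTIC_PEAK, abs=1e-6)

    def test_peak_invariance_over_ratio_grid(self):
        # beta/alpha from barely-distinct to two orders of magnitude
        for ratio in np.geomspace(1.01, 100.0, 25):
            alpha = 40.0
            beta = alpha * ratio
            tp = synaptic_time_to_peak(alpha, beta)
            assert synaptic_response(alpha, beta, tp) == pytest.approx(
                SYNAPTIC_PEAK, abs=1e-6)

    def test_time_to_peak_calculus_oracle(self):
        # argmax of the bi-exponential: set dh/dt = 0 -> ln(b/a)/(b-a)
        alpha, beta = 20.0, 80.0
        t = np.linspace(0, 0.5, 500001)
        h = synaptic_response(alpha, beta, t)
        t_star = t[np.argmax(h)]
        assert t_star == pytest.approx(np.log(beta / alpha) / (beta - alpha),
                                       abs=2e-6)

    def test_time_rescaling_halves_peak_time(self):
        a, b = 30.0, 90.0
        assert synaptic_time_to_peak(2 * a, 2 * b) == pytest.approx(
            synaptic_time_to_peak(a, b) / 2)
        tp = synaptic_time_to_peak(2 * a, 2 * b)
        assert synaptic_response(2 * a, 2 * b, tp) == pytest.approx(
            SYNAPTIC_PEAK, abs=1e-9)

    def test_confluent_limit_continuous(self):
        t = np.linspace(0, 0.3, 30001)
        h_eq = synaptic_response(50.0, 50.0, t)
        h_near = synaptic_response(50.0, 50.0 + 1e-6, t)
        assert np.max(np.abs(h_eq - h_near)) < 1e-3


class TestDoseInterpolation:
    def test_endpoints(self):
        P0 = np.array([1.0, -2.0, 0.5])
        P1 = np.array([4.0, -8.0, 0.1])
        assert np.allclose(interpolate_dose(P0, P1, 0.0), P0)
        assert np.allclose(interpolate_dose(P0, P1, 1.0), P1)

    def test_half_dose_is_geometric_mean(self):
        P0 = np.array([1.0, -2.0])
        P1 = np.array([4.0, -8.0])
        assert np.allclose(interpolate_dose(P0, P1, 0.5),
                           np.sign(P0) * np.sqrt(np.abs(P0 * P1)))

    def test_extrapolation_preserves_sign(self):
        assert interpolate_dose([-2.0], [-8.0], 2.0)[0] == pytest.approx(-32.0)

    def test_monotone_and_saturating(self):
        vals = [interpolate_dose([2.0], [6.0], d)[0] for d in (0, 0.5, 1, 2, 4)]
        assert np.all(np.diff(vals) > 0)

    def test_zero_handling(self):
        assert interpolate_dose([0.0], [0.0], 0.7)[0] == 0.0
        with pytest.raises(ValueError):
            interpolate_dose([0.0], [1.0], 0.5)
        with pytest.raises(ValueError):
            DoseSpec(np.array([1.0]), np.array([-1.0]), 0.5)


class TestIntegrate:
    def test_uncoupled_drive_settles_to_fixed_point(self):
        # with zero coupling the dendritic potential relaxes to the drive
        c = 0.012
        cfg = single_population_config(drive=c, duration=3.0)
        sim = integrate(cfg, seed=0)
        pop = cfg.populations[0]
        assert sim.Q[0, -1] == pytest.approx(float(firing_rate(c, pop)),
                                             rel=1e-6)
        V, Q = fixed_point(cfg)
        assert V["cortex_excitatory"] == pytest.approx(c, rel=1e-9)

    def test_delay_causality(self):
        # a perturbation of the source cannot reach the target before tau
        tau = 0.040
        pops = (
            Population("cortex_excitatory", 300, 0.014, 0.0038, 50, 200),
            Population("relay_nuclei", 300, 0.013, 0.0038, 50, 200),
        )
        proj = Projection("cortex_excitatory", "relay_nuclei",
                          coupling_strength=1e-3, delay=tau)
        cfg = ModelConfig(populations=pops, projections=(proj,),
                          external={"cortex_excitatory": ExternalInput(0.012),
                                    "relay_nuclei": ExternalInput(0.012)},
                          duration=2.0)
        t_kick = 1.0
        base = integrate(cfg, seed=0)
        kick = np.zeros(len(base.afferents))
        kick[[i for i, (t, s) in enumerate(base.afferents)
              if t == "cortex_excitatory"]] = 1e-3
        pert = integrate(cfg, seed=0, perturbation=kick, perturb_time=t_kick)
        i_rel = base.populations.index("relay_nuclei")
        diff = np.abs(base.Q[i_rel] - pert.Q[i_rel])
        before = base.t < t_kick + tau - 1e-9
        after = base.t > t_kick + tau + 0.05
        assert np.all(diff[before] == 0.0)
        assert np.any(diff[after] > 0)

    def test_seed_determinism_bit_exact(self, waking_small):
        s1 = integrate(waking_small, seed=7)
        s2 = integrate(waking_small, seed=7)
        assert np.array_equal(s1.Q, s2.Q)
        assert np.array_equal(s1.V_afferent, s2.V_afferent)

    def test_rates_bounded_by_qmax(self, waking_small):
        sim = integrate(waking_small, seed=1)
        for i, lab in enumerate(sim.populations):
            qmax = waking_small.population(lab).Q_max
            assert np.all(sim.Q[i] >= 0)
            assert np.all(sim.Q[i] <= qmax + 1e-9)

    def test_dt_convergence(self):
        # noise-free waking run: halving dt moves the mean rate < 1%
        cfg = waking_config(duration=5.0, noise_sd=0.0)
        r = []
        for dt in (1e-4, 5e-5):
            sim = integrate(replace(cfg, dt=dt), seed=0)
            r.append(sim.Q[0].mean())
        assert abs(r[1] - r[0]) / abs(r[0]) < 0.01

    def test_blowup_names_population(self):
        # a rise rate far too stiff for the step size destabilizes the
        # integrator once noise nudges it off the exact fixed point
        cfg = single_population_config(alpha=50.0, beta=2e5, drive=0.012,
                                       noise=1e-9, duration=1.0)
        with pytest.raises(SimulationBlowUpError, match="cortex_excitatory"):
            integrate(cfg, seed=0)

    def test_dose_zero_endpoint_bit_exact(self, waking_small):
        from thalcort.meanfield import _config_vector
        P0 = _config_vector(waking_small)
        ref = integrate(waking_small, seed=3)
        via_dose = integrate(waking_small, dose=DoseSpec(P0, 2 * P0, 0.0),
                             seed=3)
        # D = 0 must leave the config untouched
        assert np.array_equal(ref.Q, via_dose.Q)


class TestLFP:
    def test_single_afferent_absolute_value(self):
        cfg = single_population_config(drive=0.012, duration=2.0)
        sim = integrate(cfg, seed=0)
        region = lfp(sim, "cortex_excitatory")
        manual = np.abs(sim.V_afferent).sum(axis=0)
        assert np.allclose(region, manual)
        assert np.all(region >= 0)

    def test_no_cancellation(self):
        sim_like = integrate(single_population_config(drive=0.012,
                                                      duration=1.0), seed=0)
        sim_like.V_afferent = np.array([[0.5, -0.5], [-0.5, 0.5]])
        sim_like.afferents = [("cortex_excitatory", "a"),
                              ("cortex_excitatory", "b")]
        assert np.allclose(lfp(sim_like, "cortex_excitatory"), [1.0, 1.0])

    def test_unknown_region_errors(self, waking_small):
        sim = integrate(waking_small, seed=0)
        with pytest.raises(ValueError):
            lfp(sim, "STN_nonexistent")


class TestInterpolateConfig:
    def test_structure_mismatch_rejected(self, waking_small):
        other = replace(waking_small,
                        projections=waking_small.projections[:-1])
        with pytest.raises(ValueError):
            interpolate_config(waking_small, other, 0.5)

    def test_midpoint_couplings_are_geometric(self, waking_small):
        altered = replace(waking_small, projections=tuple(
            replace(p, coupling_strength=p.coupling_strength * 4)
            for p in waking_small.projections))
        mid = interpolate_config(waking_small, altered, 0.5)
        for p0, pm in zip(waking_small.projections, mid.projections):
            assert pm.coupling_strength == pytest.approx(
                2 * p0.coupling_strength, rel=1e-12)


class TestProjectionInvariants:
    def test_inhibitory_source_sign_enforced(self):
        with pytest.raises(ValueError, match="neurochemistry"):
            Projection("GPe", "STN", coupling_strength=+1e-3, delay=0.002)
        with pytest.raises(ValueError, match="neurochemistry"):
            Projection("STN", "GPe", coupling_strength=-1e-3, delay=0.002)

    def test_dt_delay_guard(self):
        pop = Population("cortex_excitatory", 300, 0.014, 0.0038, 50, 200)
        proj = Projection("cortex_excitatory", "cortex_excitatory",
                          coupling_strength=0.0, delay=2e-4)
        with pytest.raises(ValueError, match="dt"):
            ModelConfig(populations=(pop,), projections=(proj,), dt=1e-4)
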