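"""Biomechanics analysis: stress conversion, cycle segmentation, slope and
tangent-modulus estimation against closed-form oracles, anisotropy index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pelvimech as pm
from pelvimech.biomech import (
    Cycle,
    SpecimenMechanics,
    anisotropy_index,
    compute_stress_strain,
    mean_slope,
    segment_cycles,
    select_steady_cycles,
    tangent_modulus,
)
from pelvimech.synthetic import MechTrace, _ls_window_slope
from conftest import make_linear_trace


def _truncate(trace, t_max):
    keep = trace.time <= t_max
    return MechTrace(
        time=trace.time[keep],
        strain_x=trace.strain_x[keep],
        strain_y=trace.strain_y[keep],
        force_x=trace.force_x[keep],
        force_y=trace.force_y[keep],
        geometry=trace.geometry,
        protocol=trace.protocol,
        specimen_id=trace.specimen_id,
    )


class TestStressStrain:
    def test_nominal_stress_units(self, protocol, noise_free_trace):
        """0.1 N over 1 mm x 10 mm is 0.01 MPa."""
        geom = pm.SpecimenGeometry(thickness=1.0, width_x=10.0, width_y=10.0)
        n = 5
        trace = MechTrace(
            time=np.arange(n) / 30.0,
            strain_x=np.linspace(0, 4.0, n),
            strain_y=np.linspace(0, 4.0, n),
            force_x=np.full(n, 0.1),
            force_y=np.zeros(n),
            geometry=geom,
            protocol=protocol,
        )
        sx, sy = compute_stress_strain(trace)
        assert np.allclose(sx.stress, 0.01)
        assert np.allclose(sy.stress, 0.0)
        assert np.allclose(sx.strain, np.linspace(0, 0.04, n))

    def test_roundtrip_recovers_material_law(self, protocol, geometry):
        """Noise-free, precondition-free simulation followed by stress
        conversion reproduces sigma = A(e^{B eps}-1) pointwise on loading."""
        p = pm.TissueMechParams(noise_sd=0.0, precond_drop=0.0)
        trace = pm.simulate_specimen_mech(p, protocol, geometry, seed=2)
        sx, _ = compute_stress_strain(trace)
        for c in select_steady_cycles(segment_cycles(sx, protocol), 3):
            # interior samples only: the shared boundary samples at the
            # trough/peak can belong to the adjacent (eta-scaled) limb
            expected = p.A_x * np.expm1(p.B_x * c.loading_strain[1:-1])
            assert np.allclose(c.loading_stress[1:-1], expected, rtol=1e-9, atol=1e-12)


class TestSegmentation:
    def test_clean_input_gives_ten_cycles_per_level(self, noise_free_trace, protocol):
        sx, _ = compute_stress_strain(noise_free_trace)
        cycles = segment_cycles(sx, protocol)
        for lv in protocol.strain_levels:
            assert sum(c.level == lv for c in cycles) == protocol.cycles_per_level

    def test_truncated_trace_errors_naming_level(self, noise_free_trace, protocol):
        # cut inside the second cycle of the 21.6% level
        rate = protocol.strain_rate / 60.0
        t_start_last = sum(2 * lv / rate * 10 for lv in (4.6, 10.0, 15.7))
        trace = _truncate(noise_free_trace, t_start_last + 1.5 * 2 * 21.6 / rate)
        sx, _ = compute_stress_strain(trace)
        with pytest.raises(ValueError, match="21.6"):
            segment_cycles(sx, protocol)

    def test_noisy_strain_still_segments(self, noise_free_trace, protocol, rng):
        sx, _ = compute_stress_strain(noise_free_trace)
        noisy = pm.StressStrainSeries(
            axis="x",
            strain=sx.strain + rng.normal(0, 0.002, len(sx.strain)),  # 0.2% strain jitter
            stress=sx.stress,
            time=sx.time,
        )
        cycles = segment_cycles(noisy, protocol)
        for lv in protocol.strain_levels:
            assert sum(c.level == lv for c in cycles) == protocol.cycles_per_level


class TestSteadyCycleSelection:
    def test_last_three_of_ten(self, noise_free_trace, protocol):
        sx, _ = compute_stress_strain(noise_free_trace)
        steady = select_steady_cycles(segment_cycles(sx, protocol), 3)
        for lv in protocol.strain_levels:
            assert sorted(c.index for c in steady if c.level == lv) == [8, 9, 10]

    def test_k_equal_to_available_is_identity(self):
        cycles = [
            Cycle(10.0, i, np.array([0.0, 0.1]), np.array([0.0, 1.0]),
                  np.array([0.1, 0.0]), np.array([1.0, 0.0]))
            for i in range(1, 11)
        ]
        assert select_steady_cycles(cycles, 10) == sorted(cycles, key=lambda c: c.index)

    def test_too_few_cycles_errors(self):
        cycles = [
            Cycle(10.0, i, np.array([0.0, 0.1]), np.array([0.0, 1.0]),
                  np.array([0.1, 0.0]), np.array([1.0, 0.0]))
            for i in (1, 2)
        ]
        with pytest.raises(ValueError, match="need 3"):
            select_steady_cycles(cycles, 3)


class TestMeanSlope:
    def test_linear_material_recovers_k_exactly(self):
        """sigma = k*eps with eta=1: mean slope equals k to 1e-9 relative."""
        k = 0.25
        params, trace = make_linear_trace(k=k, eta=1.0)
        sx, _ = compute_stress_strain(trace)
        for c in select_steady_cycles(segment_cycles(sx, trace.protocol), 3):
            assert mean_slope(c) == pytest.approx(k, rel=1e-6)

    def test_average_of_loading_and_unloading(self):
        """Loading slope k with unloading slope 0.8k averages to 0.9k."""
        k = 1.0
        eps = np.linspace(0.0, 0.1, 50)
        c = Cycle(10.0, 1, eps, k * eps, eps[::-1], 0.8 * k * eps[::-1])
        assert mean_slope(c) == pytest.approx(0.9 * k, rel=1e-12)

    def test_matches_normal_equations_oracle(self, noise_free_trace, protocol):
        """Per-limb fits agree with an explicit normal-equations solve."""
        sx, _ = compute_stress_strain(noise_free_trace)
        c = select_steady_cycles(segment_cycles(sx, protocol), 3)[-1]

        def ne_slope(x, y):
            xm, ym = x.mean(), y.mean()
            return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())

        expected = 0.5 * (
            ne_slope(c.loading_strain, c.loading_stress)
            + ne_slope(c.unloading_strain, c.unloading_stress)
        )
        assert mean_slope(c) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_segment_errors(self):
        c = Cycle(10.0, 1, np.full(5, 0.1), np.linspace(0, 1, 5),
                  np.full(5, 0.1), np.linspace(1, 0, 5))
        with pytest.raises(ValueError, match="degenerate|constant"):
            mean_slope(c)


class TestTangentModulus:
    def test_linear_material_gives_k_at_every_level(self):
        k = 0.4
        params, trace = make_linear_trace(k=k)
        sp = pm.analyze_specimen(trace)
        for ax in ("x", "y"):
            for lv in trace.protocol.strain_levels:
                assert sp.tangent_modulus[ax][lv] == pytest.approx(k, rel=1e-6)

    def test_exponential_material_matches_window_oracle(self, noise_free_params,
                                                        protocol, geometry):
        """Noise-free 30 Hz estimates match the closed-form window slope to
        well under 2% at every level, both axes."""
        p = pm.TissueMechParams(A_x=0.01, A_y=0.04, B_x=20.0, B_y=10.0,
                                noise_sd=0.0, precond_drop=0.0)
        trace = pm.simulate_specimen_mech(p, protocol, geometry, seed=7)
        sp = pm.analyze_specimen(trace)
        for ax in ("x", "y"):
            for lv in protocol.strain_levels:
                oracle = _ls_window_slope(p.A(ax), p.B(ax), lv / 100.0, 0.01)
                assert sp.tangent_modulus[ax][lv] == pytest.approx(oracle, rel=0.02)

    def test_window_larger_than_segment_errors(self):
        eps = np.linspace(0.0, 0.005, 10)
        c = Cycle(4.6, 1, eps, eps, eps[::-1], eps[::-1])
        with pytest.raises(ValueError, match="window"):
            tangent_modulus([c], window_pct=1.0)

    def test_too_few_samples_in_window_errors(self):
        eps = np.array([0.0, 0.05, 0.1])
        c = Cycle(10.0, 1, eps, eps, eps[::-1], eps[::-1])
        with pytest.raises(ValueError, match="sample rate"):
            tangent_modulus([c], window_pct=1.0)

    def test_estimates_increase_across_levels(self, noise_free_trace):
        sp = pm.analyze_specimen(noise_free_trace)
        for ax in ("x", "y"):
            vals = [sp.tangent_modulus[ax][lv] for lv in noise_free_trace.protocol.strain_levels]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_pooled_scope_close_to_per_cycle(self, noise_free_trace):
        a = pm.analyze_specimen(noise_free_trace, scope="per_cycle")
        b = pm.analyze_specimen(noise_free_trace, scope="pooled")
        for ax in ("x", "y"):
            for lv in noise_free_trace.protocol.strain_levels:
                assert b.tangent_modulus[ax][lv] == pytest.approx(
                    a.tangent_modulus[ax][lv], rel=0.02
                )


class TestAnisotropyIndex:
    def test_definition(self):
        sp = SpecimenMechanics("s", tangent_modulus={"x": {10.0: 2.0}, "y": {10.0: 1.0}})
        assert anisotropy_index(sp) == {10.0: 2.0}

    def test_isotropic_specimen_is_one(self, noise_free_trace):
        sp = pm.analyze_specimen(noise_free_trace)
        for lv, ai in sp.anisotropy_index.items():
            assert ai == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_transverse_rejected(self):
        sp = SpecimenMechanics("s", tangent_modulus={"x": {10.0: 2.0}, "y": {10.0: 0.0}})
        with pytest.raises(ValueError, match="<= 0"):
            anisotropy_index(sp)

    def test_anisotropic_specimen_recovers_factor_ratio(self, protocol, geometry):
        """RGTA-like specimen (longitudinal/transverse stress scale 1/0.7)
        yields AI within 5% of the true modulus ratio at every level."""
        p = pm.TissueMechParams(A_x=0.04, A_y=0.028, noise_sd=0.0)
        trace = pm.simulate_specimen_mech(p, protocol, geometry, seed=13)
        sp = pm.analyze_specimen(trace)
        for lv in protocol.strain_levels:
            truth = pm.true_tangent_modulus(p, "x", lv) / pm.true_tangent_modulus(p, "y", lv)
            assert sp.anisotropy_index[lv] == pytest.approx(truth, rel=0.05)

    def test_ai_invariant_to_common_force_rescaling(self, noise_free_trace):
        scaled = MechTrace(
            time=noise_free_trace.time,
            strain_x=noise_free_trace.strain_x,
            strain_y=noise_free_trace.strain_y,
            force_x=3.7 * noise_free_trace.force_x,
            force_y=3.7 * noise_free_trace.force_y,
            geometry=noise_free_trace.geometry,
            protocol=noise_free_trace.protocol,
        )
        a = pm.analyze_specimen(noise_free_trace)
        b = pm.analyze_specimen(scaled)
        for lv in noise_free_trace.protocol.strain_levels:
            assert b.anisotropy_index[lv] == pytest.approx(a.anisotropy_index[lv], rel=1e-9)


class TestAnalyzeSpecimen:
    def test_rerun_is_deterministic(self, noise_free_trace):
        a = pm.analyze_specimen(noise_free_trace)
        b = pm.analyze_specimen(noise_free_trace)
        assert a.tangent_modulus == b.tangent_modulus
        assert a.mean_slope == b.mean_slope

    def test_error_carries_specimen_context(self, noise_free_trace, protocol):
        rate = protocol.strain_rate / 60.0
        bad = _truncate(noise_free_trace, 1.5 * 2 * 4.6 / rate)
        with pytest.raises(ValueError, match="specimen"):
            pm.analyze_specimen(bad)
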