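import numpy as np
import pytest
from scipy import stats

from hemodose import (
    CirculationParams,
    CompartmentModel,
    PatientModel,
    build_schedule,
    compartment_dose_rate_sample,
    compute_metrics,
    score_course,
)

from conftest import make_uniform_model


class TestBuildSchedule:
    def test_single_field_beam_on_time(self):
        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        assert sched.fraction_dose_gy == pytest.approx(2.0)
        assert sched.beam_on_per_field_s == pytest.approx(40.0)  # 2 Gy at 3 Gy/min
        assert sched.fraction_duration_s == pytest.approx(40.0)

    def test_two_fields_with_gap(self):
        sched = build_schedule(
            {"n_fractions": 30, "prescription_gy": 60.0, "fields_per_fraction": 2}
        )
        assert sched.beam_on_per_field_s == pytest.approx(20.0)
        assert sched.fraction_duration_s == pytest.approx(50.0)  # 20 + 10 + 20
        starts, ends = sched.beam_windows()
        np.testing.assert_allclose(starts, [0.0, 30.0])
        np.testing.assert_allclose(ends, [20.0, 50.0])

    def test_beam_on_inversely_proportional_to_dose_rate(self):
        slow = build_schedule({"n_fractions": 30, "prescription_gy": 60.0}, dose_rate_gy_min=3.0)
        fast = build_schedule({"n_fractions": 30, "prescription_gy": 60.0}, dose_rate_gy_min=6.0)
        assert slow.beam_on_per_field_s == pytest.approx(2 * fast.beam_on_per_field_s)

    def test_invalid_prescription_rejected(self):
        with pytest.raises(ValueError):
            build_schedule({"n_fractions": 30, "prescription_gy": 0.0})
        with pytest.raises(ValueError):
            build_schedule({"n_fractions": 0, "prescription_gy": 60.0})


class TestDoseRateSample:
    def test_uniform_compartment_constant_rate(self):
        comp = CompartmentModel(name="c", f_volume=0.5, f_flow=0.5, voxel_doses=[2.0])
        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        # 2 Gy compartment over 30 x 40 s of beam-on: per-fraction share 2/30 Gy
        # delivered in 40 s is 1/600 Gy/s
        rates = compartment_dose_rate_sample(comp, sched, np.random.default_rng(0), size=100)
        np.testing.assert_allclose(rates, 2.0 / (30 * 40.0))

    def test_partial_coverage_zeroes_expected_share(self):
        comp = CompartmentModel(
            name="c", f_volume=0.5, f_flow=0.5, coverage=0.5, voxel_doses=[2.0]
        )
        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        rates = compartment_dose_rate_sample(comp, sched, np.random.default_rng(1), size=10_000)
        n_zero = int((rates == 0.0).sum())
        assert stats.binomtest(n_zero, 10_000, 0.5).pvalue > 1e-4

    def test_cold_compartment_always_zero(self):
        comp = CompartmentModel(name="c", f_volume=0.5, f_flow=0.5, voxel_doses=[0.0, 0.0])
        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        rates = compartment_dose_rate_sample(comp, sched, np.random.default_rng(2), size=50)
        assert np.all(rates == 0.0)


class TestScoreCourse:
    def test_uniform_bath_every_particle_gets_prescription(self, male_physiology):
        rx = 60.0
        model = make_uniform_model(male_physiology, rx)
        sched = build_schedule({"n_fractions": 30, "prescription_gy": rx})
        dist = score_course(model, CirculationParams(n_particles=2000, rng_seed=1), sched)
        np.testing.assert_allclose(dist.doses, rx, rtol=1e-12)

    def test_single_fraction_base_case(self, male_physiology):
        rx = 2.0
        model = make_uniform_model(male_physiology, rx)
        sched = build_schedule({"n_fractions": 1, "prescription_gy": rx})
        dist = score_course(model, CirculationParams(n_particles=500, rng_seed=5), sched)
        np.testing.assert_allclose(dist.doses, rx, rtol=1e-12)

    def test_mean_conservation(self, male_physiology):
        """E[D_mean] = sum_c f_volume_c * coverage_c * mean(voxel_doses_c)."""
        compartments = (
            CompartmentModel(
                name="hot", f_volume=0.2, f_flow=0.3, coverage=0.8,
                voxel_doses=np.linspace(20.0, 60.0, 50),
            ),
            CompartmentModel(
                name="warm", f_volume=0.3, f_flow=0.4, voxel_doses=np.linspace(0.0, 10.0, 30),
            ),
            CompartmentModel(name="cold", f_volume=0.5, f_flow=0.3, voxel_doses=[0.0]),
        )
        model = PatientModel(physiology=male_physiology, compartments=compartments)
        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        dist = score_course(model, CirculationParams(n_particles=10_000, rng_seed=9), sched)
        expected = sum(c.f_volume * c.coverage * c.mean_voxel_dose for c in compartments)
        se = dist.doses.std(ddof=1) / np.sqrt(dist.n_particles)
        assert dist.doses.mean() == pytest.approx(expected, abs=3 * se)

    def test_coverage_linearity(self, male_physiology):
        """Halving a sole irradiated compartment's coverage halves D_mean."""
        def build(coverage):
            compartments = (
                CompartmentModel(
                    name="hot", f_volume=0.2, f_flow=0.3, coverage=coverage,
                    voxel_doses=[40.0],
                ),
                CompartmentModel(name="cold", f_volume=0.8, f_flow=0.7, voxel_doses=[0.0]),
            )
            return PatientModel(physiology=male_physiology, compartments=compartments)

        sched = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
        params = CirculationParams(n_particles=10_000, rng_seed=21)
        full = score_course(build(1.0), params, sched)
        half = score_course(build(0.5), params, sched)
        ratio = half.doses.mean() / full.doses.mean()
        rel_se = 3 * np.sqrt(
            (full.doses.std() / full.doses.mean()) ** 2
            + (half.doses.std() / half.doses.mean()) ** 2
        ) / np.sqrt(full.n_particles)
        assert ratio == pytest.approx(0.5, rel=3 * rel_se + 0.02)

    def test_fractionation_narrows_the_distribution(self, male_physiology):
        """At fixed total dose, D_10% - D_90% shrinks as fractions increase."""
        compartments = (
            CompartmentModel(
                name="hot", f_volume=0.2, f_flow=0.3, voxel_doses=np.linspace(10.0, 70.0, 40),
            ),
            CompartmentModel(name="cold", f_volume=0.8, f_flow=0.7, voxel_doses=[0.0]),
        )
        model = PatientModel(physiology=male_physiology, compartments=compartments)
        spreads = []
        for n_fractions in (1, 5, 30):
            sched = build_schedule({"n_fractions": n_fractions, "prescription_gy": 60.0})
            dist = score_course(model, CirculationParams(n_particles=4000, rng_seed=2), sched)
            m = compute_metrics(dist, x_levels=(10.0, 90.0))
            spreads.append(m.d_x[10.0] - m.d_x[90.0])
        assert spreads[0] > spreads[1] > spreads[2]

    def test_seed_only_changes_labels_not_distribution(self, male_physiology):
        """Different seeds give distributionally equal dose vectors."""
        compartments = (
            CompartmentModel(
                name="hot", f_volume=0.3, f_flow=0.4, voxel_doses=np.linspace(0.0, 40.0, 20),
            ),
            CompartmentModel(name="cold", f_volume=0.7, f_flow=0.6, voxel_doses=[0.0]),
        )
        model = PatientModel(physiology=male_physiology, compartments=compartments)
        sched = build_schedule({"n_fractions": 10, "prescription_gy": 20.0})
        a = score_course(model, CirculationParams(n_particles=4000, rng_seed=1), sched)
        b = score_course(model, CirculationParams(n_particles=4000, rng_seed=2), sched)
        assert stats.ks_2samp(a.doses, b.doses).pvalue > 0.01

    def test_determinism_under_fixed_seed(self, male_physiology):
        model = make_uniform_model(male_physiology, 30.0, f_volumes=(0.4, 0.6))
        sched = build_schedule({"n_fractions": 5, "prescription_gy": 30.0})
        params = CirculationParams(n_particles=300, rng_seed=8)
        a = score_course(model, params, sched)
        b = score_course(model, params, sched)
        np.testing.assert_array_equal(a.doses, b.doses)
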