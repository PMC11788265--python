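import numpy as np
import pytest

from ctdr.robust_eval import (
    RobustnessReport,
    d50_statistic,
    evaluate_robustness,
    oar_delta,
    scenario_doses,
    v_d,
    voxelwise_min,
)
from ctdr.robust_plan import make_scenarios
from ctdr.volumes import Volume


def dose_vol(data, spacing=(2.0, 2.0, 2.0)):
    return Volume(np.asarray(data, float), spacing, quantity="dose")


class TestVoxelwiseMin:
    def test_single_dose_is_itself(self):
        d = dose_vol(np.random.default_rng(0).random((6, 6, 6)))
        np.testing.assert_array_equal(voxelwise_min([d]).data, d.data)

    def test_min_leq_mean_and_idempotent(self):
        rng = np.random.default_rng(1)
        doses = [dose_vol(rng.random((6, 6, 6))) for _ in range(4)]
        vmin = voxelwise_min(doses)
        mean = np.mean([d.data for d in doses], axis=0)
        assert np.all(vmin.data <= mean + 1e-12)
        np.testing.assert_array_equal(voxelwise_min([vmin, vmin]).data, vmin.data)

    def test_lower_bounds_every_scenario(self):
        rng = np.random.default_rng(2)
        doses = [dose_vol(rng.random((6, 6, 6))) for _ in range(5)]
        vmin = voxelwise_min(doses)
        for d in doses:
            assert np.all(vmin.data <= d.data + 1e-12)

    def test_geometry_mismatch_rejected(self):
        a = dose_vol(np.zeros((4, 4, 4)))
        b = dose_vol(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="congruent"):
            voxelwise_min([a, b])


class TestVD:
    def test_vd_at_zero_is_100(self):
        d = dose_vol(np.random.default_rng(3).random((5, 5, 5)))
        mask = np.ones((5, 5, 5), bool)
        assert v_d(d, mask, 0.0) == 100.0

    def test_vd_counts_fraction(self):
        data = np.zeros((4, 4, 4))
        data[:2] = 10.0
        assert v_d(dose_vol(data), np.ones((4, 4, 4), bool), 5.0) == 50.0


class TestD50:
    def test_uniform_dose_recovers_level(self):
        doses = [dose_vol(np.full((5, 5, 5), 48.0)) for _ in range(4)]
        ctv = np.ones((5, 5, 5), bool)
        d50 = d50_statistic(doses, ctv, prescription=54.0)
        assert abs(d50 - 48.0) <= 0.1 * 54.0 / 100 + 1e-6

    def test_bisection_matches_exhaustive_scan(self):
        """Bisection equals a 0.01 Gy exhaustive scan for the largest passing D."""
        rng = np.random.default_rng(4)
        ctv = np.ones((8, 8, 8), bool)
        doses = [dose_vol(50.0 + rng.normal(0, 1.5, size=(8, 8, 8))) for _ in range(6)]
        d50 = d50_statistic(doses, ctv, prescription=54.0)

        stack = np.stack([d.data[ctv] for d in doses])
        need = int(np.ceil(len(doses) / 2))
        grid = np.arange(0.0, 60.0, 0.01)
        passing = [
            D for D in grid
            if np.sum(100.0 * np.mean(stack >= D, axis=1) > 98.0) >= need
        ]
        assert abs(d50 - max(passing)) < 0.1 * 54.0 / 100 + 0.01

    def test_needs_two_scenarios(self):
        with pytest.raises(ValueError, match="two"):
            d50_statistic([dose_vol(np.ones((3, 3, 3)))], np.ones((3, 3, 3), bool), 54.0)

    def test_all_zero_rejected(self):
        doses = [dose_vol(np.zeros((3, 3, 3)))] * 2
        with pytest.raises(ValueError, match="zero"):
            d50_statistic(doses, np.ones((3, 3, 3), bool), 54.0)


class TestOarDelta:
    def _report(self, vals):
        return RobustnessReport(
            scenario_v95=np.array([100.0]),
            worst_case_v95=100.0,
            worst_scenario_index=0,
            voxelwise_min_v95=100.0,
            d50=50.0,
            oar_metrics={"oar": {"Davg": np.asarray(vals)}},
            prescription=50.0,
        )

    def test_identical_inputs_zero(self):
        r = self._report([10.0, 12.0])
        assert oar_delta(r, r, "oar") == 0.0

    def test_two_percent_offset(self):
        a = self._report([10.0, 20.0])
        b = self._report([10.0, 21.0])  # +1 Gy on 50 Gy prescription = 2%
        assert oar_delta(a, b, "oar") == pytest.approx(2.0)

    def test_symmetric(self):
        a = self._report([10.0, 20.0])
        b = self._report([11.0, 19.0])
        assert oar_delta(a, b, "oar") == oar_delta(b, a, "oar")

    def test_missing_oar_rejected(self):
        r = self._report([1.0])
        with pytest.raises(KeyError):
            oar_delta(r, r, "nope")


class TestScenarioDoses:
    def test_count_and_nominal_consistency(self, brain_case):
        from ctdr.dose_engine import compute_dose

        scen = make_scenarios(3.0, 0.035)
        doses = scenario_doses(brain_case.plan, brain_case.ct, scen, rois=brain_case.rois)
        assert len(doses) == 13
        nominal = doses[scen.nominal_index]
        np.testing.assert_allclose(nominal.data, brain_case.reference_dose.data, atol=1e-9)

    def test_mirror_symmetry_of_opposite_shifts(self, brain_case):
        """+x and -x shifted doses agree after mirroring on the (nearly)
        symmetric brain phantom."""
        from ctdr.robust_plan import Scenario, ScenarioSet

        scen = ScenarioSet([Scenario(), Scenario((4.0, 0.0, 0.0)), Scenario((-4.0, 0.0, 0.0))])
        doses = scenario_doses(brain_case.plan, brain_case.ct, scen, rois=brain_case.rois)
        ctv = brain_case.rois["CTV"]
        # mean CTV dose of the two opposite shifts should agree closely
        m1, m2 = doses[1].data[ctv].mean(), doses[2].data[ctv].mean()
        assert abs(m1 - m2) < 0.01 * brain_case.plan.prescription


class TestEvaluateRobustness:
    def test_report_invariants(self, brain_case):
        scen = make_scenarios(3.0, 0.035)
        rep = evaluate_robustness(brain_case.plan, brain_case.ct, scen, brain_case.rois)
        assert rep.worst_case_v95 == rep.scenario_v95.min()
        assert rep.voxelwise_min_v95 <= rep.scenario_v95.min() + 1e-9
        assert 0 < rep.d50 <= 1.1 * brain_case.plan.prescription
        assert "brainstem" in rep.oar_metrics
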