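"""Synthetic cohort generator: reproducibility, invariants, distributions."""

import numpy as np
import pytest

from captraj import (
    CapConfig,
    LinearTruth,
    SigmoidParams,
    assign_cap,
    default_hd_scenario,
    generate_cohort,
    left_flat_sigmoid,
    linear_truth_scenario,
)
from captraj.cohort import BASAL_GANGLIA_ROIS, roi_columns
from conftest import probe_scenario


class TestScenarioValidation:
    def test_default_scenario_valid(self):
        sc = default_hd_scenario()
        assert abs(sum(sc.study_weights.values()) - 1.0) < 1e-12
        assert sc.cag_range_control == (15, 31)
        assert sc.cag_range_carrier == (38, 55)

    def test_basal_ganglia_changepoints_precede_cortex(self):
        sc = default_hd_scenario()
        bg = [sc.roi_truths[r].tau for r in BASAL_GANGLIA_ROIS]
        cortex = [sc.roi_truths[r].tau for r in ("prcg", "sfg", "spg", "sog", "stg")]
        assert max(bg) < min(cortex)

    @pytest.mark.parametrize(
        "kw",
        [
            {"study_weights": {"A": 0.5, "B": 0.6}},
            {"age_range": (72.0, 18.0)},
            {"noise_sd_fraction": -0.1},
            {"artefact_rate": 1.5},
            {"roi_truths": {}},
        ],
    )
    def test_invalid_scenarios_rejected(self, kw):
        with pytest.raises(ValueError):
            default_hd_scenario(**kw)


class TestGeneration:
    def test_seed_determinism(self):
        sc = probe_scenario(seed=42, n_carriers=50, n_controls=20)
        a, b = generate_cohort(sc), generate_cohort(sc)
        assert a.equals(b)
        c = generate_cohort(sc, seed=43)
        assert not a.equals(c)

    def test_record_invariants(self):
        cohort = generate_cohort(default_hd_scenario(n_carriers=200, n_controls=80, seed=1))
        assert np.all(cohort["icv"] > cohort["whole_brain"])
        assert np.all(cohort["whole_brain"] > 0)
        for roi in roi_columns(cohort):
            assert np.all(cohort[roi] > 0)
            assert np.all(cohort[roi] < cohort["whole_brain"])
        # ages strictly increase across visits
        for _, sub in cohort.groupby("subject_id"):
            ages = sub.sort_values("visit_index")["age"].to_numpy()
            assert np.all(np.diff(ages) > 0)

    def test_zero_noise_lies_exactly_on_curve(self):
        truth = SigmoidParams(8000.0, 2400.0, 300.0, 60.0)
        sc = probe_scenario(
            seed=2, noise=0.0, truth=truth, icv_coupling=0.0,
            study_batch_frac={"A": 0.0, "B": 0.0, "C": 0.0},
            group_frac={"control": 0.0, "premanifest": 0.0, "manifest": 0.0},
        )
        cohort = generate_cohort(sc)
        carriers = cohort[cohort["group"] != "control"]
        cap = carriers["age"].to_numpy() * (carriers["cag"].to_numpy() - 33.66)
        np.testing.assert_allclose(
            carriers["probe"], left_flat_sigmoid(cap, truth), rtol=1e-12
        )
        controls = cohort[cohort["group"] == "control"]
        np.testing.assert_allclose(controls["probe"], truth.v0, rtol=1e-12)

    def test_carrier_caps_consistent_elementwise(self):
        cohort = generate_cohort(probe_scenario(seed=3))
        capped = assign_cap(cohort, CapConfig())
        carriers = capped[capped["group"] != "control"]
        np.testing.assert_allclose(
            carriers["cap"],
            carriers["age"] * (carriers["cag"] - 33.66),
            rtol=1e-12,
        )

    def test_population_distributions(self):
        sc = default_hd_scenario(n_carriers=1400, n_controls=600, seed=5)
        cohort = generate_cohort(sc)
        base = cohort[cohort["visit_index"] == 0]
        carriers = base[base["group"] != "control"]
        controls = base[base["group"] == "control"]
        assert carriers["cag"].between(38, 55).all()
        assert controls["cag"].between(15, 31).all()
        # CAG means near the configured population values
        assert carriers["cag"].mean() == pytest.approx(42.7, abs=0.5)
        assert controls["cag"].mean() == pytest.approx(20.4, abs=0.5)
        assert base["age"].between(*sc.age_range).all()
        # roughly uniform baseline ages: mean near the midpoint
        assert base["age"].mean() == pytest.approx(np.mean(sc.age_range), abs=2.0)
        # study mix follows the weights
        freq = base["study"].value_counts(normalize=True)
        for s, w in sc.study_weights.items():
            assert freq[s] == pytest.approx(w, abs=0.05)

    def test_attrition_limits_visits(self):
        cohort = generate_cohort(default_hd_scenario(n_carriers=300, n_controls=0, seed=6))
        visits = cohort.groupby("subject_id").size()
        assert visits.max() <= 5
        assert visits.min() >= 1
        full = generate_cohort(
            default_hd_scenario(n_carriers=300, n_controls=0, seed=6, retention=1.0)
        )
        assert full.groupby("subject_id").size().mean() >= visits.mean()

    def test_heavy_tail_option(self):
        sc = probe_scenario(seed=7, heavy_tails=True)
        cohort = generate_cohort(sc)
        assert np.isfinite(cohort["probe"]).all()


class TestLinearTruth:
    def test_zero_noise_on_the_line(self):
        sc = linear_truth_scenario(n_carriers=50, noise_sd_fraction=0.0, seed=8,
                                   study_batch_frac={"A": 0.0, "B": 0.0, "C": 0.0},
                                   icv_coupling=0.0)
        cohort = generate_cohort(sc)
        cap = cohort["age"] * (cohort["cag"] - 33.66)
        truth = sc.roi_truths["roi_linear"]
        assert isinstance(truth, LinearTruth)
        np.testing.assert_allclose(cohort["roi_linear"], truth.v0 + truth.slope * cap,
                                   rtol=1e-12)

    def test_carriers_only(self):
        cohort = generate_cohort(linear_truth_scenario(seed=9))
        assert not cohort["group"].eq("control").any()


class TestScenarioFiles:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        sc = probe_scenario(seed=12, n_carriers=30, n_controls=10)
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(yaml.safe_load(sc.to_json())))
        from captraj.simulate import scenario_from_yaml

        back = scenario_from_yaml(path)
        assert back == sc
        assert generate_cohort(back).equals(generate_cohort(sc))

    def test_linear_truth_survives_round_trip(self, tmp_path):
        import yaml

        sc = linear_truth_scenario(n_carriers=25, seed=13)
        path = tmp_path / "s.yaml"
        path.write_text(yaml.safe_dump(yaml.safe_load(sc.to_json())))
        from captraj.simulate import scenario_from_yaml

        back = scenario_from_yaml(path)
        assert isinstance(back.roi_truths["roi_linear"], LinearTruth)
        assert back == sc
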