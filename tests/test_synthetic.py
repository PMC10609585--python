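import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from prokrates.pipeline import compute_rates, reduce_experiment
from prokrates.synthetic import (
    ObservationNoiseModel,
    TrueTreatmentParams,
    simulate_dynamics,
    simulate_experiment,
)


class TestDynamics:
    def test_balanced_growth_holds_abundance(self):
        p = TrueTreatmentParams("control", 0.7, 0.7, 1e9)
        for t in (0.0, 1.0, 2.0, 5.0):
            assert simulate_dynamics(p, t) == pytest.approx(1e9, rel=1e-12)

    def test_doubling(self):
        p = TrueTreatmentParams("control", math.log(2), 0.0, 1e9)
        assert simulate_dynamics(p, 1.0) == pytest.approx(2e9, rel=1e-12)

    def test_ambient_decline(self):
        # SGR 1.321, MR 1.441 -> N0 * exp(-0.24) after 2 days
        p = TrueTreatmentParams("control", 1.321, 1.441, 1e9)
        assert simulate_dynamics(p, 2.0) == pytest.approx(1e9 * math.exp(-0.24), rel=1e-9)
        assert simulate_dynamics(p, 2.0) == pytest.approx(7.866e8, rel=1e-3)

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            simulate_dynamics(TrueTreatmentParams("c", 1.0, 0.5, 1e9), -0.1)

    def test_rejects_invalid_truths(self):
        with pytest.raises(ValueError):
            TrueTreatmentParams("c", -0.1, 0.5, 1e9)
        with pytest.raises(ValueError):
            TrueTreatmentParams("c", 0.1, 0.5, 0.0)
        with pytest.raises(ValueError):
            TrueTreatmentParams("c", 0.1, 0.5, 1e9, mean_cell_volume=-1.0)


class TestSimulateExperiment:
    def test_same_seed_bit_identical(self, scenario, noise):
        design, truths, chem = scenario
        a = simulate_experiment(design, truths, noise, seed=42, chemistry=chem)
        b = simulate_experiment(design, truths, noise, seed=42, chemistry=chem)
        pd.testing.assert_frame_equal(a.to_sample_sheet(), b.to_sample_sheet())
        assert a.to_sample_sheet().to_csv(index=False) == b.to_sample_sheet().to_csv(index=False)

    def test_different_seeds_differ(self, scenario, noise):
        design, truths, chem = scenario
        a = simulate_experiment(design, truths, noise, seed=1, chemistry=chem)
        b = simulate_experiment(design, truths, noise, seed=2, chemistry=chem)
        assert not a.to_sample_sheet().equals(b.to_sample_sheet())

    def test_unit_layout(self, scenario, noise):
        design, truths, chem = scenario
        exp = simulate_experiment(design, truths, noise, seed=0, chemistry=chem)
        # one RawSample per treatment x replicate x timepoint
        assert len(exp.samples) == 4 * design.replicates * 2
        t0 = [s for s in exp.samples if s.timepoint_h == 0.0]
        t48 = [s for s in exp.samples if s.timepoint_h == 48.0]
        assert len(t0) == len(t48) == 12
        assert all(s.dpm_samples is None for s in t0)
        assert all(s.dpm_samples is not None for s in t48)

    def test_noiseless_round_trip_recovers_truth(self, scenario, noiseless_truths, config):
        design, _, chem = scenario
        exp = simulate_experiment(
            design, noiseless_truths, ObservationNoiseModel().noiseless(), seed=3,
            chemistry=chem, carbon_model=config.carbon_model,
        )
        rates = compute_rates(reduce_experiment(exp, config), config)
        for t in noiseless_truths:
            rows = rates[rates["treatment"] == t.treatment_label]
            assert len(rows) == design.replicates
            np.testing.assert_allclose(rows["sgr"], t.sgr_true, rtol=1e-6)
            np.testing.assert_allclose(rows["ngr"], t.sgr_true - t.mr_true, rtol=0, atol=1e-6)
            np.testing.assert_allclose(rows["mr"], t.mr_true, rtol=0, atol=1e-6)

    def test_counting_consistency_over_seeds(self, scenario, noise):
        """Expected total cells counted per slide equals
        N * volume_filtered / filter_area_ratio * fields_per_slide."""
        design, truths, chem = scenario
        control = truths[0]
        expected = (
            control.n0_true * noise.volume_filtered / noise.filter_area_ratio
        ) * noise.fields_per_slide
        totals = []
        for seed in range(120):
            exp = simulate_experiment(design, truths, noise, seed=seed, chemistry=chem)
            s = next(
                x for x in exp.samples
                if x.treatment == "control" and x.replicate == 1 and x.timepoint_h == 0.0
            )
            totals.append(float(np.sum(s.cells_per_field)))
        assert np.mean(totals) == pytest.approx(expected, rel=0.02)

    def test_unreachable_count_minimum_is_reported(self, scenario):
        design, truths, chem = scenario
        thin = ObservationNoiseModel(volume_filtered=1e-6)
        with pytest.raises(ValueError, match="protocol minimum"):
            simulate_experiment(design, truths, thin, seed=0, chemistry=chem)

    def test_missing_truth_rejected(self, scenario, noise):
        design, truths, chem = scenario
        with pytest.raises(ValueError, match="no ground truth"):
            simulate_experiment(design, truths[:2], noise, seed=0, chemistry=chem)

    def test_protocol_floor_on_fields(self):
        with pytest.raises(ValueError):
            ObservationNoiseModel(fields_per_slide=30)


class TestSampleSheet:
    def test_sheet_shape_and_columns(self, scenario, noise):
        from prokrates.synthetic import SAMPLE_SHEET_COLUMNS

        design, truths, chem = scenario
        exp = simulate_experiment(design, truths, noise, seed=5, chemistry=chem)
        sheet = exp.to_sample_sheet()
        assert list(sheet.columns) == SAMPLE_SHEET_COLUMNS
        assert len(sheet) == len(exp.samples) * noise.fields_per_slide

    def test_volume_scatter_respects_cv(self, scenario, noise):
        design, truths, chem = scenario
        wide = [dataclasses.replace(t, cv_cell_volume=0.6) for t in truths]
        exp = simulate_experiment(design, wide, noise, seed=9, chemistry=chem)
        vols = np.concatenate([s.cell_volumes for s in exp.samples])
        # lognormal with matched mean: sample mean near truth, strictly positive
        assert np.all(vols > 0)
        assert np.mean(vols) == pytest.approx(truths[0].mean_cell_volume, rel=0.05)
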