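"""Tests for the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from substage import (
    DemographicsParams,
    PlantedEdge,
    apply_exclusions,
    default_registry,
    generate_clinical,
    generate_connectivity,
    generate_demographics,
    generate_truth,
    generate_volumes,
)
from substage.cohort import validate_subjects
from substage.normalization import average_bilateral, compute_zscores, fit_control_model
from substage.sustain import expected_z_matrix
from conftest import reversed_sequence, sequence_kendall_tau


class TestDemographics:
    def test_group_sizes_and_schema(self):
        t = generate_demographics(224, 85, seed=1)
        validate_subjects(t)
        assert (t["group"] == "control").sum() == 224
        assert (t["group"] == "patient").sum() == 85
        assert t["subject_id"].is_unique

    def test_zero_variance_puts_subjects_at_means(self):
        p = DemographicsParams(control_age_sd=0.0, patient_age_sd=0.0, tiv_sd=0.0)
        t = generate_demographics(1, 1, p, seed=0)
        assert t.loc[t.group == "control", "age"].iloc[0] == p.control_age_mean
        assert t.loc[t.group == "patient", "age"].iloc[0] == p.patient_age_mean

    def test_same_seed_identical(self):
        a = generate_demographics(30, 20, seed=5)
        b = generate_demographics(30, 20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_moments_near_configured(self):
        t = generate_demographics(2000, 2000, seed=2)
        ctrl = t[t.group == "control"]
        assert ctrl["age"].mean() == pytest.approx(34.5, abs=1.0)
        assert (ctrl["sex"] == "male").mean() == pytest.approx(0.607, abs=0.03)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_demographics(0, 10)


class TestGroundTruth:
    def test_event_count_and_stage_range(self):
        names = [f"b{i}" for i in range(13)]
        truth = generate_truth(50, 2, names, (1.0, 2.0, 3.0), seed=0)
        assert truth.n_events == 39
        assert truth.stage.min() >= 0 and truth.stage.max() <= 39
        for s in truth.sequences:
            assert sorted(s.events()) == sorted(
                (b, t) for b in range(13) for t in (1.0, 2.0, 3.0))

    def test_single_subtype_all_zero(self):
        truth = generate_truth(20, 1, ["a", "b"], (1.0,), fractions=[1.0], seed=1)
        assert np.all(truth.subtype == 0)

    def test_reversed_sequences_have_tau_minus_one(self):
        # single-threshold events: full reversal is itself a valid sequence
        truth = generate_truth(10, 1, list("abcdef"), (1.0,), seed=3)
        s = truth.sequences[0]
        assert sequence_kendall_tau(s, reversed_sequence(s)) == pytest.approx(-1.0)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_truth(10, 1, ["a"], (2.0, 1.0))

    def test_manifest_round_trip(self):
        truth = generate_truth(15, 2, ["a", "b", "c"], (1.0, 2.0), seed=4)
        truth.planted_edges = [PlantedEdge(0, 3, 0.7, 1)]
        truth.clinical_slopes = {"score": [0.5, -0.5]}
        back = type(truth).from_dict(truth.to_dict())
        assert back.sequences[0] == truth.sequences[0]
        assert np.array_equal(back.stage, truth.stage)
        assert back.planted_edges == truth.planted_edges


class TestVolumes:
    @pytest.fixture
    def setting(self):
        reg = default_registry()
        subjects = generate_demographics(60, 40, seed=0)
        truth = generate_truth(40, 1, reg.biomarkers, (1.0, 2.0, 3.0), seed=1)
        return reg, subjects, truth

    def test_stage_zero_noiseless_equals_prediction(self, setting):
        reg, subjects, truth = setting
        truth.stage[:] = 0
        vols = generate_volumes(subjects, truth, noise_sd=0.0, seed=2, registry=reg)
        betas = reg.default_betas()
        pat = subjects[subjects.group == "patient"]
        X = np.column_stack([np.ones(len(pat)), pat.age,
                             (pat.sex == "female").astype(float), pat.tiv])
        pred = X @ betas.loc[truth.biomarkers].to_numpy().T
        got = vols.loc[pat.subject_id].to_numpy()
        assert np.allclose(got, pred)

    def test_passed_event_displaces_by_threshold_times_sd(self, setting):
        reg, subjects, truth = setting
        # put every patient at the stage right after some biomarker's z=2 event
        seq = truth.sequences[0]
        target = np.flatnonzero(seq.threshold == 2.0)[0] + 1
        truth.stage[:] = target
        bm = seq.biomarker[target - 1]
        name = truth.biomarkers[bm]
        vols = generate_volumes(subjects, truth, noise_sd=0.0, seed=2, registry=reg)
        betas, sd = reg.default_betas(), reg.default_resid_sd()
        pat = subjects[subjects.group == "patient"]
        X = np.column_stack([np.ones(len(pat)), pat.age,
                             (pat.sex == "female").astype(float), pat.tiv])
        pred = X @ betas.loc[name].to_numpy()
        expect = pred - 2.0 * sd[name]
        assert np.allclose(vols.loc[pat.subject_id, name], expect)

    def test_controls_self_consistent_zscores(self, setting):
        reg, _, _ = setting
        subjects = generate_demographics(200, 1, seed=5)
        truth = generate_truth(1, 1, reg.biomarkers, (1.0, 2.0, 3.0), seed=1)
        truth.stage[:] = 0
        vols = generate_volumes(subjects, truth, seed=6, registry=reg)
        model = fit_control_model(vols, subjects)
        z = compute_zscores(vols, subjects, model)
        zc = z.loc[subjects[subjects.group == "control"].subject_id]
        assert np.all(np.abs(zc.mean()) < 0.05)
        assert np.all((zc.std() > 0.9) & (zc.std() < 1.1))

    def test_bilateral_split_averages_back_exactly(self, setting):
        reg, subjects, truth = setting
        vols = generate_volumes(subjects, truth, seed=3, registry=reg,
                                split_bilateral=True, asymmetry_sd=100.0)
        assert "limbic_left" in vols.columns and "limbic" not in vols.columns
        merged = average_bilateral(vols, reg.bilateral_pairs)
        ref = generate_volumes(subjects, truth, seed=3, registry=reg)
        pd.testing.assert_frame_equal(
            merged[ref.columns], ref, check_exact=False, atol=1e-6)

    def test_region_mismatch_rejected(self, setting):
        reg, subjects, truth = setting
        betas = reg.default_betas().drop(index=["thalamus"])
        with pytest.raises(ValueError, match="thalamus"):
            generate_volumes(subjects, truth, control_betas=betas, registry=reg)


class TestConnectivity:
    def test_structure_and_determinism(self):
        subjects = generate_demographics(10, 30, seed=0)
        truth = generate_truth(30, 1, ["a", "b"], (1.0,), seed=0)
        s1 = generate_connectivity(subjects, truth, n_regions=12, seed=4)
        s2 = generate_connectivity(subjects, truth, n_regions=12, seed=4)
        assert np.array_equal(s1.data, s2.data)
        assert np.allclose(s1.data, np.transpose(s1.data, (0, 2, 1)))
        assert np.all(np.diagonal(s1.data, axis1=1, axis2=2) == 0)
        assert s1.n_regions == 12

    def test_planted_edge_realises_target_spearman(self):
        # Monte-Carlo over seeds: |rho_hat - 0.7| within 0.15 on average
        errs = []
        for seed in range(20):
            subjects = generate_demographics(5, 50, seed=seed)
            truth = generate_truth(50, 1, ["a", "b", "c"], (1.0, 2.0), seed=seed)
            stack = generate_connectivity(
                subjects, truth, n_regions=10,
                planted=[PlantedEdge(2, 7, 0.7, 0)], edge_noise_sd=0.1, seed=seed)
            pat = (subjects.group == "patient").to_numpy()
            rho = spearmanr(stack.edge_values(2, 7)[pat], truth.stage).statistic
            errs.append(abs(rho - 0.7))
        assert np.mean(errs) < 0.15

    def test_self_edge_rejected(self):
        subjects = generate_demographics(2, 5, seed=0)
        truth = generate_truth(5, 1, ["a"], (1.0,), seed=0)
        with pytest.raises(ValueError, match="self-edge"):
            generate_connectivity(subjects, truth, n_regions=5,
                                  planted=[PlantedEdge(3, 3, 0.5)])

    def test_96_regions_yield_4560_edges(self):
        subjects = generate_demographics(1, 2, seed=0)
        truth = generate_truth(2, 1, ["a"], (1.0,), seed=0)
        stack = generate_connectivity(subjects, truth, n_regions=96, seed=0)
        vals, pairs = stack.edge_matrix()
        assert len(pairs) == 4560 and vals.shape == (3, 4560)


class TestClinical:
    def test_zero_slope_zero_noise_constant(self):
        subjects = generate_demographics(5, 30, seed=0)
        truth = generate_truth(30, 1, ["a", "b"], (1.0, 2.0), seed=1)
        t = generate_clinical(subjects, truth, slopes={"s": [0.0]},
                              score_noise_sd=0.0, baselines={"s": 4.0},
                              patient_missing_rate=0.0, seed=2)
        assert np.all(t.loc[t.group == "patient", "s"] == 4.0)
        assert t.loc[t.group == "control", "s"].isna().all()

    def test_positive_slope_monotone_in_stage(self):
        subjects = generate_demographics(5, 40, seed=0)
        truth = generate_truth(40, 1, ["a", "b"], (1.0, 2.0), seed=3)
        t = generate_clinical(subjects, truth, slopes={"s": [0.5]},
                              score_noise_sd=0.0, patient_missing_rate=0.0, seed=2)
        vals = t.loc[t.group == "patient", "s"].to_numpy()
        order = np.argsort(truth.stage)
        assert np.all(np.diff(vals[order]) >= 0)

    def test_slope_recovered_within_ci(self):
        # planted slope 0.735 recovered by the downstream regression
        from substage.clinical import stage_clinical_regression
        hits = 0
        for seed in range(10):
            subjects = generate_demographics(5, 44, seed=seed)
            truth = generate_truth(44, 1, ["a", "b"], (1.0, 2.0), seed=seed)
            t = generate_clinical(subjects, truth, slopes={"s": [0.735]},
                                  score_noise_sd=1.0, patient_missing_rate=0.0,
                                  seed=seed)
            pat = t[t.group == "patient"]
            r = stage_clinical_regression(pat["s"], truth.stage, pat["age"],
                                          pat["sex"])
            half = 1.96 * r.extra["se_stage"]
            hits += abs(r.extra["beta_stage"] - 0.735) <= half
        assert hits >= 8  # ~95% coverage, allow Monte-Carlo slack

    def test_unknown_subtype_key_rejected(self):
        subjects = generate_demographics(2, 5, seed=0)
        truth = generate_truth(5, 2, ["a"], (1.0,), seed=0)
        with pytest.raises(ValueError, match="slopes"):
            generate_clinical(subjects, truth, slopes={"s": [0.1]})


class TestExclusions:
    def test_bookkeeping_counts(self):
        t = generate_demographics(234, 92, seed=0)
        pat = t[t.group == "patient"].subject_id.tolist()
        ctrl = t[t.group == "control"].subject_id.tolist()
        kept, summary = apply_exclusions(t, pat[:7] + ctrl[:10])
        assert summary["patient"] == {"enrolled": 92, "excluded": 7, "analyzed": 85}
        assert summary["control"] == {"enrolled": 234, "excluded": 10, "analyzed": 224}
        assert len(kept) == 85 + 224

    def test_unknown_id_rejected(self):
        t = generate_demographics(3, 3, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            apply_exclusions(t, ["nope"])
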