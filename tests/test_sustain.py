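"""Unit and oracle tests for the z-score event-based subtype/stage model."""

import numpy as np
import pytest
from scipy.special import logsumexp

from substage.sustain import (
    EventSequence,
    assign_subjects,
    bic,
    enumerate_sequences,
    expected_z_at_stage,
    expected_z_matrix,
    fit_subtypes,
    optimize_sequence,
    random_sequence,
    select_model,
    sequence_log_likelihood,
    subject_log_likelihood,
)
from conftest import planted_cohort, sequence_kendall_tau


def single_biomarker_seq():
    return EventSequence(np.array([0, 0, 0]), np.array([1.0, 2.0, 3.0]), 1)


class TestEventSequence:
    def test_rejects_threshold_order_violation(self):
        with pytest.raises(ValueError, match="not increasing"):
            EventSequence(np.array([0, 0]), np.array([2.0, 1.0]), 1)

    def test_rejects_duplicate_event(self):
        with pytest.raises(ValueError, match="duplicate"):
            EventSequence(np.array([0, 0]), np.array([1.0, 1.0]), 1)

    def test_enumeration_count_two_by_two(self):
        # 2 biomarkers x 2 thresholds: 4!/(2!2!) = 6 valid orderings
        assert len(enumerate_sequences(2, (1.0, 2.0))) == 6

    def test_random_sequences_are_valid_and_cover(self, rng):
        seen = set()
        for _ in range(200):
            s = random_sequence(2, (1.0, 2.0), rng)
            seen.add(tuple(s.biomarker.tolist()))
        assert len(seen) == 6  # uniform support over all valid orderings


class TestExpectedZ:
    def test_stage_zero_is_zero(self):
        seq = single_biomarker_seq()
        assert expected_z_at_stage(seq, 0, 0, 5.0) == 0.0

    def test_vertex_hits(self):
        seq = single_biomarker_seq()
        # thresholds (1,2,3) at sequence positions 1,2,3
        assert expected_z_at_stage(seq, 0, 2, 5.0) == pytest.approx(2.0)
        assert expected_z_at_stage(seq, 0, 3, 5.0) == pytest.approx(3.0)

    def test_slope_toward_z_max_beyond_last_event(self):
        # other biomarker's events extend the sequence past biomarker 0's last
        seq = EventSequence(np.array([0, 0, 0, 1, 1, 1]),
                            np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), 2)
        E = expected_z_matrix(seq, 5.0)
        n = seq.n_events
        slope = (E[4, 0] - E[3, 0])
        assert slope == pytest.approx((5.0 - 3.0) / (n - 3))
        assert E[n, 0] == pytest.approx(5.0)

    def test_stage_out_of_range(self):
        with pytest.raises(ValueError, match="stage"):
            expected_z_at_stage(single_biomarker_seq(), 0, 4, 5.0)

    def test_monotone_nondecreasing_in_stage(self, rng):
        seq = random_sequence(4, (1.0, 2.0), rng)
        E = expected_z_matrix(seq, 5.0)
        assert np.all(np.diff(E, axis=0) >= -1e-12)

    def test_z_max_must_exceed_top_threshold(self):
        seq = EventSequence(np.array([0, 1, 0]), np.array([1.0, 1.0, 2.0]), 2)
        with pytest.raises(ValueError, match="z_max"):
            expected_z_matrix(seq, 0.9)


class TestSubjectLikelihood:
    def test_matches_linear_space_brute_force(self, rng):
        # tiny instance: 2 biomarkers, thresholds (1,2) -> 4 events, 5 stages
        seq = random_sequence(2, (1.0, 2.0), rng)
        sigma = np.array([0.8, 1.3])
        z = rng.normal(0, 2, 2)
        E = expected_z_matrix(seq, 5.0)
        dens = [
            np.prod([
                np.exp(-0.5 * ((z[i] - E[k, i]) / sigma[i]) ** 2)
                / (sigma[i] * np.sqrt(2 * np.pi))
                for i in range(2)
            ])
            for k in range(5)
        ]
        expected = np.log(np.sum(dens) / 5.0)
        ll, post = subject_log_likelihood(z, seq, sigma, 5.0)
        assert ll == pytest.approx(expected, rel=1e-10)
        assert post == pytest.approx(np.array(dens) / np.sum(dens), rel=1e-10)

    def test_posterior_mode_at_generating_stage(self, rng):
        seq = random_sequence(3, (1.0, 2.0, 3.0), rng)
        E = expected_z_matrix(seq, 5.0)
        for k in [0, 3, 7, seq.n_events]:
            _, post = subject_log_likelihood(E[k], seq, 1.0, 5.0)
            assert int(np.argmax(post)) == k
            assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_row_prefers_stage_zero(self):
        seq = single_biomarker_seq()
        _, post = subject_log_likelihood(np.zeros(1), seq, 1.0, 5.0)
        assert int(np.argmax(post)) == 0

    def test_no_underflow_at_extreme_z(self):
        seq = single_biomarker_seq()
        ll, post = subject_log_likelihood(np.array([20.0]), seq, 1.0, 5.0)
        assert np.isfinite(ll)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            subject_log_likelihood(np.zeros(1), single_biomarker_seq(), 0.0, 5.0)

    def test_invariant_to_biomarker_permutation(self, rng):
        seq = random_sequence(4, (1.0, 2.0), rng)
        Z = rng.normal(0, 1.5, (20, 4))
        perm = rng.permutation(4)
        inv = np.argsort(perm)
        seq_p = EventSequence(inv[seq.biomarker], seq.threshold, 4)
        ll = sequence_log_likelihood(Z, seq, 1.0, 5.0)
        ll_p = sequence_log_likelihood(Z[:, perm], seq_p, 1.0, 5.0)
        assert ll_p == pytest.approx(ll, rel=1e-12)


class TestOptimizeSequence:
    def test_matches_exhaustive_search_on_tiny_instances(self, rng):
        thresholds = (1.0, 2.0)
        all_seqs = enumerate_sequences(2, thresholds)
        for trial in range(10):
            Z, _, _, _ = planted_cohort(12, n_bm=2, thresholds=thresholds,
                                        n_subtypes=1, noise_sd=0.5, seed=trial)
            lls = [sequence_log_likelihood(Z, s, 1.0, 5.0) for s in all_seqs]
            best_ll = max(lls)
            seq, ll = optimize_sequence(Z, n_restarts=6, seed=trial,
                                        thresholds=thresholds)
            assert ll == pytest.approx(best_ll, abs=1e-9)

    def test_recovers_planted_sequence_noiselessly(self, rng):
        Z, _, _, seqs = planted_cohort(80, n_bm=4, thresholds=(1.0, 2.0),
                                       n_subtypes=1, noise_sd=0.0, seed=7)
        seq, _ = optimize_sequence(Z, n_restarts=8, seed=1, thresholds=(1.0, 2.0))
        assert sequence_kendall_tau(seqs[0], seq) == pytest.approx(1.0)

    def test_all_weights_zero_rejected(self):
        Z = np.zeros((5, 2))
        with pytest.raises(ValueError, match="weights"):
            optimize_sequence(Z, weights=np.zeros(5), thresholds=(1.0, 2.0))

    def test_deterministic_given_seed(self):
        Z, *_ = planted_cohort(30, n_bm=3, thresholds=(1.0, 2.0),
                               n_subtypes=1, noise_sd=0.4, seed=2)
        r1 = optimize_sequence(Z, n_restarts=4, seed=9, thresholds=(1.0, 2.0))
        r2 = optimize_sequence(Z, n_restarts=4, seed=9, thresholds=(1.0, 2.0))
        assert r1[0] == r2[0] and r1[1] == r2[1]


class TestFitAndSelect:
    def test_two_planted_subtypes_recovered(self):
        # well-separated subtypes: biomarker blocks progress in opposite orders
        from conftest import block_pair
        Z, subtype, _, seqs = planted_cohort(
            200, n_bm=5, thresholds=(1.0, 2.0), noise_sd=0.25, seed=11,
            sequences=block_pair(5, (1.0, 2.0)))
        models = fit_subtypes(Z, max_subtypes=2, n_restarts=4, em_iters=12,
                              seed=0, thresholds=(1.0, 2.0), split_restarts=3)
        assert select_model(models) == 2
        a = assign_subjects(Z, models[1])
        acc = max((a.subtype == subtype).mean(), (a.subtype != subtype).mean())
        assert acc >= 0.9
        taus = sorted(
            max(abs(sequence_kendall_tau(seqs[c], models[1].sequences[d]))
                for d in range(2))
            for c in range(2)
        )
        assert np.mean(taus) >= 0.8

    def test_em_trace_monotone(self):
        Z, *_ = planted_cohort(100, n_bm=4, thresholds=(1.0, 2.0),
                               n_subtypes=2, noise_sd=0.4, seed=5)
        models = fit_subtypes(Z, max_subtypes=2, n_restarts=3, em_iters=10,
                              seed=1, thresholds=(1.0, 2.0), split_restarts=2)
        trace = np.asarray(models[1].em_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_null_single_subtype_prefers_c1(self):
        wins = 0
        for seed in range(5):
            Z, *_ = planted_cohort(120, n_bm=4, thresholds=(1.0, 2.0),
                                   n_subtypes=1, noise_sd=0.3, seed=seed)
            models = fit_subtypes(Z, max_subtypes=2, n_restarts=3, em_iters=8,
                                  seed=seed, thresholds=(1.0, 2.0),
                                  split_restarts=2)
            wins += select_model(models) == 1
        assert wins >= 4

    def test_bic_formula_and_tie_break(self):
        Z, *_ = planted_cohort(40, n_bm=2, thresholds=(1.0, 2.0),
                               n_subtypes=1, noise_sd=0.3, seed=0)
        models = fit_subtypes(Z, max_subtypes=1, n_restarts=3, seed=0,
                              thresholds=(1.0, 2.0))
        m = models[0]
        expected = -2 * m.log_likelihood + (1 * 4 + 0) * np.log(40)
        assert bic(m) == pytest.approx(expected)
        assert select_model(models) == 1
        with pytest.raises(ValueError):
            select_model([])

    def test_max_subtypes_exceeding_support_rejected(self):
        Z = np.zeros((3, 2))
        with pytest.raises(ValueError, match="support"):
            fit_subtypes(Z, max_subtypes=2, thresholds=(1.0, 2.0))


class TestAssign:
    def test_noiseless_roundtrip(self):
        from conftest import block_pair
        Z, subtype, stage, seqs = planted_cohort(
            60, n_bm=4, thresholds=(1.0, 2.0), noise_sd=0.0, seed=3,
            sequences=block_pair(4, (1.0, 2.0)))
        from substage.sustain import SubtypeModel
        model = SubtypeModel(seqs, np.array([0.5, 0.5]), np.ones(4),
                             np.full(4, 5.0), 0.0, 60)
        a = assign_subjects(Z, model)
        assert np.array_equal(a.stage, stage)
        # only stage-0 subjects are ambiguous between opposite orderings
        mid = stage > 0
        assert np.array_equal(a.subtype[mid], subtype[mid])
        assert np.allclose(a.stage_posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_rows_assigned_stage_zero(self):
        seqs = [single_biomarker_seq()]
        from substage.sustain import SubtypeModel
        model = SubtypeModel(seqs, np.array([1.0]), np.ones(1), np.full(1, 5.0),
                             0.0, 4)
        a = assign_subjects(np.zeros((4, 1)), model)
        assert np.all(a.stage == 0)

    def test_label_symmetry_under_subtype_permutation(self):
        Z, *_ , seqs = planted_cohort(40, n_bm=3, thresholds=(1.0, 2.0),
                                      n_subtypes=2, noise_sd=0.3, seed=8)
        from substage.sustain import SubtypeModel
        m1 = SubtypeModel(seqs, np.array([0.5, 0.5]), np.ones(3),
                          np.full(3, 5.0), 0.0, 40)
        m2 = SubtypeModel(seqs[::-1], np.array([0.5, 0.5]), np.ones(3),
                          np.full(3, 5.0), 0.0, 40)
        a1, a2 = assign_subjects(Z, m1), assign_subjects(Z, m2)
        free = ~(a1.tied | a2.tied)
        assert np.array_equal(a1.subtype[free], 1 - a2.subtype[free])
        assert np.array_equal(a1.stage[free], a2.stage[free])

    def test_biomarker_mismatch_rejected(self):
        from substage.sustain import SubtypeModel
        model = SubtypeModel([single_biomarker_seq()], np.array([1.0]),
                             np.ones(1), np.full(1, 5.0), 0.0, 4)
        with pytest.raises(ValueError, match="biomarker"):
            assign_subjects(np.zeros((4, 2)), model)

    def test_model_dict_round_trip(self):
        Z, *_ = planted_cohort(30, n_bm=3, thresholds=(1.0, 2.0),
                               n_subtypes=1, noise_sd=0.3, seed=0)
        from substage.sustain import SubtypeModel
        m = fit_subtypes(Z, max_subtypes=1, n_restarts=2, seed=0,
                         thresholds=(1.0, 2.0))[0]
        m2 = SubtypeModel.from_dict(m.to_dict(), 3)
        assert m2.sequences[0] == m.sequences[0]
        assert m2.log_likelihood == pytest.approx(m.log_likelihood)
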