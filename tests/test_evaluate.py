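"""Agreement statistics, MCCV splitting, and the variant harness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import vesseltort as vt
from vesseltort.errors import (ContractViolationError, RatingsFormatError,
                               UndefinedStatisticError)


class TestConsensus:
    def test_all_32_vote_patterns_match_enumeration(self):
        for votes in itertools.product((0, 1), repeat=5):
            counts = {0: votes.count(0), 1: votes.count(1)}
            expected = max(counts, key=counts.get)
            assert vt.consensus_label(votes) == expected

    def test_malformed_votes_rejected(self):
        with pytest.raises(RatingsFormatError):
            vt.consensus_label((0, 1, 2, 0, 1))
        with pytest.raises(RatingsFormatError):
            vt.consensus_label((0, 1, 0))


class TestAgreementSummary:
    def test_unanimous_matrix(self):
        r = np.ones((8, 5), dtype=int)
        assert vt.agreement_summary(r) == {
            "full_consensus": 1.0, "four_agree": 0.0, "three_vs_two": 0.0}

    def test_single_four_one_row(self):
        out = vt.agreement_summary(np.array([[1, 1, 1, 1, 0]]))
        assert out == {"full_consensus": 0.0, "four_agree": 1.0, "three_vs_two": 0.0}

    def test_random_matrix_matches_row_counting(self):
        rng = np.random.default_rng(8)
        r = (rng.uniform(size=(50, 5)) < 0.4).astype(int)
        out = vt.agreement_summary(r)
        maj = np.maximum(r.sum(axis=1), 5 - r.sum(axis=1))
        assert out["full_consensus"] == pytest.approx(np.mean(maj == 5))
        assert out["four_agree"] == pytest.approx(np.mean(maj == 4))
        assert out["three_vs_two"] == pytest.approx(np.mean(maj == 3))
        assert sum(out.values()) == pytest.approx(1.0)


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        assert vt.cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0
        assert vt.cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0  # degenerate marginals

    def test_perfect_disagreement(self):
        assert vt.cohen_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)

    def test_hand_computed_2x2_table(self):
        # a=b=1: 45, a=1 b=0: 5, a=0 b=1: 15, a=b=0: 35
        a = [1] * 45 + [1] * 5 + [0] * 15 + [0] * 35
        b = [1] * 45 + [0] * 5 + [1] * 15 + [0] * 35
        p_o = 0.80
        pa1, pb1 = 0.50, 0.60
        p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
        assert vt.cohen_kappa(a, b) == pytest.approx((p_o - p_e) / (1 - p_e))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.uniform(size=60) < 0.4).astype(int)
        b = np.where(rng.uniform(size=60) < 0.3, 1 - a, a)
        assert vt.cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
        assert vt.cohen_kappa(b, a) == pytest.approx(vt.cohen_kappa(a, b), abs=1e-12)
        assert -1.0 <= vt.cohen_kappa(a, b) <= 1.0

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=40))
    def test_kappa_bounded_and_symmetric(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        k = vt.cohen_kappa(a, b)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        assert vt.cohen_kappa(b, a) == pytest.approx(k, abs=1e-12)
        assert vt.cohen_kappa(a, a) == 1.0

    def test_kappa_table_shape(self):
        rng = np.random.default_rng(1)
        r = (rng.uniform(size=(40, 5)) < 0.3).astype(int)
        ratings = vt.RatingSet(tuple(f"r{i}" for i in range(40)), r)
        table = vt.kappa_table(ratings)
        assert table.shape == (5, 6)
        assert np.isnan(table.loc["E3", "E2"])  # lower triangle left empty
        assert table.loc["E1", "Rc"] == pytest.approx(
            vt.cohen_kappa(r[:, 0], ratings.consensus))


class TestMCCV:
    def test_splits_disjoint_covering_stratified(self):
        labels = np.array([1] * 59 + [0] * 141)
        rng = np.random.default_rng(0)
        rng.shuffle(labels)
        splits = vt.mccv_split(labels, n_splits=10, train_fraction=0.5, seed=4)
        assert len(splits) == 10
        n_pos = labels.sum()
        for tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == len(labels)
            train_pos_frac = labels[tr].sum() / len(tr)
            assert abs(labels[tr].sum() - n_pos * len(tr) / len(labels)) <= 1.0
            assert 0 < train_pos_frac < 1

    def test_reproducible_by_seed(self):
        labels = np.array([0, 1] * 10)
        a = vt.mccv_split(labels, n_splits=3, seed=11)
        b = vt.mccv_split(labels, n_splits=3, seed=11)
        for (t1, e1), (t2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_small_balanced_cohort_counts(self):
        labels = np.array([0] * 5 + [1] * 5)
        for tr, te in vt.mccv_split(labels, n_splits=5, train_fraction=0.5, seed=0):
            assert len(tr) == 5
            assert labels[tr].sum() in (2, 3)

    def test_error_cases(self):
        with pytest.raises(UndefinedStatisticError):
            vt.mccv_split(np.ones(10, dtype=int))
        with pytest.raises(UndefinedStatisticError):
            vt.mccv_split(np.array([0] + [1] * 9))
        with pytest.raises(ContractViolationError):
            vt.mccv_split(np.array([0, 1] * 5), train_fraction=1.5)


@pytest.fixture(scope="module")
def cohort():
    cfg = vt.GeneratorConfig(n_retinas=40)
    samples = vt.generate_cohort(cfg, seed=5)
    labels, _ = vt.generate_labels(samples, cfg)
    return samples, labels


class TestExperimentHarness:

    def test_baseline_variant_runs_without_optimizer(self, cohort):
        samples, labels = cohort
        res = vt.experiment_run(samples, labels, "baseline", n_splits=3, seed=1)
        assert len(res.train_aucs) == len(res.test_aucs) == 3
        assert all(0.0 <= a <= 1.0 for a in res.train_aucs + res.test_aucs)
        frame = res.to_frame()
        assert len(frame) == 6
        assert set(frame["stage"]) == {"train", "test"}

    def test_proposed_variant_beats_chance_on_planted_labels(self, cohort):
        samples, labels = cohort
        res = vt.experiment_run(
            samples, labels, "proposed", n_splits=2, seed=1,
            nsga_params=vt.NSGAParams(pop_size=24, generations=15),
        )
        assert res.mean_test_auc > 0.6

    def test_unknown_variant_rejected(self, cohort):
        samples, labels = cohort
        with pytest.raises(ContractViolationError):
            vt.experiment_run(samples, labels, "everything_only")

    def test_vessel_restricted_variant_drops_other_class(self, cohort):
        samples, labels = cohort
        feats = vt.CohortFeatures.from_cohort(samples, vessel_class=vt.ARTERY)
        total = sum(len(s.vessels) for s in samples)
        n_arteries = sum(
            1 for s in samples for v in s.vessels if v.av_class == vt.ARTERY)
        assert feats.tau_g.size == n_arteries < total
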