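"""Stratification, LASSO discriminators, LOOCV, enumeration, cascade objects."""

import itertools

import numpy as np
import pandas as pd
import pytest

import loopwalk.cascade as lc
from loopwalk.cascade import (
    CandidateRanking,
    DiscriminationModel,
    StratificationConfig,
    ThermostabilityCascade,
    enumerate_candidate_triples,
    extract_weight_table,
    fit_lasso_discriminator,
    loocv,
    rank_stage2,
    screen_stage1,
    select_top_candidates,
    stratify_by_tertiles,
)
from loopwalk.descriptors import ScalerParams
from loopwalk.simulate import GenerativeConfig, default_true_weights, generate_screen


def identity_scaler(n: int) -> ScalerParams:
    return ScalerParams(np.zeros(n), np.ones(n), np.zeros(n, bool))


def constant_model(weights, intercept, positive="improved", negative="non-improved"):
    w = np.asarray(weights, float)
    return DiscriminationModel(
        contrast="improved_vs_nonimproved",
        positive_label=positive,
        negative_label=negative,
        weights=w,
        intercept=float(intercept),
        regularization_strength=1.0,
        scaler=identity_scaler(w.shape[0]),
    )


class TestStratification:
    def test_214_with_34pct_tails_gives_73_73_68(self, rng):
        labels = stratify_by_tertiles(rng.normal(size=214))
        counts = pd.Series(labels).value_counts()
        assert counts["high"] == 73
        assert counts["low"] == 73
        assert counts["medium"] == 68  # the quota arithmetic, reported as computed
        assert counts.sum() == 214

    def test_exact_thirds(self):
        labels = stratify_by_tertiles(range(9), StratificationConfig(1 / 3, 1 / 3))
        counts = pd.Series(labels).value_counts()
        assert counts.to_dict() == {"high": 3, "medium": 3, "low": 3}

    def test_total_ties_fill_quotas_in_input_order(self):
        """Under a full tie the quota rule resolves by stable input order."""
        n = 10
        labels = stratify_by_tertiles([1.0] * n, StratificationConfig(0.3, 0.3))
        n_high, n_low = 3, 3
        expected = ["high"] * n_high + ["medium"] * (n - 6) + ["low"] * n_low
        assert labels.tolist() == expected

    def test_descending_rank_semantics(self):
        labels = stratify_by_tertiles([5.0, 1.0, 3.0], StratificationConfig(1 / 3, 1 / 3))
        assert labels.tolist() == ["high", "low", "medium"]

    def test_tail_quota_overflow_rejected(self):
        # ceil can push the two 34% tails past a tiny n
        with pytest.raises(ValueError, match="quotas exceed"):
            stratify_by_tertiles([5.0, 1.0, 3.0], StratificationConfig(0.34, 0.34))

    def test_fractions_summing_to_one_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            StratificationConfig(0.5, 0.5)


class TestLassoDiscriminator:
    def test_separable_clusters_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 1, (20, 5)), rng.normal(3, 1, (20, 5))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        m = fit_lasso_discriminator(X, y, positive_label="pos", lambda_policy="fixed:0.01")
        assert (m.predict_label(X) == y).all()

    def test_overwhelming_penalty_kills_all_weights(self, rng):
        """lambda -> large: sparse limit is the majority-class constant model."""
        X = rng.normal(size=(40, 6))
        y = np.array(["a"] * 30 + ["b"] * 10)
        m = fit_lasso_discriminator(X, y, positive_label="b", lambda_policy="fixed:1000")
        assert np.all(m.weights == 0.0)
        p = m.predict_proba(X)
        assert np.allclose(p, p[0])  # constant classifier
        assert p[0] == pytest.approx(10 / 40, abs=0.05)  # majority log-odds limit
        assert (m.predict_label(X) == "a").all()

    def test_sign_recovery_on_synthetic_screen(self, table):
        """The stage-1 fit recovers the generator's five weight signs."""
        screen = generate_screen(GenerativeConfig(seed=11), table)
        model = ThermostabilityCascade.from_screen(screen.records, table)
        results = model.fit(seed=11, run_loocv=False)
        w_true = default_true_weights(table)
        nz = np.flatnonzero(w_true)
        assert np.array_equal(
            np.sign(results.stage1.weights[nz]), np.sign(w_true[nz])
        )

    def test_label_flip_negates_model(self, rng):
        X = rng.normal(size=(60, 8))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 60) > 0, "hi", "lo")
        m_hi = fit_lasso_discriminator(X, y, positive_label="hi", lambda_policy="fixed:1")
        m_lo = fit_lasso_discriminator(X, y, positive_label="lo", lambda_policy="fixed:1")
        np.testing.assert_allclose(m_hi.weights, -m_lo.weights, atol=1e-5)
        assert m_hi.intercept == pytest.approx(-m_lo.intercept, abs=1e-5)
        np.testing.assert_allclose(
            m_hi.predict_proba(X), 1.0 - m_lo.predict_proba(X), atol=1e-5
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_lasso_discriminator(
                rng.normal(size=(10, 3)), ["a"] * 10, positive_label="a"
            )

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="finite"):
            fit_lasso_discriminator(X, ["a", "b"], positive_label="a")


class TestLoocv:
    def test_separable_data_scores_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 1, (10, 4)), rng.normal(3, 1, (10, 4))])
        y = np.array(["neg"] * 10 + ["pos"] * 10)
        rep = loocv(
            X, y, lambda Xt, yt: fit_lasso_discriminator(
                Xt, yt, positive_label="pos", lambda_policy="fixed:1"
            )
        )
        assert rep.accuracy == 1.0
        assert rep.n == 20

    def test_single_planted_mislabel_costs_exactly_one_fold(self, rng):
        X = np.vstack([rng.normal(-3, 1, (25, 4)), rng.normal(3, 1, (25, 4))])
        y = np.array(["neg"] * 25 + ["pos"] * 25)
        y[7] = "pos"  # plant one mislabel in otherwise separable data
        rep = loocv(
            X, y, lambda Xt, yt: fit_lasso_discriminator(
                Xt, yt, positive_label="pos", lambda_policy="fixed:1"
            )
        )
        assert rep.accuracy == pytest.approx(49 / 50)
        wrong = rep.per_sample[rep.per_sample["true"] != rep.per_sample["predicted"]]
        assert wrong.index.tolist() == [7]

    def test_singleton_class_fold_flagged_and_majority_predicted(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array(["a", "a", "a", "a", "a", "b"])
        rep = loocv(
            X, y, lambda Xt, yt: fit_lasso_discriminator(
                Xt, yt, positive_label="b", lambda_policy="fixed:1"
            )
        )
        flagged = rep.per_sample[rep.per_sample["degenerate_fold"]]
        assert flagged.index.tolist() == [5]
        assert flagged["predicted"].tolist() == ["a"]


class TestEnumeration:
    def test_full_space_and_observed_removal(self):
        assert len(enumerate_candidate_triples([])) == 8000
        observed = set()
        for t in itertools.product("ARNDCQEGHILKMFPSTWY", repeat=3):
            observed.add("".join(t))
            if len(observed) == 214:
                break
        remaining = enumerate_candidate_triples(observed)
        assert len(remaining) == 7786
        assert not observed & set(remaining)

    def test_observed_equals_space_leaves_nothing(self):
        full = enumerate_candidate_triples([])
        assert enumerate_candidate_triples(full) == []

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="invalid residue triple"):
            enumerate_candidate_triples(["PXV"])

    def test_reduced_alphabet_matches_bruteforce_loops(self):
        alphabet = "ARND"
        observed = ["AAA", "RND", "DDD"]
        expected = []
        for a in alphabet:
            for b in alphabet:
                for c in alphabet:
                    t = a + b + c
                    if t not in observed:
                        expected.append(t)
        assert len(expected) == 4 ** 3 - 3
        assert enumerate_candidate_triples(observed, alphabet) == expected


class TestStageScreening:
    def test_constant_optimist_keeps_all(self):
        m = constant_model(np.zeros(2), intercept=1.0)
        cands = ["AAA", "RRR", "NNN"]
        kept, p = screen_stage1(m, cands, np.zeros((3, 2)))
        assert kept == cands
        assert np.all(p > 0.5)

    def test_constant_pessimist_keeps_none(self):
        m = constant_model(np.zeros(2), intercept=-1.0)
        kept, p = screen_stage1(m, ["AAA"], np.zeros((1, 2)))
        assert kept == []

    def test_raising_positive_feature_never_drops_a_kept_candidate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.normal(size=5)
            m = constant_model(w, intercept=rng.normal())
            X = rng.normal(size=(30, 5))
            kept_before, _ = screen_stage1(m, list(range(30)), X)
            j = int(rng.integers(5))
            X2 = X.copy()
            X2[:, j] += abs(rng.normal()) * np.sign(w[j]) if w[j] != 0 else 0.0
            kept_after, _ = screen_stage1(m, list(range(30)), X2)
            assert set(kept_before) <= set(kept_after)

    def test_dimension_mismatch_rejected(self):
        m = constant_model(np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            screen_stage1(m, ["AAA"], np.zeros((1, 5)))


class TestRanking:
    def test_orders_by_probability(self):
        m = constant_model([1.0], 0.0, positive="high", negative="medium")
        # logit(0.9) and logit(0.3) as single-feature values
        X = np.array([[np.log(0.3 / 0.7)], [np.log(0.9 / 0.1)]])
        ranking = rank_stage2(m, ["RRR", "AAA"], X)
        assert ranking.entries["triple"].tolist() == ["AAA", "RRR"]
        assert ranking.entries["rank"].tolist() == [1, 2]
        assert ranking.entries["p_high"].iloc[0] == pytest.approx(0.9)

    def test_exact_ties_break_lexicographically_in_alphabet_order(self):
        m = constant_model(np.zeros(1), 0.0, positive="high", negative="medium")
        cands = ["VVV", "AAA", "RND"]  # all p = 0.5
        ranking = rank_stage2(m, cands, np.zeros((3, 1)))
        assert ranking.entries["triple"].tolist() == ["AAA", "RND", "VVV"]

    def test_empty_candidates_valid(self):
        m = constant_model(np.zeros(1), 0.0)
        ranking = rank_stage2(m, [], np.zeros((0, 1)))
        assert len(ranking) == 0

    def test_duplicate_candidates_rejected(self):
        m = constant_model(np.zeros(1), 0.0)
        with pytest.raises(ValueError, match="unique"):
            rank_stage2(m, ["AAA", "AAA"], np.zeros((2, 1)))


def _ranking_from_probs(probs):
    triples = [
        "".join(t) for t in itertools.islice(itertools.product("ARNDCQEGHILKMFPSTWYV", repeat=3), len(probs))
    ]
    order = np.argsort(-np.asarray(probs), kind="stable")
    entries = pd.DataFrame(
        {
            "rank": np.arange(1, len(probs) + 1),
            "triple": [triples[i] for i in order],
            "p_high": np.asarray(probs)[order],
            "p_improved": np.ones(len(probs)),
        }
    )
    return CandidateRanking(entries=entries)


class TestSelection:
    def test_quota_shortfall_returns_available_with_warning(self):
        probs = list(np.linspace(0.95, 0.55, 25)) + list(np.linspace(0.45, 0.1, 15))
        ranking = _ranking_from_probs(probs)
        with pytest.warns(UserWarning, match="shortfall"):
            high, medium = select_top_candidates(ranking, 20, 20)
        assert len(high) == 20
        assert len(medium) == 15
        assert set(high["triple"]).isdisjoint(medium["triple"])

    def test_zero_high_quota(self):
        ranking = _ranking_from_probs([0.9, 0.4])
        high, medium = select_top_candidates(ranking, 0, 1)
        assert len(high) == 0
        assert medium["p_high"].tolist() == [0.4]

    def test_disjointness_over_random_rankings(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            ranking = _ranking_from_probs(rng.uniform(0, 1, size=rng.integers(1, 60)))
            n_h, n_m = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                high, medium = select_top_candidates(ranking, n_h, n_m)
            assert set(high["triple"]).isdisjoint(medium["triple"])
            assert (medium["p_high"] <= 0.5).all()


class TestWeightTable:
    # a published-style sparse weight table for the three loop positions:
    # rows follow the packaged descriptor order, columns the loop positions
    FIXTURE = np.array(
        [
            [-0.270, -0.002, 0.0],
            [-0.102, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [-0.066, 0.0, -0.100],
            [-0.348, 0.0, 0.0],
            [0.0, 0.0, -0.219],
            [0.0, 0.0, -0.027],
            [0.023, 0.0, 0.0],
            [-0.196, 0.047, 0.043],
            [0.0, 0.0, 0.0],
            [0.129, -0.041, 0.0],
            [0.0, 0.084, 0.0],
            [0.0, 0.013, 0.0],
        ]
    )

    def _model(self, mat):
        weights = mat.T.reshape(-1)  # position-major layout
        return constant_model(weights, 0.0, positive="high", negative="medium")

    def test_fixture_cells_recovered(self, table):
        wt = extract_weight_table(
            self._model(self.FIXTURE), table.descriptor_ids, ("233", "234", "235")
        )
        np.testing.assert_array_equal(wt.to_numpy(), self.FIXTURE)
        assert wt.loc["sidechain_stability", "233"] == pytest.approx(-0.348)
        assert wt.loc["polarity", "233"] == pytest.approx(0.129)

    def test_all_zero_model(self, table):
        wt = extract_weight_table(self._model(np.zeros((13, 3))), table.descriptor_ids)
        assert (wt.to_numpy() == 0).all()

    def test_reshape_roundtrip(self, table):
        m = self._model(self.FIXTURE)
        wt = extract_weight_table(m, table.descriptor_ids)
        np.testing.assert_array_equal(wt.to_numpy().T.reshape(-1), m.weights)

    def test_dimension_mismatch_rejected(self, table):
        with pytest.raises(ValueError, match="expected"):
            extract_weight_table(constant_model(np.zeros(12), 0.0), table.descriptor_ids)


@pytest.fixture(scope="module")
def small_results(table):
    screen = generate_screen(GenerativeConfig(n_mutants=60, seed=5), table)
    model = ThermostabilityCascade.from_screen(screen.records, table)
    return model, model.fit(seed=5, run_loocv=False)


class TestCascadeObjects:
    def test_conservation_through_cascade(self, small_results):
        model, results = small_results
        candidates = enumerate_candidate_triples(set(model.triples))
        ranking = results.rank_candidates()
        from loopwalk.descriptors import encode_library

        feats = encode_library(candidates, model.descriptor_table).to_numpy()
        kept, p = screen_stage1(results.stage1, candidates, feats)
        assert len(kept) + int((p <= 0.5).sum()) == len(candidates)
        assert len(ranking) == len(kept)
        assert ranking.entries["triple"].is_unique
        assert set(ranking.entries["triple"]) == set(kept)

    def test_refit_is_bit_reproducible(self, small_results, table):
        model, results = small_results
        screen = generate_screen(GenerativeConfig(n_mutants=60, seed=5), table)
        model2 = ThermostabilityCascade.from_screen(screen.records, table)
        results2 = model2.fit(seed=5, run_loocv=False)
        np.testing.assert_array_equal(results.stage1.weights, results2.stage1.weights)
        np.testing.assert_array_equal(results.stage2.weights, results2.stage2.weights)
        pd.testing.assert_frame_equal(
            results.rank_candidates().entries, results2.rank_candidates().entries
        )

    def test_conflicting_duplicate_activities_rejected(self, table):
        with pytest.raises(ValueError, match="two different activities"):
            ThermostabilityCascade(["AAA", "AAA", "RRR"], [1.0, 2.0, 3.0], table)

    def test_summary_mentions_counts_and_accuracy(self, table):
        screen = generate_screen(GenerativeConfig(n_mutants=45, seed=3), table)
        model = ThermostabilityCascade.from_screen(screen.records, table)
        results = model.fit(seed=3, run_loocv=False)
        text = results.summary()
        assert "label counts" in text
        assert "stage 2 (high vs medium)" in text

    def test_weight_table_matches_stage2_vector(self, small_results):
        _, results = small_results
        wt = results.weight_table()
        np.testing.assert_array_equal(
            wt.to_numpy().T.reshape(-1), results.stage2.weights
        )
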