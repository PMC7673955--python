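"""Feature ranking (gain / ANOVA F) and the incremental selection loop."""

import numpy as np
import pandas as pd
import pytest

from succsite.evaluation import default_classifier
from succsite.selection import (IFSCurve, RankedFeatureList, pick_optimum,
                                rank_by_anova, rank_by_gain, run_ifs)


def _planted(n=500, n_noise=40, seed=0):
    """Feature 0 equals the label exactly; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] = y
    return X, y


class TestRankByGain:
    def test_planted_feature_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(20):
            X, y = _planted(seed=seed)
            ranked = rank_by_gain(X, y, seed=0)
            hits += ranked.names[0] == "f0"
        assert hits >= 19

    def test_constant_features_tie_break_by_original_index(self):
        X = np.ones((40, 5))
        y = np.repeat([0, 1], 20)
        ranked = rank_by_gain(X, y)
        assert ranked.names == ("f0", "f1", "f2", "f3", "f4")
        assert all(s == 0 for s in ranked.scores)

    def test_column_permutation_permutes_names_not_scores(self):
        X, y = _planted(n=300, n_noise=6, seed=1)
        cols = [f"f{i}" for i in range(7)]
        df = pd.DataFrame(X, columns=cols)
        ranked = rank_by_gain(df, y, seed=0)
        perm = ["f3", "f0", "f5", "f1", "f6", "f2", "f4"]
        ranked_perm = rank_by_gain(df[perm], y, seed=0)
        score_of = dict(zip(ranked.names, ranked.scores))
        score_of_perm = dict(zip(ranked_perm.names, ranked_perm.scores))
        assert score_of.keys() == score_of_perm.keys()
        for name in score_of:
            assert score_of[name] == pytest.approx(score_of_perm[name], rel=1e-9)

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        with pytest.raises(ValueError, match="single class"):
            rank_by_gain(X, np.zeros(30, dtype=int))


class TestRankByAnova:
    def test_separated_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        X = rng.normal(size=(200, 10))
        X[y == 1, 4] += 5.0
        assert rank_by_anova(X, y).names[0] == "f4"

    def test_identical_class_means_do_not_crash(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = np.repeat([0, 1], 50)
        ranked = rank_by_anova(X, y)
        assert len(ranked) == 5
        assert all(np.isfinite(ranked.scores))

    def test_matches_hand_arithmetic_on_toy_set(self):
        # groups [1,2,3] vs [4,5,6]: SSB=13.5 (df 1), SSW=4 (df 4) -> F=13.5
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        ranked = rank_by_anova(X, y)
        assert ranked.scores[0] == pytest.approx(13.5)

    def test_zero_within_variance_is_infinite_f_ranked_first(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        X[:, 2] = y  # perfectly separated, zero within-group variance
        ranked = rank_by_anova(X, y)
        assert ranked.names[0] == "f2" and ranked.scores[0] == np.inf

    def test_agrees_with_exhaustive_f_on_small_data(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 6))
        y = np.repeat([0, 1], 15)
        ranked = rank_by_anova(X, y)
        score_of = dict(zip(ranked.names, ranked.scores))
        for j in range(6):
            expected = f_oneway(X[y == 0, j], X[y == 1, j]).statistic
            assert score_of[f"f{j}"] == pytest.approx(expected)


class TestRankedFeatureList:
    def test_scores_must_be_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            RankedFeatureList(("a", "b"), (0.1, 0.5), "gain")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedFeatureList(("a", "a"), (1.0, 0.5), "gain")


def _ifs_data(n=160, seed=0):
    """Five informative features (shifted class means), 15 noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 20))
    X[y == 1, :5] += 2.5
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(20)]), y


class TestRunIFS:
    def test_optimum_found_among_informative_features(self):
        X, y = _ifs_data()
        ranked = rank_by_anova(X, y)
        assert set(ranked.names[:5]) == {f"f{i}" for i in range(5)}
        curve = run_ifs(ranked, X, y, k=4, seed=0, max_size=10,
                        classifier=default_classifier(n_estimators=30))
        assert curve.optimum_size <= 10
        f = curve.fitness_values
        assert f[4] >= f[0]  # adding informative features never hurts here

    def test_tie_resolves_to_fewer_features(self):
        assert pick_optimum((0.6, 0.7, 0.7)) == 1
        assert pick_optimum((0.5,)) == 0

    def test_sizes_follow_step_and_max_size(self):
        X, y = _ifs_data(n=80, seed=1)
        ranked = rank_by_anova(X, y)
        curve = run_ifs(ranked, X, y, k=4, seed=0, max_size=3,
                        classifier=default_classifier(n_estimators=10))
        assert curve.sizes == (1, 2, 3)

    def test_max_size_clipped_with_warning(self):
        X, y = _ifs_data(n=80, seed=2)
        ranked = rank_by_anova(X.iloc[:, :4], y)
        with pytest.warns(UserWarning, match="clipping"):
            curve = run_ifs(ranked, X, y, k=4, seed=0, max_size=99,
                            classifier=default_classifier(n_estimators=10))
        assert curve.sizes[-1] == 4

    def test_reproducible_and_consistent_with_direct_cv(self):
        from succsite.evaluation import cross_validate
        X, y = _ifs_data(n=120, seed=3)
        ranked = rank_by_anova(X, y)
        clf = default_classifier(n_estimators=20)
        kwargs = dict(k=4, seed=5, max_size=6, classifier=clf)
        a = run_ifs(ranked, X, y, **kwargs)
        b = run_ifs(ranked, X, y, **kwargs)
        assert a.fitness_values == b.fitness_values
        assert a.optimum_size == b.optimum_size
        # re-evaluating the optimum subset from scratch reproduces its bundle
        cols = list(ranked.top(a.optimum_size))
        res = cross_validate(X[cols].to_numpy(), y, classifier=clf, k=4, seed=5)
        assert res.pooled == a.optimum_bundle

    def test_curve_tsv_round_trip(self, tmp_path):
        X, y = _ifs_data(n=80, seed=4)
        ranked = rank_by_anova(X, y)
        curve = run_ifs(ranked, X, y, k=4, seed=0, max_size=2,
                        classifier=default_classifier(n_estimators=10))
        path = tmp_path / "curve.tsv"
        curve.write_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["n_features", "ACC", "Recall",
                                      "Precision", "MCC", "F-measure"]
        assert len(back) == 2
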