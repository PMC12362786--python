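"""Feature assembly, SMOTE geometry, ensemble training and vote scoring."""

import numpy as np
import pandas as pd
import pytest

from deafscape.exceptions import (ConsistencyError, InvalidConfigError,
                                  InvalidInputError)
from deafscape.prioritize import (FeatureMatrix, PrioritizerConfig,
                                  correlation_features, curate_label_sets,
                                  feature_importance, fit_ensemble,
                                  intersect_with_phenotype,
                                  partition_negatives, score_genes,
                                  smote_oversample, train_and_evaluate)
from deafscape.simulate import FeatureSimConfig, gen_feature_matrix

SMALL_CFG = PrioritizerConfig(k_subsets=5, n_trees=30)


def small_features(seed=0, hidden=0.0):
    return gen_feature_matrix(FeatureSimConfig(
        n_positive=30, n_negative=120, n_expression_features=8,
        n_correlation_features=6, n_binary_features=4, effect_size=2.0,
        informative_fraction=0.5, hidden_positive_fraction=hidden, seed=seed))


class TestCorrelationFeatures:
    def test_self_orthogonal_and_planted(self, rng):
        n_cond = 20
        base = rng.normal(size=n_cond)
        ortho = np.zeros(n_cond)
        ortho[:2] = [1.0, -1.0]
        ortho -= ortho.mean()
        basec = base - base.mean()
        ortho -= basec * (ortho @ basec) / (basec @ basec)  # exactly r=0
        expr = pd.DataFrame([base, base, ortho + 5],
                            index=["pos1", "cand_same", "cand_orth"])
        out = correlation_features(expr, ["pos1"])
        assert out.loc["cand_same", "corr_pos1"] == pytest.approx(1.0)
        assert out.loc["cand_orth", "corr_pos1"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)), index=["p", "a", "b"])
        expr.loc["b"] = 7.0
        out = correlation_features(expr, ["p"])
        assert out.loc["b", "corr_p"] == 0.0
        assert out.attrs["zero_variance_genes"] == ["b"]

    def test_planted_pairwise_correlation_recovered(self, rng):
        n_cond, r = 20, 0.6
        pos = rng.normal(size=n_cond)
        feats = []
        for _ in range(200):
            cand = r * (pos - pos.mean()) / pos.std() + \
                np.sqrt(1 - r**2) * rng.normal(size=n_cond)
            feats.append(cand)
        expr = pd.DataFrame([pos] + feats,
                            index=["p"] + [f"c{i}" for i in range(200)])
        out = correlation_features(expr, ["p"])
        assert out.drop(index="p")["corr_p"].mean() == pytest.approx(r, abs=0.1)


class TestLabelCuration:
    def test_set_arithmetic(self):
        genes = [f"g{i}" for i in range(10)]
        labels = curate_label_sets(genes, positive_list=["g0", "g1", "g2"],
                                   refuted_list=["g2"],
                                   minor_symptom_list=["g5", "g6"])
        assert list(labels[labels == "positive"].index) == ["g0", "g1"]
        assert set(labels[labels == "excluded"].index) == {"g2", "g5", "g6"}
        assert (labels == "negative").sum() == 5

    def test_empty_exclusions_complement(self):
        genes = ["a", "b", "c"]
        labels = curate_label_sets(genes, ["a"])
        assert set(labels[labels == "negative"].index) == {"b", "c"}

    def test_positive_minor_overlap_kept_positive(self):
        with pytest.warns(UserWarning):
            labels = curate_label_sets(["a", "b"], ["a"],
                                       minor_symptom_list=["a"])
        assert labels["a"] == "positive"


class TestPartition:
    def test_even_split(self):
        parts = partition_negatives([f"g{i}" for i in range(100)], k=10, seed=0)
        assert all(len(p) == 10 for p in parts)

    def test_remainder_split_and_coverage(self):
        genes = [f"g{i}" for i in range(103)]
        parts = partition_negatives(genes, k=10, seed=0)
        assert sorted(len(p) for p in parts) == [10] * 7 + [11] * 3
        union = [g for p in parts for g in p]
        assert sorted(union) == sorted(genes)
        assert len(set(union)) == len(genes)

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(37)]
        assert partition_negatives(genes, k=5, seed=3) == \
            partition_negatives(genes, k=5, seed=3)

    def test_invalid_k(self):
        with pytest.raises(InvalidConfigError):
            partition_negatives(["a", "b", "c"], k=1)


class TestSmote:
    def test_identical_rows_degenerate(self):
        rows = np.array([[1.0, 2.0], [1.0, 2.0]])
        synth = smote_oversample(rows, 10, k_neighbors=1, seed=0)
        assert np.allclose(synth, [1.0, 2.0])

    def test_convexity_one_dim(self):
        rows = np.array([[0.0], [1.0]])
        synth = smote_oversample(rows, 50, k_neighbors=1, seed=0)
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_rows_lie_on_knn_segments_brute_force(self, rng):
        """Geometric oracle: every synthetic row is on a segment between a
        minority row and one of its k nearest neighbors (brute-force kNN)."""
        X = rng.normal(size=(15, 4))
        k = 3
        synth = smote_oversample(X, 60, k_neighbors=k, seed=1)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        knn = np.argsort(d2, axis=1)[:, :k]
        for s in synth:
            on_segment = False
            for i in range(len(X)):
                for j in knn[i]:
                    seg = X[j] - X[i]
                    denom = seg @ seg
                    u = 0.0 if denom == 0 else (s - X[i]) @ seg / denom
                    if -1e-9 <= u <= 1 + 1e-9 and \
                            np.allclose(X[i] + u * seg, s, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_binary_rethresholding(self, rng):
        X = rng.random((10, 3))
        X[:, 2] = (X[:, 2] > 0.5).astype(float)
        synth = smote_oversample(X, 40, seed=2,
                                 binary_mask=np.array([False, False, True]))
        assert np.isin(synth[:, 2], (0.0, 1.0)).all()

    def test_k_reduction_and_tiny_minority(self):
        with pytest.warns(UserWarning):
            smote_oversample(np.eye(3), 5, k_neighbors=5, seed=0)
        with pytest.raises(InvalidInputError):
            smote_oversample(np.zeros((1, 2)), 5)


class TestTraining:
    def test_no_signal_f1_near_base_rate(self):
        feats = gen_feature_matrix(FeatureSimConfig(
            n_positive=40, n_negative=160, n_expression_features=10,
            n_correlation_features=0, n_binary_features=0,
            effect_size=0.0, seed=5))
        X = feats.values.to_numpy()
        y = (feats.labels == "positive").astype(int).to_numpy()
        f1s = [train_and_evaluate(X, y, list(feats.values.index),
                                  config=PrioritizerConfig(n_trees=50),
                                  seed=s).metrics.f1 for s in range(5)]
        assert np.mean(f1s) < 0.55  # no better than chance-level trading

    def test_deterministic_metrics(self):
        feats = small_features(seed=2)
        X = feats.values.to_numpy()
        y = (feats.labels == "positive").astype(int).to_numpy()
        a = train_and_evaluate(X, y, list(feats.values.index),
                               config=SMALL_CFG, seed=11)
        b = train_and_evaluate(X, y, list(feats.values.index),
                               config=SMALL_CFG, seed=11)
        assert a.metrics == b.metrics

    def test_smote_restricted_to_training_fold(self):
        """No synthetic row coincides with a test-fold row, and all synthetic
        rows sit inside the bounding box of the training-fold positives."""
        feats = small_features(seed=3)
        X = feats.values.to_numpy()
        y = (feats.labels == "positive").astype(int).to_numpy()
        genes = list(feats.values.index)
        res = train_and_evaluate(X, y, genes, config=SMALL_CFG, seed=4)
        test_rows = X[[genes.index(g) for g in res.test_genes]]
        for s in res.synthetic_rows:
            assert not (np.isclose(test_rows, s).all(axis=1)).any()
        train_pos = X[[genes.index(g) for g in res.train_genes
                       if y[genes.index(g)] == 1]]
        lo, hi = train_pos.min(0), train_pos.max(0)
        assert (res.synthetic_rows >= lo - 1e-9).all()
        assert (res.synthetic_rows <= hi + 1e-9).all()


class TestEnsemble:
    def test_votes_bounded_and_conserved(self):
        feats = small_features(seed=7)
        res = fit_ensemble(feats, config=SMALL_CFG, seed=1)
        k = SMALL_CFG.k_subsets
        assert len(res.scores) == 120
        hist = np.bincount([s.votes for s in res.scores], minlength=k)
        assert hist.sum() == 120
        for s in res.scores:
            assert 0 <= s.votes <= k - 1
            assert s.per_model_prediction.count("not_applicable") == 1
            assert s.votes == s.per_model_prediction.count("positive")

    def test_partition_mismatch_detected(self):
        feats = small_features(seed=7)
        res = fit_ensemble(feats, config=SMALL_CFG, seed=1)
        broken = [list(p) for p in res.partition]
        broken[0] = broken[0][:-1]
        with pytest.raises(ConsistencyError):
            score_genes(res.models, feats, broken)

    def test_importance_normalization_and_rollup(self):
        feats = small_features(seed=8)
        res = fit_ensemble(feats, config=SMALL_CFG, seed=2)
        for m in res.models:
            assert m.classifier.feature_importances_.sum() == pytest.approx(1.0)
        assert res.importance_by_block.sum() == pytest.approx(1.0)
        assert set(res.importance_by_block.index) <= {"expression",
                                                      "correlation", "binary"}

    def test_informative_features_outrank_noise(self):
        ranked_noise_low = 0
        for seed in range(10):
            feats = gen_feature_matrix(FeatureSimConfig(
                n_positive=40, n_negative=160, n_expression_features=10,
                n_correlation_features=0, n_binary_features=0,
                effect_size=2.0, informative_fraction=0.5, seed=seed))
            res = fit_ensemble(feats, config=SMALL_CFG, seed=seed)
            imp = res.importance.set_index("feature")["importance"]
            informative = [f"expr_{j + 1:03d}" for j in range(5)]
            noise = [f"expr_{j + 1:03d}" for j in range(5, 10)]
            if imp[informative].min() > imp[noise].max():
                ranked_noise_low += 1
        assert ranked_noise_low >= 9

    def test_phenotype_intersection(self):
        feats = small_features(seed=9)
        res = fit_ensemble(feats, config=SMALL_CFG, seed=3)
        top = [s.gene for s in res.scores if s.votes == SMALL_CFG.k_subsets - 1]
        supported, unsupported = intersect_with_phenotype(res.scores, top[:1])
        assert set(supported) | set(unsupported) == set(top)
        assert supported == top[:1]

    def test_phenotype_empty_set(self):
        feats = small_features(seed=9)
        res = fit_ensemble(feats, config=SMALL_CFG, seed=3)
        supported, _ = intersect_with_phenotype(res.scores, [])
        assert supported == []
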