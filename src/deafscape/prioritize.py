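"""Ensemble gene prioritization for an imbalanced positive class.

The procedure: assemble a per-gene feature matrix (expression levels,
correlations with the known disease genes, binary GO/pathway flags), curate
positive and negative label sets, split the negatives into ten disjoint
subsets, pair each subset with all positives, oversample the positive class
with SMOTE inside the training fold only, train one random-forest classifier
per subset, and score every negative gene by the number of positive votes it
receives from the nine models whose training subset excluded it (0-9).
Genes with the maximum score are candidates; intersecting them with an
external phenotype gene set yields the supported short list.

SMOTE is implemented here directly (each synthetic row is x + u * (nn - x)
for a uniform u and a k-nearest minority neighbor nn, with binary features
re-thresholded at 0.5); the random forest and nearest-neighbor searches use
scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConsistencyError, InvalidConfigError, InvalidInputError


@dataclass
class FeatureMatrix:
    """Genes x features with block structure and per-gene labels.

    ``blocks`` maps each feature name to one of ``expression``,
    ``correlation`` or ``binary``; ``labels`` holds ``positive`` /
    ``negative`` / ``excluded`` per gene.
    """

    values: pd.DataFrame
    labels: pd.Series
    blocks: dict
    hidden_positive_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise InvalidInputError("feature matrix contains missing values")
        binary_cols = [c for c, b in self.blocks.items() if b == "binary"]
        if binary_cols:
            vals = self.values[binary_cols].to_numpy()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise InvalidInputError("binary block must be 0/1")

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([self.blocks[c] == "binary" for c in self.values.columns])

    def genes_with_label(self, label: str) -> list:
        return list(self.labels.index[self.labels == label])


@dataclass
class ModelMetrics:
    model_index: int
    precision: float
    recall: float
    f1: float


@dataclass
class TrainedModel:
    model_index: int
    classifier: RandomForestClassifier
    metrics: ModelMetrics
    train_genes: list
    test_genes: list
    n_synthetic: int
    synthetic_rows: np.ndarray  # SMOTE output, for leakage auditing


@dataclass
class EnsembleScore:
    gene: str
    votes: int
    per_model_prediction: list  # "positive" / "negative" / "not_applicable"


# --------------------------------------------------------------------------
# feature assembly
# --------------------------------------------------------------------------

def correlation_features(expression: pd.DataFrame,
                         positive_genes: Sequence[str]) -> pd.DataFrame:
    """One feature per positive gene: Pearson r of expression vectors.

    ``expression`` is genes x conditions.  Zero-variance vectors get r = 0
    and are flagged in the returned frame's ``attrs['zero_variance_genes']``.
    """
    positives = [g for g in positive_genes if g in expression.index]
    if expression.shape[1] < 3:
        raise InvalidInputError("need >= 3 conditions for correlation features")
    X = expression.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flagged = list(expression.index[sd == 0])
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.where(sd > 0, np.sqrt((Xc ** 2).sum(axis=1)), 1.0)
    Xn = Xc / norm[:, None]
    pos_idx = [expression.index.get_loc(g) for g in positives]
    corr = Xn @ Xn[pos_idx].T
    corr[sd == 0, :] = 0.0
    for j, gi in enumerate(pos_idx):
        if sd[gi] == 0:
            corr[:, j] = 0.0
    out = pd.DataFrame(corr, index=expression.index,
                       columns=[f"corr_{g}" for g in positives])
    out.attrs["zero_variance_genes"] = flagged
    return out


def curate_label_sets(all_genes: Sequence[str],
                      positive_list: Sequence[str],
                      refuted_list: Sequence[str] = (),
                      minor_symptom_list: Sequence[str] = ()) -> pd.Series:
    """Label every gene positive / negative / excluded.

    Positives are the confirmed disease genes minus any refuted ones;
    refuted positives and genes carrying the phenotype only as a minor
    symptom are excluded from modeling; everything else is negative.
    A gene listed both positive and minor-symptom stays positive (warned).
    """
    all_set = list(dict.fromkeys(all_genes))
    pos = set(positive_list) & set(all_set)
    refuted = set(refuted_list)
    minor = set(minor_symptom_list)
    overlap = pos & minor
    if overlap:
        warnings.warn(f"{len(overlap)} genes in both positive and minor-symptom "
                      "lists; kept positive", stacklevel=2)
        minor -= pos
    labels = {}
    for g in all_set:
        if g in pos and g in refuted:
            labels[g] = "excluded"
        elif g in pos:
            labels[g] = "positive"
        elif g in minor or g in refuted:
            labels[g] = "excluded"
        else:
            labels[g] = "negative"
    return pd.Series(labels, name="label")


# --------------------------------------------------------------------------
# partition / SMOTE
# --------------------------------------------------------------------------

def partition_negatives(negative_genes: Sequence[str], k: int = 10,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None) -> list[list]:
    """Split the negatives into k disjoint subsets with sizes differing by <= 1."""
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    if len(negative_genes) < k:
        raise InvalidConfigError(f"{len(negative_genes)} negatives < k={k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(len(negative_genes))
    shuffled = [negative_genes[i] for i in order]
    return [list(part) for part in np.array_split(shuffled, k)]


def smote_oversample(minority: np.ndarray, n_synthetic: int,
                     k_neighbors: int = 5,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     binary_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Generate synthetic minority rows by segment interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with u ~ U[0, 1], x a
    uniformly chosen minority row and x_nn one of its k nearest minority
    neighbors (Euclidean).  Binary columns are re-thresholded at 0.5.
    """
    minority = np.asarray(minority, dtype=float)
    m = minority.shape[0]
    if m < 2:
        raise InvalidInputError("SMOTE needs at least 2 minority rows")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    if k_neighbors >= m:
        warnings.warn(f"reducing SMOTE k from {k_neighbors} to {m - 1}",
                      stacklevel=2)
        k_neighbors = m - 1
    if rng is None:
        rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, idx = nn.kneighbors(minority)
    neighbors = idx[:, 1:]  # drop self

    base = rng.integers(0, m, size=n_synthetic)
    pick = rng.integers(0, k_neighbors, size=n_synthetic)
    partner = neighbors[base, pick]
    u = rng.uniform(size=(n_synthetic, 1))
    synth = minority[base] + u * (minority[partner] - minority[base])
    if binary_mask is not None and binary_mask.any():
        synth[:, binary_mask] = (synth[:, binary_mask] > 0.5).astype(float)
    return synth


# --------------------------------------------------------------------------
# training / scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrioritizerConfig:
    k_subsets: int = 10
    test_fraction: float = 0.2
    smote_k: int = 5
    n_trees: int = 500
    max_features: str = "sqrt"


def train_and_evaluate(X: np.ndarray, y: np.ndarray,
                       genes: Sequence[str],
                       model_index: int = 0,
                       config: PrioritizerConfig = PrioritizerConfig(),
                       seed: Optional[int] = None,
                       binary_mask: Optional[np.ndarray] = None) -> TrainedModel:
    """Stratified split, SMOTE on the training fold only, random forest fit.

    Precision/recall/F1 are computed on the untouched test fold for the
    positive class.  The synthetic rows are retained on the result so tests
    can audit that no test-fold row served as an interpolation endpoint.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("dataset must contain both classes")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=y, random_state=seed)
    X_tr, y_tr = X[train_idx], y[train_idx]

    n_pos = int((y_tr == 1).sum())
    n_neg = int((y_tr == 0).sum())
    n_synth = max(0, n_neg - n_pos)
    synth = smote_oversample(X_tr[y_tr == 1], n_synth,
                             k_neighbors=config.smote_k, seed=seed,
                             binary_mask=binary_mask)
    X_fit = np.vstack([X_tr, synth])
    y_fit = np.concatenate([y_tr, np.ones(len(synth), dtype=y_tr.dtype)])

    clf = RandomForestClassifier(n_estimators=config.n_trees,
                                 max_features=config.max_features,
                                 random_state=seed, n_jobs=1)
    clf.fit(X_fit, y_fit)
    pred = clf.predict(X[test_idx])
    precision, recall, f1, _ = precision_recall_fscore_support(
        y[test_idx], pred, labels=[1], zero_division=0)
    metrics = ModelMetrics(model_index=model_index,
                           precision=float(precision[0]),
                           recall=float(recall[0]), f1=float(f1[0]))
    return TrainedModel(model_index=model_index, classifier=clf, metrics=metrics,
                        train_genes=[genes[i] for i in train_idx],
                        test_genes=[genes[i] for i in test_idx],
                        n_synthetic=int(n_synth), synthetic_rows=synth)


@dataclass
class EnsembleResult:
    models: list
    partition: list
    scores: list
    metrics: pd.DataFrame
    importance: pd.DataFrame
    importance_by_block: pd.Series


def fit_ensemble(features: FeatureMatrix,
                 config: PrioritizerConfig = PrioritizerConfig(),
                 seed: Optional[int] = None) -> EnsembleResult:
    """The full procedure: partition, train k models, score negatives."""
    rng = np.random.default_rng(seed)
    positives = features.genes_with_label("positive")
    negatives = features.genes_with_label("negative")
    if len(positives) < 2:
        raise InvalidInputError("need >= 2 positive genes")
    partition = partition_negatives(negatives, k=config.k_subsets, rng=rng)
    binary_mask = features.binary_mask

    models = []
    for i, subset in enumerate(partition):
        genes_i = positives + subset
        X = features.values.loc[genes_i].to_numpy(dtype=float)
        y = np.array([1] * len(positives) + [0] * len(subset))
        model_seed = int(rng.integers(0, 2**31 - 1))
        models.append(train_and_evaluate(X, y, genes_i, model_index=i + 1,
                                         config=config, seed=model_seed,
                                         binary_mask=binary_mask))

    scores = score_genes(models, features, partition)
    metrics = pd.DataFrame([{"model": m.model_index,
                             "precision": m.metrics.precision,
                             "recall": m.metrics.recall,
                             "f1": m.metrics.f1} for m in models])
    importance, by_block = feature_importance(models, features)
    return EnsembleResult(models=models, partition=partition, scores=scores,
                          metrics=metrics, importance=importance,
                          importance_by_block=by_block)


def score_genes(models: Sequence[TrainedModel], features: FeatureMatrix,
                partition: Sequence[Sequence[str]]) -> list[EnsembleScore]:
    """Vote count 0..k-1 per negative gene from the models that never saw it."""
    if len(models) != len(partition):
        raise ConsistencyError("one model per negative subset is required")
    negatives = features.genes_with_label("negative")
    member_of = {}
    for i, subset in enumerate(partition):
        for g in subset:
            if g in member_of:
                raise ConsistencyError(f"gene {g} appears in two subsets")
            member_of[g] = i
    if set(member_of) != set(negatives):
        raise ConsistencyError("partition does not cover the negative set")

    X_all = features.values.loc[negatives].to_numpy(dtype=float)
    preds = np.stack([m.classifier.predict(X_all) for m in models])  # k x n
    scores = []
    for j, gene in enumerate(negatives):
        own = member_of[gene]
        per_model = []
        votes = 0
        for i in range(len(models)):
            if i == own:
                per_model.append("not_applicable")
            elif preds[i, j] == 1:
                per_model.append("positive")
                votes += 1
            else:
                per_model.append("negative")
        scores.append(EnsembleScore(gene=gene, votes=votes,
                                    per_model_prediction=per_model))
    return scores


def feature_importance(models: Sequence[TrainedModel],
                       features: FeatureMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Mean-decrease-impurity importances averaged across models, plus block rollup."""
    names = list(features.values.columns)
    per_model = np.stack([m.classifier.feature_importances_ for m in models])
    mean_imp = per_model.mean(axis=0)
    table = pd.DataFrame({"feature": names,
                          "block": [features.blocks[n] for n in names],
                          "importance": mean_imp})
    table = table.sort_values("importance", ascending=False).reset_index(drop=True)
    by_block = table.groupby("block")["importance"].sum()
    return table, by_block


def intersect_with_phenotype(scores: Sequence[EnsembleScore],
                             phenotype_positive_set: Sequence[str],
                             max_votes: Optional[int] = None) -> tuple[list, list]:
    """Split max-vote candidate genes by external phenotype support."""
    if not scores:
        return [], []
    if max_votes is None:
        max_votes = max(len(s.per_model_prediction) - 1 for s in scores)
    pheno = set(phenotype_positive_set)
    candidates = [s.gene for s in scores if s.votes == max_votes]
    supported = [g for g in candidates if g in pheno]
    unsupported = [g for g in candidates if g not in pheno]
    return supported, unsupported
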