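"""Condition-specific supervised activity prediction.

Features are k-mer composition blocks plus profile-HMM scores (an external
embedding table can be substituted); evaluation follows the pooled
cross-validation convention: metrics are computed over concatenated
out-of-fold predictions, never per fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Ridge

from .alphabet import AMINO_ACIDS
from .seqio import SequenceRecord

KMER1 = list(AMINO_ACIDS)
KMER2 = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


def _hash_kmer(kmer: str, n_buckets: int) -> int:
    # deterministic base-21 rolling hash ('X' = 20); not Python hash() (randomized)
    h = 0
    for c in kmer:
        h = h * 21 + (20 if c == "X" else AMINO_ACIDS.index(c))
    return h % n_buckets


def kmer_features(
    records: Sequence[SequenceRecord],
    ks: tuple[int, ...] = (1, 2, 3),
    hash_buckets: int = 128,
) -> np.ndarray:
    """Per-k normalized k-mer composition; k<=2 explicit, k>=3 hashed."""
    blocks = []
    for k in ks:
        if k == 1:
            vocab = {c: i for i, c in enumerate(KMER1)}
            width = len(KMER1)
        elif k == 2:
            vocab = {c: i for i, c in enumerate(KMER2)}
            width = len(KMER2)
        else:
            vocab = None
            width = hash_buckets
        block = np.zeros((len(records), width))
        for r_i, rec in enumerate(records):
            s = rec.residues
            total = 0
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if vocab is not None:
                    j = vocab.get(km)
                    if j is None:  # contains X
                        continue
                else:
                    j = _hash_kmer(km, hash_buckets)
                block[r_i, j] += 1
                total += 1
            if total:
                block[r_i] /= total
        blocks.append(block)
    return np.hstack(blocks)


def feature_matrix(
    records: Sequence[SequenceRecord],
    hmm_bits: dict[str, float] | None = None,
    normalized_bits: dict[str, float] | None = None,
    embeddings: pd.DataFrame | None = None,
    ks: tuple[int, ...] = (1, 2, 3),
) -> np.ndarray:
    """Assemble the model input: k-mer blocks, optional HMM score columns and
    an optional id-indexed embedding table."""
    X = kmer_features(records, ks=ks)
    extra = []
    if hmm_bits is not None:
        extra.append(np.array([[hmm_bits[r.id]] for r in records]))
    if normalized_bits is not None:
        extra.append(np.array([[normalized_bits[r.id]] for r in records]))
    if embeddings is not None:
        extra.append(np.array([embeddings.loc[r.id].to_numpy(float) for r in records]))
    if extra:
        X = np.hstack([X] + extra)
    return X


@dataclass
class CVPlan:
    """A k-fold partition: fold id per example, in example order."""

    ids: list[str]
    fold_of: dict[str, int]
    k: int
    seed: int

    def folds(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.k)]
        for i in self.ids:
            out[self.fold_of[i]].append(i)
        return out


def make_folds(ids: Sequence[str], k: int = 5, seed: int = 0) -> CVPlan:
    """Random k-fold partition by shuffling; deterministic under seed."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError("more folds than examples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[p]: i % k for i, p in enumerate(perm)}
    return CVPlan(ids=ids, fold_of=fold_of, k=k, seed=seed)


def cross_split_identity(
    records: Sequence[SequenceRecord], plan: CVPlan, **identity_kwargs
) -> tuple[float, float]:
    """Diagnostic: (max of per-split-pair max identity, mean of means), as
    percentages, over all pairs of distinct folds."""
    from .seqio import pairwise_identity

    by_id = {r.id: r for r in records}
    folds = plan.folds()
    maxima, means = [], []
    for a in range(plan.k):
        for b in range(a + 1, plan.k):
            vals = [
                pairwise_identity(by_id[i], by_id[j], **identity_kwargs)
                for i in folds[a]
                for j in folds[b]
            ]
            if vals:
                maxima.append(max(vals))
                means.append(float(np.mean(vals)))
    return 100.0 * max(maxima), 100.0 * float(np.mean(means))


def default_classifier(seed: int = 0) -> RandomForestClassifier:
    """Bagged ensemble of 100 trees; probability = tree vote fraction
    (scikit-learn averages per-tree leaf probabilities; with fully grown trees
    these are pure leaves, i.e. votes)."""
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def default_regressor(alpha: float = 1.0) -> Ridge:
    return Ridge(alpha=alpha)


def pooled_cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    model_factory: Callable[[], object] | None = None,
    task: str = "classify",
) -> np.ndarray:
    """Out-of-fold predictions, concatenated in example order.

    Each fold's examples are predicted by a model trained on the remaining
    folds; no example is ever predicted by a model that saw it.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if model_factory is None:
        model_factory = (
            (lambda: default_classifier(plan.seed)) if task == "classify" else default_regressor
        )
    fold_idx = np.array([plan.fold_of[i] for i in plan.ids])
    preds = np.full(len(plan.ids), np.nan)
    for f in range(plan.k):
        test = fold_idx == f
        train = ~test
        if test.sum() == 0:
            raise ValueError(f"fold {f} is empty")
        model = model_factory()
        model.fit(X[train], y[train])
        if task == "classify" and hasattr(model, "predict_proba"):
            proba = model.predict_proba(X[test])
            classes = list(model.classes_)
            if len(classes) == 1:
                preds[test] = float(classes[0])
            else:
                preds[test] = proba[:, classes.index(1)]
        else:
            preds[test] = model.predict(X[test])
    return preds


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC with half credit for ties (Mann-Whitney U / n1*n0)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks on ties
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def score_metrics(
    predictions: Sequence[float],
    labels: Sequence[int],
    activity: Sequence[float] | None = None,
    boundary: float = 0.5,
) -> dict:
    """Precision at the 0.5 decision boundary and (optionally) Spearman rho of
    the predictions against measured activity."""
    predictions = np.asarray(predictions, float)
    labels = np.asarray(labels).astype(int)
    positive = predictions > boundary
    out: dict = {"n": int(len(labels)), "n_predicted_positive": int(positive.sum())}
    if positive.sum() == 0:
        out["precision"] = None
    else:
        out["precision"] = float(labels[positive].mean())
    try:
        out["auroc"] = auroc(predictions, labels)
    except ValueError:
        out["auroc"] = None
    if activity is not None:
        rho, pval = spearmanr(predictions, np.asarray(activity, float))
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(pval)
    return out


def condition_dataset(
    per_condition: pd.DataFrame,
    records: Sequence[SequenceRecord],
    condition: dict,
) -> tuple[list[SequenceRecord], np.ndarray, np.ndarray]:
    """Examples tested at a condition: (records, active labels, activity).

    Enzymes untested at the condition are excluded, not imputed.
    """
    mask = np.ones(len(per_condition), dtype=bool)
    for key, val in condition.items():
        mask &= per_condition[key] == val
    sub = per_condition[mask]
    by_id = {r.id: r for r in records}
    recs, ys, acts = [], [], []
    for _, row in sub.iterrows():
        if row["enzyme_id"] not in by_id:
            continue
        recs.append(by_id[row["enzyme_id"]])
        ys.append(int(row["active"]))
        acts.append(float(row["specific_activity"]))
    return recs, np.array(ys), np.array(acts)
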