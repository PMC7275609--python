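"""Group-constrained logistic-regression predictor search.

Candidate junction predictors are split into three groups by hierarchical
clustering (average linkage on 1 - Spearman rho of their usage across all
samples); group 1 is the cluster least correlated with the other two.
Candidate predictor sets are then: every single predictor, every pair of a
group-1 member with a member of group 2 or 3, and every triple with one
member per group.  With group sizes (3, 2, 3) this yields 41 sets.

Each set is scored by 5 repetitions of a random 50/50 train/test split: an
unregularized logistic regression is fitted on the training half, the test
half is scored, and the test AUC recorded; the mean of the 5 AUCs ranks the
sets.  The final model is the top-AUC repetition of the best set.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "ClassifierError",
    "PredictorSetEvaluation",
    "correlation_groups",
    "enumerate_predictor_sets",
    "fit_logistic",
    "roc_auc",
    "evaluate_predictor_set",
    "evaluate_all_sets",
    "select_best_model",
    "evaluations_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_REPS = 5
DEFAULT_TRAIN_FRAC = 0.5


class ClassifierError(ValueError):
    pass


def correlation_groups(matrix: pd.DataFrame, k: int = 3) -> dict[str, int]:
    """Cluster predictors into ``k`` correlation groups.

    ``matrix`` is samples x predictors.  Average-linkage hierarchical
    clustering on distance 1 - Spearman rho, cut into ``k`` clusters.
    Clusters are numbered 1..k by ascending mean between-cluster
    correlation, so group 1 is the most distinct from the rest.
    """
    predictors = list(matrix.columns)
    if k > len(predictors):
        raise ClassifierError(
            f"k={k} exceeds the number of predictors ({len(predictors)})"
        )
    rho = matrix.corr(method="spearman").to_numpy()
    if np.isnan(rho).any():
        raise ClassifierError("Spearman correlation undefined (constant predictor?)")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method="average"), t=k, criterion="maxclust")
    if len(set(labels)) < k:
        raise ClassifierError(
            f"could not separate predictors into {k} distinct clusters"
        )

    cluster_ids = sorted(set(labels))
    between_corr = {}
    for cid in cluster_ids:
        inside = labels == cid
        if inside.all():
            between_corr[cid] = math.nan
        else:
            between_corr[cid] = float(rho[np.ix_(inside, ~inside)].mean())
    order = sorted(cluster_ids, key=lambda cid: between_corr[cid])
    rank = {cid: i + 1 for i, cid in enumerate(order)}
    return {p: rank[c] for p, c in zip(predictors, labels)}


def enumerate_predictor_sets(grouping: dict[str, int]) -> list[tuple[str, ...]]:
    """Enumerate the group-constrained candidate predictor sets.

    Singles: every predictor.  Pairs: one group-1 member with one member of
    group 2 or 3.  Triples: one member from each group.
    """
    groups: dict[int, list[str]] = {1: [], 2: [], 3: []}
    for predictor, g in grouping.items():
        if g not in groups:
            raise ClassifierError(f"predictor {predictor} has invalid group {g}")
        groups[g].append(predictor)
    for g, members in groups.items():
        if not members:
            raise ClassifierError(f"group {g} is empty")
    for members in groups.values():
        members.sort()

    sets: list[tuple[str, ...]] = [(p,) for p in sorted(grouping)]
    for p1 in groups[1]:
        for p2 in sorted(groups[2] + groups[3]):
            sets.append(tuple(sorted((p1, p2))))
    for combo in itertools.product(groups[1], groups[2], groups[3]):
        sets.append(tuple(sorted(combo)))
    # unordered and distinct
    unique = sorted(set(sets), key=lambda s: (len(s), s))
    if len(unique) != len(sets):
        logger.info("dropped %d duplicate predictor sets", len(sets) - len(unique))
    return unique


def fit_logistic(features: np.ndarray, labels: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit (no penalty, iteration-capped).

    On quasi-separated data the capped fit is returned; its scores still
    rank samples correctly.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClassifierError("training data contains a single class")
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(features, dtype=float), labels)
    return model


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie) (Mann-Whitney form)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClassifierError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class PredictorSetEvaluation:
    members: tuple[str, ...]
    aucs: tuple[float, ...]
    mean_auc: float
    sd_auc: float
    best_intercept: float
    best_coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not (0 <= a <= 1) for a in self.aucs):
            raise ClassifierError("AUC outside [0, 1]")


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def evaluate_predictor_set(
    members,
    matrix: pd.DataFrame,
    labels: pd.Series,
    reps: int = DEFAULT_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int | np.random.Generator | None = None,
    stratified: bool = True,
    max_retries: int = 10,
) -> PredictorSetEvaluation:
    """Score one predictor set by repeated random-split train/test AUC."""
    members = tuple(members)
    if not members:
        raise ClassifierError("empty predictor set")
    missing = [m for m in members if m not in matrix.columns]
    if missing:
        raise ClassifierError(f"predictors absent from the matrix: {missing}")
    data = pd.concat([matrix[list(members)], labels.rename("__label__")], axis=1)
    data = data.dropna()
    X = data[list(members)].to_numpy(dtype=float)
    y = data["__label__"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ClassifierError("matrix does not contain both classes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    aucs: list[float] = []
    best_model: LogisticRegression | None = None
    best_auc = -1.0
    for _ in range(reps):
        for attempt in range(max_retries):
            if stratified:
                train, test = _stratified_split(y, train_frac, rng)
            else:
                perm = rng.permutation(len(y))
                n_train = int(round(train_frac * len(y)))
                train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            if (
                len(np.unique(y[train])) == 2
                and len(np.unique(y[test])) == 2
            ):
                break
            logger.warning("degenerate split (single-class half); resampling")
        else:
            raise ClassifierError("could not draw a two-class split")
        model = fit_logistic(X[train], y[train])
        scores = model.predict_proba(X[test])[:, 1]
        auc = roc_auc(scores, y[test])
        aucs.append(auc)
        if auc > best_auc:
            best_auc = auc
            best_model = model
    assert best_model is not None
    return PredictorSetEvaluation(
        members=members,
        aucs=tuple(aucs),
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        best_intercept=float(best_model.intercept_[0]),
        best_coefficients=tuple(float(c) for c in best_model.coef_[0]),
    )


def evaluate_all_sets(
    matrix: pd.DataFrame,
    labels: pd.Series,
    grouping: dict[str, int],
    reps: int = DEFAULT_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int | None = None,
    stratified: bool = True,
) -> list[PredictorSetEvaluation]:
    """Enumerate and evaluate every group-constrained predictor set."""
    rng = np.random.default_rng(seed)
    return [
        evaluate_predictor_set(
            members, matrix, labels,
            reps=reps, train_frac=train_frac, seed=rng, stratified=stratified,
        )
        for members in enumerate_predictor_sets(grouping)
    ]


def select_best_model(
    evaluations: list[PredictorSetEvaluation],
) -> PredictorSetEvaluation:
    """Best set = highest mean AUC; ties broken by fewer predictors, then name."""
    if not evaluations:
        raise ClassifierError("no evaluations supplied")
    return min(
        evaluations, key=lambda e: (-e.mean_auc, len(e.members), e.members)
    )


def evaluations_to_frame(
    evaluations: list[PredictorSetEvaluation],
) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        row = {
            "members": "+".join(ev.members),
            "n_predictors": len(ev.members),
            "mean_auc": ev.mean_auc,
            "sd_auc": ev.sd_auc,
        }
        for i, a in enumerate(ev.aucs, 1):
            row[f"auc_{i}"] = a
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("mean_auc", ascending=False)
        .reset_index(drop=True)
    )
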