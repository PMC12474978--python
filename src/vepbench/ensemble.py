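"""Random-forest ensemble over per-method VEP scores.

Individual predictors carry complementary information; a random forest on
the per-method score vector can out-discriminate any single method.
Scores are z-score standardized (centering/scale fitted on training rows
only), the data split 75:25 stratified by class, and the forest's
``mtry`` (features sampled per split) tuned by cross-validated AUROC
under either randomly sampled 5-fold CV or gene-holdout CV, where entire
genes are withheld so validation measures generalization to unseen genes.
Variants with duplicated occurrences (population level) stay on one side
of every split to avoid leakage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .calibration import _rank_auroc
from .roc import MethodComparison, delong_test

logger = logging.getLogger(__name__)


@dataclass
class ZScoreParams:
    center: pd.Series
    scale: pd.Series
    dropped: List[str] = field(default_factory=list)


def zscore_preprocess(
    train_scores: pd.DataFrame, apply_scores: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame, ZScoreParams]:
    """Standardize features with parameters fitted on training rows only.

    Sample standard deviation (n-1 divisor).  Constant training features
    are dropped from both tables with a warning; all-constant is an error.
    """
    center = train_scores.mean()
    scale = train_scores.std(ddof=1)
    constant = scale[(scale == 0) | scale.isna()].index.tolist()
    if len(constant) == len(train_scores.columns):
        raise ValueError("all features are constant on the training data")
    if constant:
        logger.warning("zscore_preprocess: dropping constant features %s", constant)
    keep = [c for c in train_scores.columns if c not in constant]
    params = ZScoreParams(center=center[keep], scale=scale[keep], dropped=constant)
    train_std = (train_scores[keep] - params.center) / params.scale
    apply_std = (apply_scores[keep] - params.center) / params.scale
    return train_std, apply_std, params


def split_train_test(
    instances: Sequence[str],
    labels: Sequence[int],
    ratio: float = 0.75,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Class-stratified split of instance indices; variant-grouped.

    *instances* are variant keys, possibly with population-level
    duplicates; all occurrences of one variant land on the same side.
    Returns (train_indices, test_indices) into the input sequence.
    """
    keys = np.asarray(list(instances))
    y = np.asarray(list(labels), dtype=int)
    if len(keys) != len(y):
        raise ValueError("instances and labels must align")
    rng = np.random.default_rng(seed)
    uniq = pd.DataFrame({"key": keys, "y": y}).drop_duplicates("key")
    counts = {cls: int((uniq["y"] == cls).sum()) for cls in (0, 1)}
    for cls, n_c in counts.items():
        if n_c < 2:
            raise ValueError(f"class {cls} has fewer than 2 unique instances")
    # largest-remainder allocation so the overall split hits the ratio
    # exactly while staying stratified within +-1 per class
    target_total = int(round(ratio * len(uniq)))
    floors = {cls: int(np.floor(ratio * n_c)) for cls, n_c in counts.items()}
    remainders = sorted(
        counts, key=lambda cls: ratio * counts[cls] - floors[cls], reverse=True
    )
    leftover = target_total - sum(floors.values())
    n_train_by_class = dict(floors)
    for cls in remainders[:leftover]:
        n_train_by_class[cls] += 1
    train_keys: set = set()
    for cls, n_c in counts.items():
        cls_keys = uniq.loc[uniq["y"] == cls, "key"].to_numpy()
        n_train = min(max(n_train_by_class[cls], 1), n_c - 1)
        perm = rng.permutation(n_c)
        train_keys.update(cls_keys[perm[:n_train]])
    in_train = np.array([k in train_keys for k in keys])
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


@dataclass
class EnsembleResult:
    cv_scheme: str
    level: str
    auroc: float
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    stratum_auroc: Dict[str, float] = field(default_factory=dict)
    importances: Dict[str, float] = field(default_factory=dict)
    mtry: int = 0
    cv_auroc_by_mtry: Dict[int, float] = field(default_factory=dict)


def _gene_of(key: str) -> str:
    return key.split(":", 1)[0]


def _make_folds(
    keys: np.ndarray,
    y: np.ndarray,
    cv_scheme: str,
    n_folds: int,
    rng: np.random.Generator,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    n = len(keys)
    if cv_scheme == "kfold5":
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        return [
            (np.setdiff1d(np.arange(n), f, assume_unique=False), f) for f in folds
        ]
    if cv_scheme == "gene_holdout":
        genes = np.array([_gene_of(k) for k in keys])
        uniq_genes = np.array(sorted(set(genes)))
        if len(uniq_genes) < n_folds:
            raise ValueError(
                f"gene_holdout needs >= {n_folds} genes, got {len(uniq_genes)}"
            )
        perm = rng.permutation(len(uniq_genes))
        gene_folds = np.array_split(uniq_genes[perm], n_folds)
        out = []
        for gf in gene_folds:
            val = np.flatnonzero(np.isin(genes, gf))
            train = np.flatnonzero(~np.isin(genes, gf))
            out.append((train, val))
        return out
    raise ValueError(f"unknown cv_scheme {cv_scheme!r}")


def train_ensemble(
    train_scores: pd.DataFrame,
    labels: Sequence[int],
    cv_scheme: str = "kfold5",
    mtry_grid: Optional[Sequence[int]] = None,
    n_trees: int = 500,
    seed: int = 0,
    level: str = "mutation",
    n_folds: int = 5,
) -> Tuple[RandomForestClassifier, EnsembleResult]:
    """Tune mtry by CV AUROC, refit on all training data, report importances.

    *train_scores* is indexed by variant key (``gene:p.change``), one
    column per method, already standardized and complete (rows with
    missing features are the caller's concern).
    """
    X = train_scores.to_numpy(dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if y.min() == y.max():
        raise ValueError("labels are constant")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features after preprocessing")
    p = X.shape[1]
    if mtry_grid is None:
        mtry_grid = sorted({1, 2, 3, max(1, int(round(np.sqrt(p))))})
    mtry_grid = [m for m in mtry_grid if 1 <= m <= p]
    keys = np.asarray(train_scores.index)
    rng = np.random.default_rng(seed)
    folds = _make_folds(keys, y, cv_scheme, n_folds, rng)
    cv_scores: Dict[int, float] = {}
    for mtry in mtry_grid:
        aucs = []
        for fold_i, (tr, va) in enumerate(folds):
            if len(set(y[va])) < 2 or len(set(y[tr])) < 2:
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mtry,
                random_state=int(seed % (2**31)) + fold_i,
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[va])[:, 1]
            aucs.append(_rank_auroc(prob[y[va] == 1], prob[y[va] == 0]))
        if not aucs:
            raise ValueError("no usable CV folds (single-class validation sets)")
        cv_scores[mtry] = float(np.mean(aucs))
    best_mtry = max(cv_scores, key=lambda m: (cv_scores[m], -m))
    final = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=best_mtry,
        random_state=int(seed % (2**31)),
        n_jobs=1,
    )
    final.fit(X, y)
    importances = dict(
        zip(train_scores.columns, (float(v) for v in final.feature_importances_))
    )
    result = EnsembleResult(
        cv_scheme=cv_scheme,
        level=level,
        auroc=cv_scores[best_mtry],
        importances=importances,
        mtry=best_mtry,
        cv_auroc_by_mtry=cv_scores,
    )
    return final, result


def evaluate_and_compare(
    model: RandomForestClassifier,
    test_scores: pd.DataFrame,
    test_labels: Sequence[int],
    baseline_scores: Optional[Mapping[str, float]] = None,
    baseline_name: str = "baseline",
    cv_scheme: str = "kfold5",
    level: str = "mutation",
    strata: Optional[Mapping[str, str]] = None,
) -> Tuple[EnsembleResult, Optional[MethodComparison]]:
    """Held-out test metrics plus a paired DeLong test against a baseline.

    Accuracy/sensitivity/specificity use the 0.5 predicted-probability
    threshold.  Test instances without a baseline score are dropped from
    the comparison only (logged), never from the test metrics.
    """
    X = test_scores.to_numpy(dtype=float)
    y = np.asarray(list(test_labels), dtype=int)
    prob = model.predict_proba(X)[:, 1]
    pred = (prob >= 0.5).astype(int)
    acc = float((pred == y).mean())
    sens = float(pred[y == 1].mean()) if (y == 1).any() else float("nan")
    spec = float(1 - pred[y == 0].mean()) if (y == 0).any() else float("nan")
    auroc = _rank_auroc(prob[y == 1], prob[y == 0])
    stratum_auroc: Dict[str, float] = {}
    if strata:
        labels_by_key = np.asarray([strata.get(k, "other") for k in test_scores.index])
        for s in sorted(set(labels_by_key)):
            mask = labels_by_key == s
            if len(set(y[mask])) == 2:
                stratum_auroc[s] = _rank_auroc(
                    prob[mask & (y == 1)], prob[mask & (y == 0)]
                )
    result = EnsembleResult(
        cv_scheme=cv_scheme,
        level=level,
        auroc=float(auroc),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        stratum_auroc=stratum_auroc,
    )
    comparison = None
    if baseline_scores is not None:
        keys = list(test_scores.index)
        have = np.array(
            [
                baseline_scores.get(k) is not None
                and np.isfinite(baseline_scores.get(k, np.nan))
                for k in keys
            ]
        )
        n_dropped = int((~have).sum())
        if n_dropped:
            logger.warning(
                "evaluate_and_compare: %d test instances lack baseline scores",
                n_dropped,
            )
        base = np.array([baseline_scores[k] for i, k in enumerate(keys) if have[i]])
        if len(set(y[have])) == 2:
            comparison = delong_test(
                prob[have], base, y[have], method_a="ensemble", method_b=baseline_name
            )
    return result, comparison
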