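"""Driver-rediscovery benchmark: ROC analysis against known-driver labels.

Known oncogenic mutations form the positive class and non-oncogenic
variants (germline polymorphisms without known medical impact, or
context-matched simulated neutral variants) the negative class.  Analyses
run at two instance levels: *mutation* level, each unique variant counted
once, and *population* level, each occurrence counted, reflecting the
real-world frequency of every mutation.  Negatives are upsampled with
replacement to balance the classes.  AUROC confidence intervals and
paired method comparisons use DeLong's structural-components estimator,
with Benjamini–Hochberg correction across the comparison family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from .calibration import bh_adjust
from .types import MutationRecord

logger = logging.getLogger(__name__)


def build_instances(
    mutations: Sequence[MutationRecord], level: str = "population"
) -> List[str]:
    """Variant-key instance multiset at mutation or population level."""
    if level == "population":
        return [m.variant_key for m in mutations]
    if level == "mutation":
        return list(dict.fromkeys(m.variant_key for m in mutations))
    raise ValueError(f"level must be 'mutation' or 'population', got {level!r}")


def upsample_negatives(
    negatives: Sequence[str], n_target: int, seed: int
) -> List[str]:
    """Sample *n_target* negatives with replacement (class balancing)."""
    if len(negatives) == 0:
        raise ValueError("cannot upsample from an empty negative set")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(negatives), size=int(n_target))
    return [negatives[i] for i in idx]


def _midrank_components(
    pos: np.ndarray, neg: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus DeLong structural components V10 (pos) and V01 (neg)."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = rankdata(all_scores)
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


@dataclass
class RocResult:
    method: str
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    level: str = "population"
    stratum: str = "all"
    degenerate: bool = False


def auroc_delong(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    method: str = "",
    level: str = "population",
    stratum: str = "all",
    alpha: float = 0.05,
) -> RocResult:
    """AUROC with a DeLong 95% CI (normal approximation, clipped to [0,1]).

    Ties contribute 1/2 to concordance.  When the DeLong variance is zero
    (perfect separation or constant scores) the CI collapses to the point
    estimate and the result is flagged degenerate.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    auc, v10, v01 = _midrank_components(pos, neg)
    var = v10.var(ddof=1) / len(pos) if len(pos) > 1 else 0.0
    var += v01.var(ddof=1) / len(neg) if len(neg) > 1 else 0.0
    if var <= 0:
        return RocResult(
            method, auc, auc, auc, len(pos), len(neg), level, stratum, True
        )
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    return RocResult(
        method,
        auc,
        float(np.clip(auc - z * se, 0, 1)),
        float(np.clip(auc + z * se, 0, 1)),
        len(pos),
        len(neg),
        level,
        stratum,
        False,
    )


@dataclass
class MethodComparison:
    method_a: str
    method_b: str
    delta_auc: float
    ci_low: float
    ci_high: float
    p: float
    q: Optional[float] = None
    degenerate: bool = False


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    method_a: str = "a",
    method_b: str = "b",
    alpha: float = 0.05,
) -> MethodComparison:
    """Paired DeLong test of two correlated AUROCs on identical instances.

    Degenerate variance (e.g. identical scorers) yields p = 1 for a zero
    delta and a flagged result otherwise.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("paired comparison requires identical instance sets")
    pos_mask = y == 1
    if pos_mask.all() or (~pos_mask).all():
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _midrank_components(a[pos_mask], a[~pos_mask])
    auc_b, v10_b, v01_b = _midrank_components(b[pos_mask], b[~pos_mask])
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
        return MethodComparison(
            method_a, method_b, float(delta), float(delta), float(delta), p,
            degenerate=True,
        )
    se = np.sqrt(var)
    z = delta / se
    p = 2 * norm.sf(abs(z))
    zc = norm.ppf(1 - alpha / 2)
    return MethodComparison(
        method_a,
        method_b,
        float(delta),
        float(delta - zc * se),
        float(delta + zc * se),
        float(p),
    )


def compare_methods(
    scores_by_method: Mapping[str, Sequence[float]],
    labels: Sequence[int],
    method_classes: Optional[Mapping[str, str]] = None,
) -> List[MethodComparison]:
    """Planned pairwise DeLong comparisons with BH correction.

    With *method_classes* given (method -> methodological class), the plan
    is: within each class, best-vs-others; then each class best vs the
    overall best method.  Without classes, the overall best is compared to
    every other method.  q-values are BH over the comparisons performed.
    """
    names = list(scores_by_method)
    if len(names) < 2:
        raise ValueError("need at least two methods to compare")
    n_inst = {len(scores_by_method[m]) for m in names}
    if len(n_inst) != 1 or n_inst.pop() != len(labels):
        raise ValueError("all methods must score the identical instance multiset")
    y = np.asarray(list(labels), dtype=int)
    pos_mask = y == 1
    aucs = {}
    for mname in names:
        s = np.asarray(list(scores_by_method[mname]), dtype=float)
        aucs[mname], _, _ = _midrank_components(s[pos_mask], s[~pos_mask])
    pairs: List[Tuple[str, str]] = []
    if method_classes:
        classes: Dict[str, List[str]] = {}
        for mname in names:
            classes.setdefault(method_classes.get(mname, "other"), []).append(mname)
        class_best = {}
        for cls, members in classes.items():
            best = max(members, key=lambda mm: aucs[mm])
            class_best[cls] = best
            pairs.extend((best, other) for other in members if other != best)
        overall = max(names, key=lambda mm: aucs[mm])
        pairs.extend(
            (best, overall)
            for best in class_best.values()
            if best != overall and (best, overall) not in pairs
        )
    else:
        overall = max(names, key=lambda mm: aucs[mm])
        pairs = [(overall, other) for other in names if other != overall]
    results = [
        delong_test(
            scores_by_method[a], scores_by_method[b], y, method_a=a, method_b=b
        )
        for a, b in pairs
    ]
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def per_gene_tpr(
    classifications: Mapping[str, str],
    truth_pos: Sequence[str],
    genes: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[float, int]]:
    """Per-gene true positive rate over known-driver variants.

    TPR = (# truth-positive variants called pathogenic) / (# truth-positive
    variants with a non-missing classification).  Genes with no non-missing
    classified driver are omitted with a warning.
    """
    by_gene: Dict[str, List[str]] = {}
    for key in truth_pos:
        gene = key.split(":", 1)[0]
        by_gene.setdefault(gene, []).append(key)
    wanted = list(genes) if genes is not None else sorted(by_gene)
    out: Dict[str, Tuple[float, int]] = {}
    for gene in wanted:
        keys = by_gene.get(gene, [])
        classed = [
            classifications.get(k, "missing")
            for k in keys
        ]
        non_missing = [c for c in classed if c != "missing"]
        if not non_missing:
            logger.warning("per_gene_tpr: gene %s has no classified drivers", gene)
            continue
        tpr = sum(c == "pathogenic" for c in non_missing) / len(non_missing)
        out[gene] = (float(tpr), len(keys))
    return out


def roc_points(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> List[Tuple[float, float]]:
    """(fpr, tpr) points of the empirical ROC curve, for TSV export."""
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pts.append(
            (float((neg >= t).mean()), float((pos >= t).mean()))
        )
    pts.append((1.0, 1.0))
    return pts
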