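"""Score calibration: turning raw VEP scores into pathogenic/benign calls.

Methods ship in four flavors.  Some provide built-in three-way classes
(used verbatim); tiered classifiers expose several uncertainty classes and
the most discriminative one is selected by AUROC; p-value-based methods are
thresholded on Benjamini–Hochberg q-values; score-only methods get a
dataset-specific cutoff maximizing sensitivity + specificity (a Youden-type
cutpoint), with the median of all maximizing thresholds used when the
maximizer is not unique.  Boundary rules are inclusive: a score equal to
the threshold is called pathogenic, on whichever side of the scale the
method marks pathogenicity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import MethodSpec, ScoreMatrix


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up q-values, original order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUROC with ties counted 1/2."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    n1, n2 = len(pos), len(neg)
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n2)


@dataclass
class CutpointResult:
    """A learned sensitivity+specificity-maximizing threshold."""

    method: str
    threshold: float
    candidate_maxima: List[float]
    objective: float
    orientation: str


def youden_cutpoint(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    orientation: str = "higher_pathogenic",
    method: str = "",
) -> CutpointResult:
    """Threshold maximizing sensitivity + specificity over observed scores.

    Candidate thresholds are the unique observed scores (both classes
    pooled).  For ``higher_pathogenic``, score >= t calls pathogenic; for
    ``lower_pathogenic``, score <= t does.  All maximizers are reported and
    the final threshold is their median.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    candidates = np.unique(np.concatenate([pos, neg]))
    if orientation == "higher_pathogenic":
        sens = (pos[:, None] >= candidates[None, :]).mean(axis=0)
        spec = (neg[:, None] < candidates[None, :]).mean(axis=0)
    elif orientation == "lower_pathogenic":
        sens = (pos[:, None] <= candidates[None, :]).mean(axis=0)
        spec = (neg[:, None] > candidates[None, :]).mean(axis=0)
    else:
        raise ValueError(f"bad orientation {orientation!r}")
    objective = sens + spec
    best = objective.max()
    maxima = candidates[np.isclose(objective, best, rtol=0, atol=1e-12)]
    return CutpointResult(
        method=method,
        threshold=float(np.median(maxima)),
        candidate_maxima=[float(t) for t in maxima],
        objective=float(best),
        orientation=orientation,
    )


def select_best_class(
    classed_scores: Mapping[str, Tuple[Sequence[float], Sequence[float]]],
) -> str:
    """Pick the uncertainty class whose (pos, neg) scores give maximal AUROC.

    For tiered classifiers that exclude increasingly many uncertain
    variants: ties break toward the class retaining the most variants.
    """
    best_label = None
    best_key: Optional[Tuple[float, int]] = None
    for label in sorted(classed_scores):
        pos, neg = classed_scores[label]
        pos = np.asarray(list(pos), dtype=float)
        neg = np.asarray(list(neg), dtype=float)
        if pos.size == 0 or neg.size == 0:
            continue
        auroc = _rank_auroc(pos, neg)
        key = (round(auroc, 12), pos.size + neg.size)
        if best_key is None or key > best_key:
            best_key = key
            best_label = label
    if best_label is None:
        raise ValueError("no class with both positive and negative scores")
    return best_label


def qvalue_classify(
    pvalues: Mapping[str, float], alpha: float = 0.05
) -> Dict[str, str]:
    """BH-correct per-variant p-values; q <= alpha is pathogenic."""
    keys = list(pvalues)
    q = bh_adjust([pvalues[k] for k in keys])
    return {
        k: ("pathogenic" if qk <= alpha else "benign") for k, qk in zip(keys, q)
    }


def classify_variants(
    scores: ScoreMatrix,
    spec: MethodSpec,
    cutpoint: Optional[CutpointResult] = None,
    builtin_labels: Optional[Mapping[str, str]] = None,
    pvalues: Optional[Mapping[str, float]] = None,
    alpha: float = 0.05,
) -> Dict[str, str]:
    """Classify every variant in *scores* for one method.

    Returns variant_key -> {pathogenic, benign, uncertain, missing}.  A
    missing score is always ``"missing"``, never benign.  The cutoff rule
    is boundary-inclusive on the pathogenic side per the method's
    orientation.
    """
    out: Dict[str, str] = {}
    if spec.calibration_mode == "builtin_classes":
        assert spec.class_map is not None
        labels = builtin_labels or {}
        col = scores.scores(spec.name)
        for key in scores.variant_keys:
            raw = labels.get(key)
            if raw is None and np.isnan(col.loc[key]):
                out[key] = "missing"
            elif raw is None:
                out[key] = "uncertain"
            else:
                out[key] = spec.class_map.get(raw, "uncertain")
        return out
    if spec.calibration_mode == "qvalue_threshold":
        if pvalues is None:
            raise ValueError("qvalue_threshold requires per-variant p-values")
        called = qvalue_classify(pvalues, alpha=alpha)
        for key in scores.variant_keys:
            out[key] = called.get(key, "missing")
        return out
    if spec.calibration_mode in ("learned_cutoff", "class_selection"):
        if cutpoint is None:
            raise ValueError(f"{spec.calibration_mode} requires a cutpoint")
        col = scores.scores(spec.name)
        t = cutpoint.threshold
        for key, s in col.items():
            if np.isnan(s):
                out[key] = "missing"
            elif spec.orientation == "higher_pathogenic":
                out[key] = "pathogenic" if s >= t else "benign"
            else:
                out[key] = "pathogenic" if s <= t else "benign"
        return out
    raise ValueError(f"unknown calibration mode {spec.calibration_mode!r}")


@dataclass
class CalibrationReport:
    """One row per method for the calibration report TSV."""

    rows: List[Dict[str, object]] = field(default_factory=list)

    def add(self, spec: MethodSpec, cutpoint: Optional[CutpointResult]) -> None:
        self.rows.append(
            {
                "method": spec.name,
                "mode": spec.calibration_mode,
                "orientation": spec.orientation,
                "threshold": None if cutpoint is None else cutpoint.threshold,
                "objective": None if cutpoint is None else cutpoint.objective,
                "n_candidates": 0
                if cutpoint is None
                else len(cutpoint.candidate_maxima),
            }
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)
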