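"""Pathway mutual-exclusivity benchmark.

Driver mutations in the same oncogenic signaling pathway tend not to
co-occur in one tumor (functional redundancy).  For each gene in a
pathway, a one-vs-all 2x2 table is built over patients: does the patient
carry a reclassified-pathogenic mutation in the gene, and does the patient
carry a known-oncogenic mutation in *any* pathway gene (the focal gene
included)?  A two-sided Fisher exact test with a negative log odds ratio
and BH q <= 0.1 flags significant exclusivity.  The pathway-level rate
divides significant tests by the number of genes in the pathway, counting
untestable genes in the denominator.

Two companion analyses: OR_mutex contrasts reclassified-pathogenic against
reclassified-benign carriers for co-mutation with *other* pathway genes'
oncogenic mutations, and a TMB-adjusted logistic regression checks that
observed exclusivity is not an artifact of hypermutated samples carrying
everything.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .binding import EnrichmentResult, binding_fisher
from .calibration import bh_adjust
from .contingency import (
    ZeroMarginError,
    check_margins,
    fisher_two_sided_p,
    validate_table,
)
from .types import MutationRecord, PathwaySpec, PatientRecord, ONCOGENIC_CLASSES

logger = logging.getLogger(__name__)


def _carriers(
    mutations: Sequence[MutationRecord],
    genes: Set[str],
    *,
    oncogenic: bool = False,
    classifications: Optional[Mapping[str, str]] = None,
    call: str = "pathogenic",
) -> Set[str]:
    """Patients carrying a qualifying mutation in any of *genes*.

    With ``oncogenic=True`` a qualifying mutation is OncoKB
    (likely-)oncogenic; otherwise it is a VUS whose method classification
    equals *call*.
    """
    out: Set[str] = set()
    for m in mutations:
        if m.gene not in genes:
            continue
        if oncogenic:
            if m.oncokb_class in ONCOGENIC_CLASSES:
                out.add(m.patient_id)
        else:
            if m.oncokb_class in ONCOGENIC_CLASSES:
                continue
            if (
                classifications is not None
                and classifications.get(m.variant_key) == call
            ):
                out.add(m.patient_id)
    return out


def build_mutex_table(
    gene: str,
    pathway: PathwaySpec,
    classifications: Mapping[str, str],
    patients: Sequence[PatientRecord],
    mutations: Sequence[MutationRecord],
) -> List[List[int]]:
    """One-vs-all 2x2 for *gene* against oncogenic mutations in *pathway*.

    Rows: patient carries >= 1 reclassified-pathogenic mutation in the
    gene, vs not (VUSs/no mutation).  Columns: patient carries >= 1 known
    oncogenic mutation in any pathway gene — the focal gene included — vs
    not.  A patient with only an oncogenic mutation in the focal gene
    falls in the second row but still counts in the first column.
    """
    if gene not in pathway:
        raise ValueError(f"gene {gene!r} is not in pathway {pathway.name!r}")
    path_rows = _carriers(
        mutations, {gene}, classifications=classifications, call="pathogenic"
    )
    onco_cols = _carriers(mutations, set(pathway.genes), oncogenic=True)
    a = b = c = d = 0
    for p in patients:
        in_row = p.patient_id in path_rows
        in_col = p.patient_id in onco_cols
        if in_row and in_col:
            a += 1
        elif in_row:
            b += 1
        elif in_col:
            c += 1
        else:
            d += 1
    return [[a, b], [c, d]]


@dataclass
class MutexResult:
    gene: str
    pathway: str
    table: List[List[int]]
    log_or: float
    p: float
    q: Optional[float] = None
    fdr: float = 0.1
    method: str = ""

    @property
    def significant(self) -> bool:
        """Mutual exclusivity: negative log-OR and q at or below the FDR."""
        return self.q is not None and self.log_or < 0 and self.q <= self.fdr


def mutex_fisher(
    table: Sequence[Sequence[int]],
    gene: str = "",
    pathway: str = "",
    fdr: float = 0.1,
) -> Optional[MutexResult]:
    """Exact two-sided test on a mutex 2x2; None (with notice) at zero margin.

    The log odds ratio uses a Haldane–Anscombe 0.5 correction when any
    cell is zero so its sign stays defined; the exact p never does.
    """
    t = validate_table(table)
    try:
        check_margins(t)
    except ZeroMarginError:
        logger.warning(
            "mutex_fisher: zero margin for %s/%s, test skipped", gene, pathway
        )
        return None
    p = fisher_two_sided_p(t)
    tf = t.astype(float)
    if np.any(tf == 0):
        tf = tf + 0.5
    log_or = float(np.log((tf[0, 0] * tf[1, 1]) / (tf[0, 1] * tf[1, 0])))
    return MutexResult(gene, pathway, t.tolist(), log_or, p, fdr=fdr)


def mutex_battery(
    results: Sequence[Optional[MutexResult]],
) -> List[MutexResult]:
    """BH-correct one invocation's family of mutex tests (skips dropped)."""
    kept = [r for r in results if r is not None]
    qs = bh_adjust([r.p for r in kept])
    for r, q in zip(kept, qs):
        r.q = float(q)
    return kept


def pathway_rate(results: Sequence[MutexResult], pathway: PathwaySpec) -> float:
    """Significant mutually-exclusive tests / all genes in the pathway.

    Untestable genes (no result) still count in the denominator.
    """
    n_sig = sum(
        1 for r in results if r.pathway == pathway.name and r.significant
    )
    return n_sig / len(pathway.genes)


def or_mutex(
    classifications: Mapping[str, str],
    patients: Sequence[PatientRecord],
    mutations: Sequence[MutationRecord],
    gene: str,
    pathway: PathwaySpec,
) -> Optional[EnrichmentResult]:
    """OR of pathogenic vs benign reclassified carriers co-mutating in-pathway.

    Rows: carriers of a reclassified-pathogenic vs reclassified-benign VUS
    in the focal gene (pathogenic takes precedence for mixed carriers).
    Columns: carries a known-oncogenic mutation in *another* pathway gene
    (the focal gene excluded) vs not.  Returns None, flagged underpowered,
    when either carrier class is empty.
    """
    if gene not in pathway:
        raise ValueError(f"gene {gene!r} is not in pathway {pathway.name!r}")
    path_set = _carriers(
        mutations, {gene}, classifications=classifications, call="pathogenic"
    )
    benign_set = (
        _carriers(
            mutations, {gene}, classifications=classifications, call="benign"
        )
        - path_set
    )
    others = set(pathway.genes) - {gene}
    onco_other = _carriers(mutations, others, oncogenic=True)
    cohort_ids = {p.patient_id for p in patients}
    path_set &= cohort_ids
    benign_set &= cohort_ids
    if not path_set or not benign_set:
        logger.warning(
            "or_mutex: underpowered for %s/%s (a carrier class is empty)",
            gene,
            pathway.name,
        )
        return None
    a = sum(1 for pid in path_set if pid in onco_other)
    b = len(path_set) - a
    c = sum(1 for pid in benign_set if pid in onco_other)
    d = len(benign_set) - c
    return binding_fisher([[a, b], [c, d]], group=f"{gene}|{pathway.name}")


@dataclass
class LogisticResult:
    coef_mutation: float
    se_mutation: float
    p_mutation: float
    coef_tmb_high: float
    se_tmb_high: float
    p_tmb_high: float
    intercept: float
    separation: bool = False
    n: int = 0


def tmb_adjusted_logistic(
    samples: Sequence[Tuple[bool, bool, bool]],
) -> LogisticResult:
    """Logistic fit: pathway-oncogenic ~ reclassified-mutation + TMB-high.

    Each sample is (pathway_oncogenic, reclassified_mut, tmb_high).  A
    negative, significant mutation coefficient indicates exclusivity
    independent of mutational burden.  Perfect separation is detected and
    flagged (NaN estimates) rather than silently diverging.
    """
    arr = np.asarray([[int(a), int(b), int(c)] for a, b, c in samples], dtype=float)
    if len(arr) < 10:
        raise ValueError("need at least 10 samples")
    y = arr[:, 0]
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    X = sm.add_constant(arr[:, 1:], has_constant="add")
    model = sm.Logit(y, X)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and flagged below
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
        params = fit.params
        bse = fit.bse
        pvals = fit.pvalues
        fitted = fit.predict(X)
        separation = bool(
            np.any(np.abs(params) > 15)
            or np.any(~np.isfinite(bse))
            or np.all((fitted < 1e-8) | (fitted > 1 - 1e-8))
        )
    except Exception:  # statsmodels raises PerfectSeparationError and kin
        separation = True
        params = np.full(3, np.nan)
        bse = np.full(3, np.nan)
        pvals = np.full(3, np.nan)
    if separation:
        params = np.full(3, np.nan)
        bse = np.full(3, np.nan)
        pvals = np.full(3, np.nan)
    return LogisticResult(
        coef_mutation=float(params[1]),
        se_mutation=float(bse[1]),
        p_mutation=float(pvals[1]),
        coef_tmb_high=float(params[2]),
        se_tmb_high=float(bse[2]),
        p_tmb_high=float(pvals[2]),
        intercept=float(params[0]),
        separation=separation,
        n=len(arr),
    )
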