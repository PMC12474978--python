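"""IPTW survival benchmark: gene strata, weighting, left-truncated Cox/KM.

Patients are stratified per gene by their strongest annotation (known
oncogenic > reclassified pathogenic > reclassified benign > no mutation;
patients whose sequencing panel lacks the gene are excluded).  Because
genomic strata differ systematically in clinical covariates, contrasts are
reweighted by stabilized inverse-probability-of-treatment weights (IPTW)
from a main-effects logistic propensity model, with standardized-mean-
difference balance diagnostics before and after weighting.

Overall survival runs from diagnosis, left-truncated at cohort entry
(first tumor sequencing): a patient joins the risk set only after entry,
which avoids immortal-time bias.  Cox partial-likelihood fits use Breslow
tie handling, per-patient case weights, and a robust sandwich variance
(case weights invalidate the naive information-based variance).  The
per-gene VEP metric is RR, the ratio of the pathogenic-vs-none hazard
ratio to the benign-vs-none hazard ratio, with a patient-level bootstrap
confidence interval re-running both weighted fits per replicate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import bh_adjust
from .types import (
    MutationRecord,
    ONCOGENIC_CLASSES,
    PanelCoverage,
    PathwaySpec,
    PatientRecord,
)

logger = logging.getLogger(__name__)

STRATUM_ORDER = (
    "oncogenic",
    "reclassified_pathogenic",
    "reclassified_benign",
    "no_mutation",
)


@dataclass
class GeneStrata:
    gene: str
    groups: Dict[str, str]  # patient_id -> stratum (or "excluded")

    def patients_in(self, stratum: str) -> List[str]:
        return [pid for pid, g in self.groups.items() if g == stratum]


def assign_gene_strata(
    patients: Sequence[PatientRecord],
    mutations: Sequence[MutationRecord],
    classifications: Mapping[str, str],
    gene: str,
    coverage: Optional[PanelCoverage] = None,
) -> GeneStrata:
    """Assign each patient to one gene-level annotation stratum.

    Precedence for patients carrying several mutation classes in the gene:
    oncogenic > reclassified_pathogenic > reclassified_benign.  VUSs whose
    method classification is uncertain or missing do not promote a patient
    out of no_mutation.  Panel-uncovered patients are 'excluded'.
    """
    best: Dict[str, int] = {}
    rank = {"oncogenic": 0, "reclassified_pathogenic": 1, "reclassified_benign": 2}
    for m in mutations:
        if m.gene != gene:
            continue
        if m.oncokb_class in ONCOGENIC_CLASSES:
            label = "oncogenic"
        else:
            call = classifications.get(m.variant_key)
            if call == "pathogenic":
                label = "reclassified_pathogenic"
            elif call == "benign":
                label = "reclassified_benign"
            else:
                continue
        r = rank[label]
        if r < best.get(m.patient_id, 99):
            best[m.patient_id] = r
    inv = {v: k for k, v in rank.items()}
    groups: Dict[str, str] = {}
    for p in patients:
        if coverage is not None and not coverage.covers(p.panel_id, gene):
            groups[p.patient_id] = "excluded"
            continue
        groups[p.patient_id] = inv.get(best.get(p.patient_id, 99), "no_mutation")
    return GeneStrata(gene=gene, groups=groups)


# ---------------------------------------------------------------------------
# IPTW


@dataclass
class WeightSet:
    weights: pd.Series  # patient_id -> stabilized weight
    balance: pd.DataFrame  # covariate, smd_before, smd_after
    propensity: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def mean_weight(self) -> float:
        return float(self.weights.mean())


class PositivityError(ValueError):
    """A fitted propensity hit 0/1: some covariate pattern has no overlap."""


def _design_matrix(
    patients: Sequence[PatientRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    from .types import patients_to_frame

    frame = patients_to_frame(patients).set_index("patient_id")
    cols = {}
    for name in covariates:
        if name not in frame.columns:
            raise KeyError(f"covariate {name!r} not present on patients")
        col = frame[name]
        if col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            cols[name] = col.astype(float)
    X = pd.DataFrame(cols, index=frame.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}")
    return X


def _smd(X: pd.DataFrame, treated: np.ndarray, w: np.ndarray) -> pd.Series:
    """Weighted standardized mean differences per design column."""
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        w1, w0 = w[treated], w[~treated]
        m1 = np.average(x[treated], weights=w1)
        m0 = np.average(x[~treated], weights=w0)
        v1 = np.average((x[treated] - m1) ** 2, weights=w1)
        v0 = np.average((x[~treated] - m0) ** 2, weights=w0)
        denom = np.sqrt((v1 + v0) / 2.0)
        out[col] = 0.0 if denom == 0 else (m1 - m0) / denom
    return pd.Series(out)


def estimate_iptw(
    patients: Sequence[PatientRecord],
    group_indicator: Mapping[str, bool],
    covariates: Sequence[str],
    truncate_percentile: Optional[float] = None,
) -> WeightSet:
    """Stabilized IPTW for a binary group contrast.

    Propensity comes from a main-effects logistic regression of group
    membership on baseline covariates; stabilized weights are
    ``P(group)/e`` for group members and ``(1-P(group))/(1-e)`` for the
    reference arm, keeping the mean weight near 1.  Optional propensity
    truncation at the given symmetric percentile is off by default.
    """
    import statsmodels.api as sm

    ids = [p.patient_id for p in patients]
    treated = np.array([bool(group_indicator[pid]) for pid in ids])
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need at least 2 patients per arm")
    X = _design_matrix(patients, covariates)
    # drop constant columns: no information, breaks the MLE
    keep = [c for c in X.columns if X[c].nunique() > 1]
    Xk = X[keep]
    design = sm.add_constant(Xk.to_numpy(dtype=float), has_constant="add")
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # separation surfaces as a PositivityError below, not a warning
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            treated.astype(float), design, family=sm.families.Binomial()
        ).fit(maxiter=200)
    e = np.asarray(fit.predict(design), dtype=float)
    if truncate_percentile is not None:
        lo, hi = np.percentile(e, [truncate_percentile, 100 - truncate_percentile])
        e = np.clip(e, lo, hi)
    if np.any(e < 1e-6) or np.any(e > 1 - 1e-6):
        idx = int(np.argmax((e < 1e-6) | (e > 1 - 1e-6)))
        pattern = {c: X.iloc[idx][c] for c in X.columns}
        raise PositivityError(
            f"fitted propensity at 0/1 for covariate pattern {pattern}"
        )
    marginal = treated.mean()
    w = np.where(treated, marginal / e, (1 - marginal) / (1 - e))
    smd_before = _smd(Xk, treated, np.ones(len(w)))
    smd_after = _smd(Xk, treated, w)
    balance = pd.DataFrame(
        {"smd_before": smd_before, "smd_after": smd_after}
    ).rename_axis("covariate")
    ws = WeightSet(
        weights=pd.Series(w, index=pd.Index(ids, name="patient_id")),
        balance=balance,
        propensity=pd.Series(e, index=pd.Index(ids, name="patient_id")),
    )
    if not (0.8 <= ws.mean_weight <= 1.2):
        logger.warning(
            "estimate_iptw: mean stabilized weight %.3f outside [0.8, 1.2]",
            ws.mean_weight,
        )
    return ws


# ---------------------------------------------------------------------------
# Weighted left-truncated Cox partial likelihood


def _cox_newton(
    entry: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton–Raphson for the weighted Breslow partial likelihood.

    Risk set at event time t admits subjects with ``entry < t <= time``
    (delayed entry).  Returns (beta, model covariance, robust covariance).
    """
    n, p = X.shape
    event_times = np.unique(time[event > 0])
    # risk/death masks per distinct event time: E x n booleans
    at_risk = (entry[None, :] < event_times[:, None]) & (
        time[None, :] >= event_times[:, None]
    )
    dies = (time[None, :] == event_times[:, None]) & (event[None, :] > 0)
    wd = (dies * weights[None, :]).sum(axis=1)  # weighted deaths per time
    xd = dies.astype(float) @ (weights[:, None] * X)  # sum of w*X over deaths

    beta = np.zeros(p)
    loglik_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max()  # guard overflow; cancels in ratios
        r = weights * np.exp(eta)
        s0 = at_risk @ r  # E
        s1 = at_risk @ (r[:, None] * X)  # E x p
        xbar = s1 / s0[:, None]
        grad = (xd - wd[:, None] * xbar).sum(axis=0)
        info = np.zeros((p, p))
        for k in range(p):  # S2 accumulated per column pair
            s2_k = at_risk @ (r[:, None] * X * X[:, [k]])  # E x p
            info[k] = (wd[:, None] * (s2_k / s0[:, None])).sum(axis=0)
        info -= (wd[:, None, None] * (xbar[:, :, None] * xbar[:, None, :])).sum(
            axis=0
        )
        loglik = float((dies * (weights * eta)[None, :]).sum() - (wd * np.log(s0)).sum())
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix in Cox fit") from exc
        # step-halving keeps the likelihood monotone
        alpha = 1.0
        while alpha > 1e-4:
            cand = beta + alpha * step
            eta_c = X @ cand
            eta_c -= eta_c.max()
            r_c = weights * np.exp(eta_c)
            s0_c = at_risk @ r_c
            ll_c = float(
                (dies * (weights * eta_c)[None, :]).sum() - (wd * np.log(s0_c)).sum()
            )
            if ll_c >= loglik - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if np.max(np.abs(beta)) > 20:
            # monotone partial likelihood (e.g. a lone carrier dying first):
            # no finite maximizer exists
            raise ValueError("no finite Cox estimate (monotone likelihood)")
        if abs(ll_c - loglik_prev) < tol and np.max(np.abs(alpha * step)) < 1e-12:
            break
        loglik_prev = ll_c

    # final quantities at the solution
    eta = X @ beta
    eta -= eta.max()
    r = weights * np.exp(eta)
    s0 = at_risk @ r
    s1 = at_risk @ (r[:, None] * X)
    xbar = s1 / s0[:, None]
    info = np.zeros((p, p))
    for k in range(p):
        s2_k = at_risk @ (r[:, None] * X * X[:, [k]])
        info[k] = (wd[:, None] * (s2_k / s0[:, None])).sum(axis=0)
    info -= (wd[:, None, None] * (xbar[:, :, None] * xbar[:, None, :])).sum(axis=0)
    cov = np.linalg.inv(info)

    # score residuals for the sandwich variance (Lin-Wei with case weights)
    # U_i = d_i (X_i - xbar(t_i)) - exp(eta_i) * sum_{t_k in (entry_i, t_i]}
    #          (wd_k / s0_k) (X_i - xbar(t_k))
    d_term = np.zeros((n, p))
    ev_idx = {t: i for i, t in enumerate(event_times)}
    for i in np.nonzero(event > 0)[0]:
        d_term[i] = X[i] - xbar[ev_idx[time[i]]]
    ratio = wd / s0  # E
    # cumulative pieces: for subject i, sum over event times where i at risk
    at_risk_f = at_risk.astype(float)
    cum0 = at_risk_f.T @ ratio  # n
    cum1 = at_risk_f.T @ (ratio[:, None] * xbar)  # n x p
    exp_eta = np.exp(eta)
    U = d_term - exp_eta[:, None] * (X * cum0[:, None] - cum1)
    Uw = weights[:, None] * U
    robust = cov @ (Uw.T @ Uw) @ cov
    return beta, cov, robust


@dataclass
class CoxResult:
    gene: str
    contrast: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_group: int
    n_ref: int
    weighted: bool
    log_hr: float
    se: float
    q: Optional[float] = None


def weighted_cox(
    patients: Sequence[PatientRecord],
    group_indicator: Mapping[str, bool],
    weights: Optional[Mapping[str, float]] = None,
    gene: str = "",
    contrast: str = "group_vs_ref",
    robust: bool = True,
) -> CoxResult:
    """Weighted, left-truncated Cox fit of a binary group contrast.

    Time origin is diagnosis; a patient enters the risk set at ``t_entry``
    and leaves at ``t_end``.  The confidence interval uses the robust
    sandwich variance by default (required once IPTW case weights enter).
    """
    ids = [p.patient_id for p in patients]
    g = np.array([bool(group_indicator[pid]) for pid in ids])
    if g.all() or (~g).all():
        raise ValueError("both arms must be non-empty")
    entry = np.array([p.t_entry - p.t_dx for p in patients], dtype=float)
    time = np.array([p.t_end - p.t_dx for p in patients], dtype=float)
    event = np.array([int(p.event) for p in patients], dtype=float)
    if event.sum() == 0:
        raise ValueError("no events observed")
    w = (
        np.ones(len(ids))
        if weights is None
        else np.array([float(weights[pid]) for pid in ids])
    )
    beta, cov, robust_cov = _cox_newton(entry, time, event, g.astype(float)[:, None], w)
    var = (robust_cov if robust else cov)[0, 0]
    se = float(np.sqrt(var))
    z = norm.ppf(0.975)
    log_hr = float(beta[0])
    p_val = float(2 * norm.sf(abs(log_hr / se))) if se > 0 else float("nan")
    return CoxResult(
        gene=gene,
        contrast=contrast,
        hr=float(np.exp(log_hr)),
        ci_low=float(np.exp(log_hr - z * se)),
        ci_high=float(np.exp(log_hr + z * se)),
        p=p_val,
        n_group=int(g.sum()),
        n_ref=int((~g).sum()),
        weighted=weights is not None,
        log_hr=log_hr,
        se=se,
    )


# ---------------------------------------------------------------------------
# RR metric


@dataclass
class RRResult:
    gene: str
    rr: float
    ci_low: float
    ci_high: float
    hr_pathogenic: float
    hr_benign: float
    n_bootstrap: int
    n_dropped: int


def rr_survival(
    cox_pathogenic: CoxResult,
    cox_benign: CoxResult,
    refit: Callable[[np.random.Generator], Optional[Tuple[float, float]]],
    bootstrap_b: int = 200,
    seed: int = 0,
) -> RRResult:
    """RR = HR(pathogenic vs none) / HR(benign vs none), bootstrap CI.

    *refit* draws one patient-level bootstrap resample and re-runs both
    weighted fits, returning (hr_pathogenic, hr_benign) or ``None`` for a
    degenerate replicate (e.g. an empty arm).  More than 20% dropped
    replicates is an error.
    """
    if cox_pathogenic.gene != cox_benign.gene:
        raise ValueError("contrasts must concern the same gene")
    rr = cox_pathogenic.hr / cox_benign.hr
    rng = np.random.default_rng(seed)
    draws: List[float] = []
    n_dropped = 0
    for _ in range(bootstrap_b):
        try:
            pair = refit(rng)
        except (ValueError, np.linalg.LinAlgError):
            pair = None
        if pair is None or not np.isfinite(pair[0]) or not np.isfinite(pair[1]):
            n_dropped += 1
            continue
        draws.append(pair[0] / pair[1])
    if n_dropped > 0.2 * bootstrap_b:
        raise ValueError(
            f"{n_dropped}/{bootstrap_b} bootstrap replicates dropped (> 20%)"
        )
    if n_dropped:
        logger.warning("rr_survival: dropped %d bootstrap replicates", n_dropped)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RRResult(
        gene=cox_pathogenic.gene,
        rr=float(rr),
        ci_low=float(lo),
        ci_high=float(hi),
        hr_pathogenic=cox_pathogenic.hr,
        hr_benign=cox_benign.hr,
        n_bootstrap=len(draws),
        n_dropped=n_dropped,
    )


def gene_rr_analysis(
    patients: Sequence[PatientRecord],
    strata: GeneStrata,
    covariates: Sequence[str],
    bootstrap_b: int = 200,
    seed: int = 0,
    use_iptw: bool = True,
) -> Tuple[CoxResult, CoxResult, RRResult]:
    """Fit both reclassified contrasts for one gene and the RR metric.

    Each contrast (pathogenic vs no-mutation, benign vs no-mutation) gets
    its own IPTW fit; the bootstrap resamples patients within the contrast
    cohort and repeats weighting + Cox per replicate.
    """
    by_id = {p.patient_id: p for p in patients}

    def _contrast_cohort(stratum: str) -> Tuple[List[PatientRecord], Dict[str, bool]]:
        cohort = []
        indicator = {}
        for pid, grp in strata.groups.items():
            if grp == stratum:
                cohort.append(by_id[pid])
                indicator[pid] = True
            elif grp == "no_mutation":
                cohort.append(by_id[pid])
                indicator[pid] = False
        return cohort, indicator

    def _fit(
        cohort: Sequence[PatientRecord], indicator: Mapping[str, bool], contrast: str
    ) -> CoxResult:
        if use_iptw:
            ws = estimate_iptw(cohort, indicator, covariates)
            weights = ws.weights.to_dict()
        else:
            weights = None
        return weighted_cox(
            cohort, indicator, weights, gene=strata.gene, contrast=contrast
        )

    cohort_p, ind_p = _contrast_cohort("reclassified_pathogenic")
    cohort_b, ind_b = _contrast_cohort("reclassified_benign")
    cox_p = _fit(cohort_p, ind_p, "reclassified_pathogenic_vs_no_mutation")
    cox_b = _fit(cohort_b, ind_b, "reclassified_benign_vs_no_mutation")

    def refit(rng: np.random.Generator) -> Optional[Tuple[float, float]]:
        out = []
        for cohort, indicator, contrast in (
            (cohort_p, ind_p, "p"),
            (cohort_b, ind_b, "b"),
        ):
            idx = rng.integers(0, len(cohort), size=len(cohort))
            resample = [cohort[i] for i in idx]
            # re-key duplicated patients so weights stay per-row
            rows = []
            ind = {}
            for j, pat in enumerate(resample):
                clone = PatientRecord(
                    patient_id=f"{pat.patient_id}#{j}",
                    cohort_id=pat.cohort_id,
                    panel_id=pat.panel_id,
                    covariates=dict(pat.covariates),
                    tmb=pat.tmb,
                    msi_score=pat.msi_score,
                    t_dx=pat.t_dx,
                    t_entry=pat.t_entry,
                    t_end=pat.t_end,
                    event=pat.event,
                )
                rows.append(clone)
                ind[clone.patient_id] = indicator[pat.patient_id]
            vals = np.array(list(ind.values()))
            if vals.sum() < 2 or (~vals).sum() < 2 or not any(
                r.event for r in rows
            ):
                return None
            out.append(_fit(rows, ind, contrast).hr)
        return out[0], out[1]

    rr = rr_survival(cox_p, cox_b, refit, bootstrap_b=bootstrap_b, seed=seed)
    return cox_p, cox_b, rr


# ---------------------------------------------------------------------------
# Weighted Kaplan-Meier


def weighted_km(
    strata: Mapping[str, Sequence[PatientRecord]],
    weights: Optional[Mapping[str, float]] = None,
    min_stratum: int = 10,
) -> Dict[str, pd.DataFrame]:
    """Weighted product-limit curves per stratum, left-truncated at entry.

    Strata with fewer than *min_stratum* patients are dropped with a
    warning; survival steps use weighted event and at-risk counts, so the
    curve is invariant to rescaling every weight.
    """
    out: Dict[str, pd.DataFrame] = {}
    for name, pats in strata.items():
        if len(pats) < min_stratum:
            logger.warning(
                "weighted_km: stratum %r dropped (%d < %d patients)",
                name,
                len(pats),
                min_stratum,
            )
            continue
        entry = np.array([p.t_entry - p.t_dx for p in pats])
        time = np.array([p.t_end - p.t_dx for p in pats])
        event = np.array([int(p.event) for p in pats])
        w = (
            np.ones(len(pats))
            if weights is None
            else np.array([float(weights[p.patient_id]) for p in pats])
        )
        times = np.unique(time[event > 0])
        surv = 1.0
        rows = []
        for t in times:
            at_risk = (entry < t) & (time >= t)
            nw = float(w[at_risk].sum())
            dw = float(w[(time == t) & (event > 0)].sum())
            if nw <= 0:
                continue
            surv *= 1.0 - dw / nw
            rows.append({"time": float(t), "survival": surv, "at_risk": nw})
        out[name] = pd.DataFrame(rows, columns=["time", "survival", "at_risk"])
    if not out:
        raise ValueError("all strata dropped (below minimum size)")
    return out


# ---------------------------------------------------------------------------
# Double-mutant analysis


@dataclass
class DoubleMutantResult:
    gene_a: str
    gene_b: str
    strata_sizes: Dict[str, int]
    km: Dict[str, pd.DataFrame]
    cox: Dict[str, CoxResult]
    n_excluded_oncogenic: int


def double_mutant_analysis(
    gene_a: str,
    gene_b: str,
    classifications: Mapping[str, str],
    patients: Sequence[PatientRecord],
    mutations: Sequence[MutationRecord],
    covariates: Optional[Sequence[str]] = None,
    min_stratum: int = 10,
) -> DoubleMutantResult:
    """Joint prognosis of reclassified-pathogenic mutations in two genes.

    Patients carrying a known-oncogenic mutation in either gene are
    excluded; the rest fall in {double, A_only, B_only, neither} by their
    reclassified-pathogenic carrier status.  Each stratum gets a weighted
    KM curve and a Cox contrast vs 'neither' (IPTW when covariates are
    given); contrasts under *min_stratum* are skipped and logged.
    """
    onco = {
        m.patient_id
        for m in mutations
        if m.gene in (gene_a, gene_b) and m.oncokb_class in ONCOGENIC_CLASSES
    }
    carriers = {gene_a: set(), gene_b: set()}
    for m in mutations:
        if m.gene in carriers and m.oncokb_class not in ONCOGENIC_CLASSES:
            if classifications.get(m.variant_key) == "pathogenic":
                carriers[m.gene].add(m.patient_id)
    strata: Dict[str, List[PatientRecord]] = {
        "double": [],
        f"{gene_a}_only": [],
        f"{gene_b}_only": [],
        "neither": [],
    }
    for p in patients:
        if p.patient_id in onco:
            continue
        a = p.patient_id in carriers[gene_a]
        b = p.patient_id in carriers[gene_b]
        if a and b:
            strata["double"].append(p)
        elif a:
            strata[f"{gene_a}_only"].append(p)
        elif b:
            strata[f"{gene_b}_only"].append(p)
        else:
            strata["neither"].append(p)
    cox: Dict[str, CoxResult] = {}
    weights_all: Dict[str, float] = {}
    for name in ("double", f"{gene_a}_only", f"{gene_b}_only"):
        if len(strata[name]) < min_stratum:
            logger.warning(
                "double_mutant_analysis: contrast %r skipped (%d patients)",
                name,
                len(strata[name]),
            )
            continue
        cohort = strata[name] + strata["neither"]
        indicator = {p.patient_id: (p in strata[name]) for p in cohort}
        if covariates:
            ws = estimate_iptw(cohort, indicator, covariates)
            weights = ws.weights.to_dict()
            weights_all.update(weights)
        else:
            weights = None
        try:
            cox[name] = weighted_cox(
                cohort,
                indicator,
                weights,
                gene=f"{gene_a}/{gene_b}",
                contrast=f"{name}_vs_neither",
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning(
                "double_mutant_analysis: contrast %r skipped (%s)", name, exc
            )
    km = weighted_km(strata, weights_all or None, min_stratum=min_stratum)
    return DoubleMutantResult(
        gene_a=gene_a,
        gene_b=gene_b,
        strata_sizes={k: len(v) for k, v in strata.items()},
        km=km,
        cox=cox,
        n_excluded_oncogenic=len(onco & {p.patient_id for p in patients}),
    )


# ---------------------------------------------------------------------------
# Discovery / confirmation FDR logic


@dataclass
class DiscoveryConfirmationReport:
    discovery: List[CoxResult]
    discovery_significant: List[CoxResult]
    confirmation: List[CoxResult]
    fdr: float


def discovery_confirmation(
    discovery_results: Sequence[CoxResult],
    confirmation_fit: Optional[Callable[[CoxResult], Optional[CoxResult]]] = None,
    fdr: float = 0.1,
) -> DiscoveryConfirmationReport:
    """Two-stage FDR: BH on the full discovery family, then re-test hits.

    Only discovery-significant contrasts are fit in the confirmation
    cohort, and confirmation q-values are BH over that reduced family
    only.  An empty discovery-significant set skips confirmation.
    """
    discovery = list(discovery_results)
    qs = bh_adjust([r.p for r in discovery])
    for r, q in zip(discovery, qs):
        r.q = float(q)
    hits = [r for r in discovery if r.q is not None and r.q <= fdr]
    confirmation: List[CoxResult] = []
    if not hits:
        logger.info("discovery_confirmation: no discovery hits; skipped")
    elif confirmation_fit is not None:
        for r in hits:
            conf = confirmation_fit(r)
            if conf is not None:
                confirmation.append(conf)
        cqs = bh_adjust([r.p for r in confirmation])
        for r, q in zip(confirmation, cqs):
            r.q = float(q)
    return DiscoveryConfirmationReport(
        discovery=discovery,
        discovery_significant=hits,
        confirmation=confirmation,
        fdr=fdr,
    )
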