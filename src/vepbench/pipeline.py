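"""End-to-end orchestration: simulate -> calibrate -> benchmarks -> ensemble.

The pipeline mirrors the study design: learn per-method cutoffs against a
known-driver vs negative-control classification task, reclassify VUSs,
then score every method on four benchmarks — driver-rediscovery ROC,
binding-residue enrichment (OR_binding), IPTW survival (hazard ratios and
the RR metric), and pathway mutual exclusivity — plus a random-forest
ensemble over the per-method scores.  All outputs are TSVs with fixed
column order plus a JSON manifest, and a fixed seed reproduces every file.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import binding as binding_mod
from . import calibration as calib_mod
from . import ensemble as ensemble_mod
from . import mutex as mutex_mod
from . import roc as roc_mod
from . import survival as surv_mod
from .sbs96 import estimate_context_profile, select_annotation_rich_negatives
from .simulate import SimConfig, SimulatedCohort, default_config, generate_cohort
from .types import (
    MethodSpec,
    ONCOGENIC_CLASSES,
    filter_panel,
    derive_clinical_flags,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path = Path("results")
    seed: int = 0
    n_patients: int = 2000
    benchmarks: Tuple[str, ...] = ("roc", "binding", "survival", "mutex", "ensemble")
    survival_genes: Tuple[str, ...] = ("KEAP1", "STK11", "SMARCA4")
    bootstrap_b: int = 60
    fdr_roc: float = 0.05
    fdr_survival: float = 0.1
    fdr_mutex: float = 0.1
    fdr_binding: float = 0.1
    sim_config: Optional[SimConfig] = None


def calibrate_methods(
    cohort: SimulatedCohort, n_negatives: int = 500
) -> Tuple[Dict[str, Dict[str, str]], pd.DataFrame]:
    """Learn per-method cutoffs and classify every VUS.

    Positives are known-oncogenic variants; negatives an annotation-rich
    subset of never-oncogenic variants (the stand-in for a curated
    no-medical-impact polymorphism set).  Returns per-method maps
    variant_key -> {pathogenic, benign, missing} over VUS keys, plus the
    calibration report.
    """
    scores = cohort.scores
    onco_keys = sorted(
        {
            m.variant_key
            for m in cohort.mutations
            if m.oncokb_class in ONCOGENIC_CLASSES
        }
    )
    vus_keys = [k for k in scores.variant_keys if k not in set(onco_keys)]
    k = min(n_negatives, len(vus_keys))
    neg_keys = select_annotation_rich_negatives(vus_keys, scores, k)
    report = calib_mod.CalibrationReport()
    classifications: Dict[str, Dict[str, str]] = {}
    for spec in cohort.config.method_specs():
        col = scores.scores(spec.name)
        pos = col.loc[[k for k in onco_keys if not np.isnan(col.get(k, np.nan))]]
        neg = col.loc[[k for k in neg_keys if not np.isnan(col.get(k, np.nan))]]
        cut = calib_mod.youden_cutpoint(
            pos.to_numpy(), neg.to_numpy(), spec.orientation, method=spec.name
        )
        report.add(spec, cut)
        full = calib_mod.classify_variants(scores, spec, cutpoint=cut)
        classifications[spec.name] = {key: full[key] for key in vus_keys}
    return classifications, report.to_frame()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = config.sim_config or default_config(
        n_patients=config.n_patients, seed=config.seed
    )
    cohort = generate_cohort(sim_config)
    manifest: Dict[str, object] = {
        "seed": config.seed,
        "n_patients": sim_config.n_patients,
        "n_mutations": len(cohort.mutations),
        "methods": [m.name for m in sim_config.methods],
        "benchmarks": list(config.benchmarks),
        "outputs": [],
        "assumptions": [
            "multi-sample patients: union of mutations over samples",
            "stratum precedence oncogenic > reclassified_pathogenic > "
            "reclassified_benign",
            "OR_binding computed at mutation level over mapped genes",
        ],
    }

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    classifications, calib_report = calibrate_methods(cohort)
    _write(calib_report, "calibration.tsv")

    method_names = [m.name for m in sim_config.methods]
    scores = cohort.scores

    if "roc" in config.benchmarks:
        onco_mut = [
            m
            for m in cohort.mutations
            if m.oncokb_class in ONCOGENIC_CLASSES and m.is_missense
        ]
        pos_instances = roc_mod.build_instances(onco_mut, level="population")
        truth = cohort.truth.variant_class.set_index("variant_key")["latent_class"]
        neg_pool = sorted(
            k for k in scores.variant_keys if truth.get(k) == "passenger"
        )
        neg_instances = roc_mod.upsample_negatives(
            neg_pool, len(pos_instances), seed=config.seed
        )
        rows = []
        scores_by_method = {}
        labels = [1] * len(pos_instances) + [0] * len(neg_instances)
        for name in method_names:
            col = scores.scores(name)
            spec = next(m for m in sim_config.methods if m.name == name)
            sign = 1.0 if spec.orientation == "higher_pathogenic" else -1.0
            pos_s = np.array([col.get(k, np.nan) for k in pos_instances]) * sign
            neg_s = np.array([col.get(k, np.nan) for k in neg_instances]) * sign
            # median-impute missing scores so instance sets stay identical
            fill = np.nanmedian(np.concatenate([pos_s, neg_s]))
            pos_s = np.where(np.isnan(pos_s), fill, pos_s)
            neg_s = np.where(np.isnan(neg_s), fill, neg_s)
            res = roc_mod.auroc_delong(pos_s, neg_s, method=name)
            rows.append(
                {
                    "method": name,
                    "stratum": "all",
                    "level": "population",
                    "auroc": res.auroc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                }
            )
            scores_by_method[name] = np.concatenate([pos_s, neg_s])
        _write(pd.DataFrame(rows), "roc_results.tsv")
        comparisons = roc_mod.compare_methods(scores_by_method, labels)
        _write(
            pd.DataFrame(
                [
                    {
                        "method_a": c.method_a,
                        "method_b": c.method_b,
                        "delta_auc": c.delta_auc,
                        "ci_low": c.ci_low,
                        "ci_high": c.ci_high,
                        "p": c.p,
                        "q": c.q,
                    }
                    for c in comparisons
                ]
            ),
            "roc_comparisons.tsv",
        )
        manifest["roc_best_method"] = max(
            rows, key=lambda r: r["auroc"]
        )["method"]

    if "binding" in config.benchmarks:
        vus_mut = [
            m
            for m in cohort.mutations
            if m.oncokb_class not in ONCOGENIC_CLASSES and m.is_missense
        ]
        part = binding_mod.partition_binding(vus_mut, cohort.binding_map)
        results = []
        for name in method_names:
            try:
                res = binding_mod.or_binding(
                    classifications[name], part, group=name
                )
            except ValueError as exc:
                logger.warning("binding benchmark: %s skipped (%s)", name, exc)
                continue
            results.append(res)
        binding_mod.enrichment_battery(results)
        _write(
            pd.DataFrame(
                [
                    {
                        "method": r.group,
                        "a": r.a,
                        "b": r.b,
                        "c": r.c,
                        "d": r.d,
                        "or": r.or_point,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p": r.p,
                        "q": r.q,
                    }
                    for r in results
                ]
            ),
            "binding_or.tsv",
        )

    if "survival" in config.benchmarks:
        covariates = ["age", "male", "stage_iv", "smoker", "tmb"]
        rows = []
        rr_rows = []
        for gene in config.survival_genes:
            cohort_patients = filter_panel(
                cohort.patients, cohort.coverage, gene
            )
            for name in method_names:
                strata = surv_mod.assign_gene_strata(
                    cohort_patients,
                    cohort.mutations,
                    classifications[name],
                    gene,
                )
                try:
                    cox_p, cox_b, rr = surv_mod.gene_rr_analysis(
                        cohort_patients,
                        strata,
                        covariates,
                        bootstrap_b=config.bootstrap_b,
                        seed=config.seed,
                    )
                except ValueError as exc:
                    logger.warning(
                        "survival: %s/%s skipped (%s)", gene, name, exc
                    )
                    continue
                for cox in (cox_p, cox_b):
                    rows.append(
                        {
                            "gene": gene,
                            "method": name,
                            "contrast": cox.contrast,
                            "hr": cox.hr,
                            "ci_low": cox.ci_low,
                            "ci_high": cox.ci_high,
                            "p": cox.p,
                            "n_group": cox.n_group,
                            "n_ref": cox.n_ref,
                        }
                    )
                rr_rows.append(
                    {
                        "gene": gene,
                        "method": name,
                        "rr": rr.rr,
                        "ci_low": rr.ci_low,
                        "ci_high": rr.ci_high,
                        "hr_pathogenic": rr.hr_pathogenic,
                        "hr_benign": rr.hr_benign,
                    }
                )
        surv_frame = pd.DataFrame(rows)
        if not surv_frame.empty:
            surv_frame["q"] = calib_mod.bh_adjust(surv_frame["p"].tolist())
        _write(surv_frame, "survival_cox.tsv")
        _write(pd.DataFrame(rr_rows), "survival_rr.tsv")

    if "mutex" in config.benchmarks:
        mutex_results = []
        for pw in cohort.pathways:
            for gene in pw.genes:
                gene_patients = filter_panel(
                    cohort.patients, cohort.coverage, gene
                )
                for name in method_names:
                    table = mutex_mod.build_mutex_table(
                        gene,
                        pw,
                        classifications[name],
                        gene_patients,
                        cohort.mutations,
                    )
                    res = mutex_mod.mutex_fisher(
                        table, gene=gene, pathway=pw.name, fdr=config.fdr_mutex
                    )
                    if res is not None:
                        res.method = name
                        mutex_results.append(res)
        mutex_mod.mutex_battery(mutex_results)
        _write(
            pd.DataFrame(
                [
                    {
                        "method": getattr(r, "method", ""),
                        "pathway": r.pathway,
                        "gene": r.gene,
                        "a": r.table[0][0],
                        "b": r.table[0][1],
                        "c": r.table[1][0],
                        "d": r.table[1][1],
                        "log_or": r.log_or,
                        "p": r.p,
                        "q": r.q,
                        "significant": r.significant,
                    }
                    for r in mutex_results
                ]
            ),
            "mutex_tests.tsv",
        )
        rate_rows = []
        for pw in cohort.pathways:
            for name in method_names:
                sub = [
                    r
                    for r in mutex_results
                    if r.pathway == pw.name and getattr(r, "method", "") == name
                ]
                rate_rows.append(
                    {
                        "pathway": pw.name,
                        "method": name,
                        "rate": mutex_mod.pathway_rate(sub, pw),
                    }
                )
        _write(pd.DataFrame(rate_rows), "mutex_rates.tsv")

    if "ensemble" in config.benchmarks:
        truth = cohort.truth.variant_class.set_index("variant_key")["latent_class"]
        onco_keys = sorted(
            {
                m.variant_key
                for m in cohort.mutations
                if m.oncokb_class in ONCOGENIC_CLASSES
            }
        )
        neg_keys = sorted(k for k in scores.variant_keys if truth.get(k) == "passenger")
        frame = scores.frame.loc[onco_keys + neg_keys].dropna()
        y = pd.Series(
            [1] * len(onco_keys) + [0] * len(neg_keys),
            index=onco_keys + neg_keys,
        ).loc[frame.index]
        tr, te = ensemble_mod.split_train_test(
            frame.index, y.to_numpy(), seed=config.seed
        )
        train_std, test_std, _ = ensemble_mod.zscore_preprocess(
            frame.iloc[tr], frame.iloc[te]
        )
        model, cv_result = ensemble_mod.train_ensemble(
            train_std,
            y.iloc[tr].to_numpy(),
            cv_scheme="kfold5",
            n_trees=200,
            seed=config.seed,
        )
        best = manifest.get("roc_best_method", method_names[0])
        spec = next(m for m in sim_config.methods if m.name == best)
        sign = 1.0 if spec.orientation == "higher_pathogenic" else -1.0
        baseline = (scores.scores(best) * sign).to_dict()
        test_result, comparison = ensemble_mod.evaluate_and_compare(
            model,
            test_std,
            y.iloc[te].to_numpy(),
            baseline_scores=baseline,
            baseline_name=best,
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "cv_scheme": cv_result.cv_scheme,
                        "mtry": cv_result.mtry,
                        "cv_auroc": cv_result.auroc,
                        "test_auroc": test_result.auroc,
                        "accuracy": test_result.accuracy,
                        "sensitivity": test_result.sensitivity,
                        "specificity": test_result.specificity,
                        "delta_auc_vs_best": None
                        if comparison is None
                        else comparison.delta_auc,
                        "p_vs_best": None if comparison is None else comparison.p,
                    }
                ]
            ),
            "ensemble_metrics.tsv",
        )
        manifest["ensemble_importances"] = cv_result.importances

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
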