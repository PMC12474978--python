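"""Synthetic tumor-cohort generator with known ground truth.

Emulates the statistical structure of a panel-sequenced cancer cohort so
every benchmark is testable without restricted downloads:

* per-gene mutation prevalence with oncogene/TSG roles and a latent
  driver/passenger class behind every VUS;
* class-conditional VEP scores (Beta-distributed on [0, 1], reflected for
  lower-is-pathogenic methods) with per-method missingness;
* confounded survival: covariates that raise mutation odds also shift the
  exponential baseline hazard, and each gene-class carries its own log
  hazard ratio — the IPTW pipeline must undo the confounding;
* binding-residue enrichment among latent drivers at a configured odds
  ratio;
* within-pathway mutual exclusivity at a configured odds ratio, induced
  exactly (per patient, conditional on covariates) by coupling the focal
  gene's driver indicator to the rest of the pathway through the Plackett
  2x2 construction;
* left truncation: patients enter at a sequencing time after diagnosis,
  and survival is drawn conditional on surviving to entry.

All randomness flows from one seed through named substreams
(``SeedSequence(seed, spawn_key=...)``), so components are independent and
extending the cohort does not perturb earlier draws.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sbs96 import SBS96_CATEGORIES, revcomp
from .types import (
    BindingResidueMap,
    MethodSpec,
    MutationRecord,
    PanelCoverage,
    PathwaySpec,
    PatientRecord,
    ScoreMatrix,
)

logger = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"

#: (location, scale) used to standardize covariates before applying
#: confounding effects, so effect sizes read per-SD (binary raw 0/1)
COVARIATE_SCALES = {
    "age": (65.0, 10.0),
    "male": (0.0, 1.0),
    "stage_iv": (0.0, 1.0),
    "smoker": (0.0, 1.0),
    "tmb": (6.0, 4.0),
}


@dataclass(frozen=True)
class GeneSimConfig:
    """Per-gene generative parameters.

    ``p_mut`` is the per-patient probability of any mutation in the gene;
    ``frac_oncogenic`` the fraction of mutated patients whose mutation is
    a known (OncoKB-style) oncogenic variant; ``pathogenic_vus_frac`` the
    latent-driver fraction among the remaining VUSs.  The three log hazard
    ratios act additively on the per-patient log hazard.
    """

    symbol: str
    role: str = "other"
    p_mut: float = 0.1
    frac_oncogenic: float = 0.4
    pathogenic_vus_frac: float = 0.4
    loghr_oncogenic: float = 0.0
    loghr_pathogenic_vus: float = 0.0
    loghr_benign_vus: float = 0.0


@dataclass(frozen=True)
class MethodSimConfig:
    """Class-conditional score distributions for one simulated VEP."""

    name: str
    orientation: str = "higher_pathogenic"
    benign_beta: Tuple[float, float] = (2.0, 6.0)
    pathogenic_beta: Tuple[float, float] = (6.0, 2.0)
    missing_rate: float = 0.0


@dataclass(frozen=True)
class PathwaySimConfig:
    """A pathway and the driver-exclusivity odds ratio it induces.

    The first listed gene is the focal gene: its driver indicator is
    coupled to 'any driver in the other pathway genes' at the given odds
    ratio, conditional on covariates.
    """

    name: str
    genes: Tuple[str, ...]
    exclusivity_or: float = 1.0


@dataclass
class SimConfig:
    n_patients: int = 2000
    seed: int = 0
    genes: Tuple[GeneSimConfig, ...] = ()
    methods: Tuple[MethodSimConfig, ...] = ()
    pathways: Tuple[PathwaySimConfig, ...] = ()
    binding_enrichment_or: float = 5.0
    binding_fraction: float = 0.1
    context_profile: Optional[np.ndarray] = None  # None -> uniform SBS96
    confounding: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    baseline_hazard: float = 0.03  # events per month
    censor_horizon: float = 60.0  # months from diagnosis
    entry_max: float = 6.0  # latest sequencing time, months from diagnosis
    protein_length: int = 400
    n_hotspots: int = 8
    n_pathogenic_pool: int = 60
    n_benign_pool: int = 120
    panel_missing_genes: Tuple[str, ...] = ()
    panel_b_fraction: float = 0.2

    def validate(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate gene symbols in config")
        for g in self.genes:
            for prob in (g.p_mut, g.frac_oncogenic, g.pathogenic_vus_frac):
                if not 0 <= prob <= 1:
                    raise ValueError(f"probability out of [0,1] for {g.symbol}")
        known = set(symbols)
        focal_seen = set()
        for pw in self.pathways:
            for gene in pw.genes:
                if gene not in known:
                    raise ValueError(
                        f"pathway {pw.name!r} references unknown gene {gene!r}"
                    )
            if pw.genes[0] in focal_seen:
                raise ValueError(
                    f"gene {pw.genes[0]!r} is focal in more than one pathway"
                )
            focal_seen.add(pw.genes[0])
            if pw.exclusivity_or <= 0:
                raise ValueError("exclusivity odds ratio must be > 0")
        if self.binding_enrichment_or <= 0:
            raise ValueError("binding_enrichment_or must be > 0")
        for m in self.methods:
            if not 0 <= m.missing_rate <= 1:
                raise ValueError(f"missing_rate out of [0,1] for {m.name}")
        if self.context_profile is not None:
            p = np.asarray(self.context_profile, dtype=float)
            if p.shape != (96,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("context_profile must be 96 probabilities summing to 1")

    def method_specs(self) -> List[MethodSpec]:
        return [
            MethodSpec(name=m.name, orientation=m.orientation) for m in self.methods
        ]


def default_config(n_patients: int = 2000, seed: int = 0) -> SimConfig:
    """An NSCLC-like study configuration.

    Mutation prevalences follow the familiar ranking of lung
    adenocarcinoma panels (TP53 ~ 45%, KRAS ~ 25%, KEAP1/STK11 ~ 15%);
    KEAP1/STK11/SMARCA4 drivers carry hazard ratios near 2, the magnitude
    reported for these genes in lung cohorts, while benign VUSs carry
    none.  Smoking, age and TMB confound both mutation odds and hazard.
    Simulated methods span strong ('am'-grade) to mediocre discriminators
    in both score orientations.
    """
    ln2 = float(np.log(2.0))
    genes = (
        GeneSimConfig("TP53", "TSG", 0.45, 0.6, 0.4, 0.25, 0.25, 0.0),
        GeneSimConfig("KRAS", "OG", 0.25, 0.85, 0.3, 0.30, 0.30, 0.0),
        GeneSimConfig("EGFR", "OG", 0.15, 0.8, 0.3, -0.20, -0.20, 0.0),
        GeneSimConfig("KEAP1", "TSG", 0.17, 0.25, 0.5, ln2, ln2, 0.0),
        GeneSimConfig("STK11", "TSG", 0.15, 0.4, 0.5, 0.50, 0.50, 0.0),
        GeneSimConfig("SMARCA4", "TSG", 0.08, 0.3, 0.5, 0.50, 0.50, 0.0),
        GeneSimConfig("NFE2L2", "OG", 0.05, 0.7, 0.3, 0.30, 0.30, 0.0),
        GeneSimConfig("CUL3", "TSG", 0.04, 0.4, 0.4, 0.20, 0.20, 0.0),
        GeneSimConfig("NF1", "TSG", 0.12, 0.5, 0.4, 0.10, 0.10, 0.0),
        GeneSimConfig("ERBB4", "OG", 0.06, 0.2, 0.3, 0.0, 0.0, 0.0),
        GeneSimConfig("IRS2", "OG", 0.04, 0.2, 0.3, 0.0, 0.0, 0.0),
    )
    methods = (
        MethodSimConfig("am", "higher_pathogenic", (2.0, 8.0), (8.0, 2.0), 0.02),
        MethodSimConfig("revel", "higher_pathogenic", (2.0, 6.0), (7.0, 2.5), 0.05),
        MethodSimConfig("cadd", "higher_pathogenic", (3.0, 5.0), (5.0, 3.0), 0.02),
        MethodSimConfig("esm", "lower_pathogenic", (2.5, 6.0), (6.0, 2.5), 0.05),
        MethodSimConfig("fathmm", "lower_pathogenic", (3.0, 6.0), (6.0, 3.0), 0.10),
        MethodSimConfig("sift", "lower_pathogenic", (3.5, 5.0), (5.0, 3.5), 0.02),
    )
    pathways = (
        PathwaySimConfig("NRF2", ("KEAP1", "NFE2L2", "CUL3"), 0.25),
        PathwaySimConfig("RTK_RAS", ("KRAS", "EGFR", "NF1", "ERBB4", "IRS2"), 0.4),
        PathwaySimConfig("TP53_PW", ("TP53",), 1.0),
    )
    return SimConfig(
        n_patients=n_patients,
        seed=seed,
        genes=genes,
        methods=methods,
        pathways=pathways,
        binding_enrichment_or=5.0,
        confounding={"smoker": (1.2, 0.7), "age": (0.3, 0.3), "tmb": (0.6, 0.4)},
        panel_missing_genes=("IRS2",),
    )


def iptw_benchmark_config(n_patients: int = 2000, seed: int = 0) -> SimConfig:
    """The confounded survival-recovery scenario.

    One gene of interest carries a true hazard ratio of 2.0 for both its
    oncogenic variants and its latent-pathogenic VUSs; smoking, age and
    TMB raise both mutation odds and hazard, inflating the naive
    (unweighted) estimate.  Prevalence is high enough for a well-powered
    contrast (~600 reclassified-pathogenic carriers at n = 2000), and
    hazard-side heterogeneity is kept moderate with partial follow-up so
    the marginal hazard ratio targeted by IPTW nearly coincides with the
    conditional one (hazard-ratio non-collapsibility is otherwise not a
    weighting failure).
    """
    ln2 = float(np.log(2.0))
    genes = (
        GeneSimConfig("GENE1", "TSG", 0.45, 0.30, 0.65, ln2, ln2, 0.0),
        GeneSimConfig("GENE2", "OG", 0.25, 0.6, 0.4, 0.2, 0.2, 0.0),
        GeneSimConfig("GENE3", "TSG", 0.2, 0.5, 0.4, 0.15, 0.15, 0.0),
    )
    methods = (
        MethodSimConfig("am", "higher_pathogenic", (2.0, 8.0), (8.0, 2.0), 0.0),
    )
    return SimConfig(
        n_patients=n_patients,
        seed=seed,
        genes=genes,
        methods=methods,
        confounding={"smoker": (1.2, 0.5), "age": (0.3, 0.2), "tmb": (0.6, 0.3)},
        censor_horizon=24.0,
    )


@dataclass
class TruthRecord:
    """Generator-side ground truth for parameter-recovery tests."""

    variant_class: pd.DataFrame  # variant_key, gene, latent_class
    gene_loghrs: pd.DataFrame  # gene, class, loghr
    driver_propensity: pd.DataFrame  # patient_id x gene -> P(driver)
    confounder_score: pd.Series  # patient_id -> mutation-logit shift


@dataclass
class SimulatedCohort:
    patients: List[PatientRecord]
    mutations: List[MutationRecord]
    scores: ScoreMatrix
    binding_map: BindingResidueMap
    pathways: List[PathwaySpec]
    truth: TruthRecord
    coverage: PanelCoverage
    config: SimConfig

    def __iter__(self):
        # tuple-style unpacking of the six primary outputs
        return iter(
            (
                self.patients,
                self.mutations,
                self.scores,
                self.binding_map,
                self.pathways,
                self.truth,
            )
        )


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def plackett_p11(
    p_a: np.ndarray, p_b: np.ndarray, psi: float
) -> np.ndarray:
    """P(A=1, B=1) for binary margins (p_a, p_b) and odds ratio psi."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if psi == 1.0:
        return p_a * p_b
    b = 1.0 + (p_a + p_b) * (psi - 1.0)
    disc = b * b - 4.0 * psi * (psi - 1.0) * p_a * p_b
    p11 = (b - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    return np.clip(p11, np.maximum(0.0, p_a + p_b - 1.0), np.minimum(p_a, p_b))


def sample_exclusive_pair(
    p_a: np.ndarray,
    p_b: np.ndarray,
    odds_ratio: float,
    rng: np.random.Generator,
    b_draws: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw coupled Bernoulli pairs (A, B) with the given odds ratio.

    Margins are preserved; ``b_draws`` may supply pre-drawn B indicators
    (with marginal probabilities p_b), in which case A is drawn from its
    conditional distribution given B.
    """
    p_a = np.broadcast_to(np.asarray(p_a, dtype=float), np.shape(p_b)).copy()
    p_b = np.asarray(p_b, dtype=float)
    if b_draws is None:
        b = rng.random(p_b.shape) < p_b
    else:
        b = np.asarray(b_draws, dtype=bool)
    p11 = plackett_p11(p_a, p_b, odds_ratio)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond1 = np.where(p_b > 0, p11 / p_b, 0.0)
        cond0 = np.where(p_b < 1, (p_a - p11) / (1.0 - p_b), 0.0)
    p_cond = np.where(b, cond1, cond0)
    a = rng.random(p_b.shape) < np.clip(p_cond, 0.0, 1.0)
    return a, b


def generate_mutation_contexts(
    config: SimConfig, n: int, seed: int
) -> List[Tuple[str, str]]:
    """i.i.d. (context3, alt) draws from the config's SBS96 profile."""
    p = (
        np.full(96, 1.0 / 96.0)
        if config.context_profile is None
        else np.asarray(config.context_profile, dtype=float)
    )
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("context profile must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(96, size=int(n), p=p)
    return [SBS96_CATEGORIES[i] for i in idx]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class _GenePools:
    """Deterministic per-gene variant pools with latent classes."""

    hotspots: List[str]
    pathogenic: List[str]
    benign: List[str]
    residues: Dict[str, int]


def _build_pools(
    cfg: SimConfig, gene: GeneSimConfig, binding: np.ndarray, gidx: int
) -> _GenePools:
    rng = _stream(cfg.seed, 5, gidx)
    odds_benign = cfg.binding_fraction / (1 - cfg.binding_fraction)
    p_bind_driver = float(
        (cfg.binding_enrichment_or * odds_benign)
        / (1 + cfg.binding_enrichment_or * odds_benign)
    )
    binding_set = np.flatnonzero(binding) + 1
    nonbinding_set = np.flatnonzero(~binding) + 1

    def draw_variants(n: int, p_bind: float) -> List[str]:
        keys = []
        seen = set()
        while len(keys) < n:
            use_binding = rng.random() < p_bind
            pool = binding_set if use_binding else nonbinding_set
            res = int(pool[rng.integers(0, len(pool))])
            ref_aa = AA[rng.integers(0, len(AA))]
            alt_aa = AA[rng.integers(0, len(AA))]
            if alt_aa == ref_aa:
                continue
            key = f"p.{ref_aa}{res}{alt_aa}"
            if key in seen:
                continue
            seen.add(key)
            keys.append(key)
        return keys

    hotspots = draw_variants(cfg.n_hotspots, p_bind_driver)
    # keep pools disjoint by re-drawing collisions across groups
    pathogenic = []
    taken = set(hotspots)
    for key in draw_variants(cfg.n_pathogenic_pool + len(taken), p_bind_driver):
        if key not in taken and len(pathogenic) < cfg.n_pathogenic_pool:
            pathogenic.append(key)
            taken.add(key)
    benign = []
    for key in draw_variants(cfg.n_benign_pool + len(taken), cfg.binding_fraction):
        if key not in taken and len(benign) < cfg.n_benign_pool:
            benign.append(key)
            taken.add(key)
    residues = {
        k: int("".join(c for c in k if c.isdigit()))
        for k in hotspots + pathogenic + benign
    }
    return _GenePools(hotspots, pathogenic, benign, residues)


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort; reproducible under config.seed."""
    config.validate()
    n = config.n_patients
    seed = config.seed
    gene_names = [g.symbol for g in config.genes]
    gene_idx = {g: i for i, g in enumerate(gene_names)}

    # --- covariates (one substream each: prefix-stable when n grows) ------
    age = _stream(seed, 0, 0).normal(65.0, 10.0, size=n)
    male = _stream(seed, 0, 1).random(n) < 0.5
    stage_iv = _stream(seed, 0, 2).random(n) < 0.45
    smoker = _stream(seed, 0, 3).random(n) < 0.6
    tmb = _stream(seed, 0, 4).gamma(2.0, 3.0, size=n)
    msi = _stream(seed, 0, 5).exponential(2.0, size=n)
    cov_values = {
        "age": age,
        "male": male.astype(float),
        "stage_iv": stage_iv.astype(float),
        "smoker": smoker.astype(float),
        "tmb": tmb,
    }
    z = {}
    for name, x in cov_values.items():
        loc, scale = COVARIATE_SCALES[name]
        z[name] = (x - loc) / scale
    mut_shift = np.zeros(n)
    haz_shift = np.zeros(n)
    for name, (mut_eff, haz_eff) in config.confounding.items():
        if name not in z:
            raise ValueError(f"unknown confounding covariate {name!r}")
        mut_shift += mut_eff * z[name]
        haz_shift += haz_eff * z[name]

    # --- panel assignment -------------------------------------------------
    rng_panel = _stream(seed, 1)
    on_panel_b = rng_panel.random(n) < config.panel_b_fraction
    panel_a_genes = set(gene_names)
    panel_b_genes = panel_a_genes - set(config.panel_missing_genes)
    coverage = PanelCoverage({"panel_A": panel_a_genes, "panel_B": panel_b_genes})

    # --- driver/benign presence per gene ----------------------------------
    def gene_probs(g: GeneSimConfig) -> Tuple[np.ndarray, np.ndarray]:
        p_driver = g.p_mut * (
            g.frac_oncogenic + (1 - g.frac_oncogenic) * g.pathogenic_vus_frac
        )
        p_benign = g.p_mut * (1 - g.frac_oncogenic) * (1 - g.pathogenic_vus_frac)
        pd_i = _sigmoid(_logit(np.full(n, p_driver)) + mut_shift)
        pb_i = _sigmoid(_logit(np.full(n, p_benign)) + mut_shift)
        if p_driver == 0:
            pd_i = np.zeros(n)
        if p_benign == 0:
            pb_i = np.zeros(n)
        return pd_i, pb_i

    p_driver_mat = np.zeros((n, len(gene_names)))
    p_benign_mat = np.zeros((n, len(gene_names)))
    for g in config.genes:
        pd_i, pb_i = gene_probs(g)
        p_driver_mat[:, gene_idx[g.symbol]] = pd_i
        p_benign_mat[:, gene_idx[g.symbol]] = pb_i

    driver = np.zeros((n, len(gene_names)), dtype=bool)
    focal_genes = {pw.genes[0]: pw for pw in config.pathways if len(pw.genes) > 1}
    for g in config.genes:
        if g.symbol in focal_genes:
            continue  # drawn by the pathway coupling below
        rng_g = _stream(seed, 2, gene_idx[g.symbol])
        driver[:, gene_idx[g.symbol]] = (
            rng_g.random(n) < p_driver_mat[:, gene_idx[g.symbol]]
        )
    for pidx, pw in enumerate(config.pathways):
        if len(pw.genes) < 2:
            continue
        focal = pw.genes[0]
        others = [gene_idx[g] for g in pw.genes[1:]]
        b_any = driver[:, others].any(axis=1)
        p_b = 1.0 - np.prod(1.0 - p_driver_mat[:, others], axis=1)
        rng_pw = _stream(seed, 3, pidx)
        a, _ = sample_exclusive_pair(
            p_driver_mat[:, gene_idx[focal]],
            p_b,
            pw.exclusivity_or,
            rng_pw,
            b_draws=b_any,
        )
        driver[:, gene_idx[focal]] = a

    benign = np.zeros_like(driver)
    for g in config.genes:
        rng_b = _stream(seed, 4, gene_idx[g.symbol])
        benign[:, gene_idx[g.symbol]] = (
            rng_b.random(n) < p_benign_mat[:, gene_idx[g.symbol]]
        )

    # --- variant pools, binding map ---------------------------------------
    binding_map = BindingResidueMap()
    pools: Dict[str, _GenePools] = {}
    n_bind = max(1, int(round(config.binding_fraction * config.protein_length)))
    for g in config.genes:
        gidx = gene_idx[g.symbol]
        rng_site = _stream(seed, 10, gidx)
        bind_mask = np.zeros(config.protein_length, dtype=bool)
        bind_mask[rng_site.choice(config.protein_length, size=n_bind, replace=False)] = True
        for j, res in enumerate(np.flatnonzero(bind_mask) + 1):
            source = "ligand" if j % 2 == 0 else "ppi_hotspot"
            binding_map.add(g.symbol, int(res), source)
        pools[g.symbol] = _build_pools(config, g, bind_mask, gidx)

    # --- per-patient mutation records --------------------------------------
    contexts_by_variant: Dict[str, Tuple[str, str, str]] = {}
    rng_ctx = _stream(seed, 9)
    profile = (
        np.full(96, 1.0 / 96.0)
        if config.context_profile is None
        else np.asarray(config.context_profile, dtype=float)
    )

    def variant_context(key: str) -> Tuple[str, str, str]:
        if key not in contexts_by_variant:
            context3, alt = SBS96_CATEGORIES[int(rng_ctx.choice(96, p=profile))]
            ref = context3[1]
            if rng_ctx.random() < 0.5:  # present on the purine strand
                context3, ref, alt = (
                    revcomp(context3),
                    revcomp(ref),
                    revcomp(alt),
                )
            contexts_by_variant[key] = (context3, ref, alt)
        return contexts_by_variant[key]

    mutations: List[MutationRecord] = []
    variant_latent: Dict[str, Tuple[str, str]] = {}  # key -> (gene, class)
    for g in config.genes:
        gidx = gene_idx[g.symbol]
        pool = pools[g.symbol]
        rng_pick = _stream(seed, 6, gidx)
        q_og = (
            g.frac_oncogenic
            / (
                g.frac_oncogenic
                + (1 - g.frac_oncogenic) * g.pathogenic_vus_frac
            )
            if g.p_mut > 0
            else 0.0
        )
        covered = ~on_panel_b | (g.symbol in panel_b_genes)
        for i in range(n):
            if not covered[i]:
                continue
            pid = f"P{i:05d}"
            sid = f"S{i:05d}"
            if driver[i, gidx]:
                if rng_pick.random() < q_og:
                    pchange = pool.hotspots[
                        int(rng_pick.integers(0, len(pool.hotspots)))
                    ]
                    onco_class = "oncogenic"
                    latent = "driver"
                else:
                    pchange = pool.pathogenic[
                        int(rng_pick.integers(0, len(pool.pathogenic)))
                    ]
                    onco_class = "vus"
                    latent = "driver"
                key = f"{g.symbol}:{pchange}"
                context3, ref, alt = variant_context(key)
                mutations.append(
                    MutationRecord(
                        patient_id=pid,
                        sample_id=sid,
                        gene=g.symbol,
                        protein_change=pchange,
                        chrom=str(1 + gidx % 22),
                        pos=1000 * gidx + pool.residues[pchange],
                        ref=ref,
                        alt=alt,
                        context3=context3,
                        is_missense=True,
                        oncokb_class=onco_class,
                    )
                )
                variant_latent[key] = (g.symbol, latent)
            if benign[i, gidx]:
                pchange = pool.benign[int(rng_pick.integers(0, len(pool.benign)))]
                key = f"{g.symbol}:{pchange}"
                context3, ref, alt = variant_context(key)
                mutations.append(
                    MutationRecord(
                        patient_id=pid,
                        sample_id=sid,
                        gene=g.symbol,
                        protein_change=pchange,
                        chrom=str(1 + gidx % 22),
                        pos=1000 * gidx + pool.residues[pchange],
                        ref=ref,
                        alt=alt,
                        context3=context3,
                        is_missense=True,
                        oncokb_class="vus",
                    )
                )
                variant_latent[key] = (g.symbol, "passenger")

    # --- scores over the full pools (annotation-rich, patient-independent) --
    all_keys: List[str] = []
    latent_by_key: Dict[str, str] = {}
    for g in config.genes:
        pool = pools[g.symbol]
        for pchange in pool.hotspots + pool.pathogenic:
            key = f"{g.symbol}:{pchange}"
            all_keys.append(key)
            latent_by_key[key] = "driver"
        for pchange in pool.benign:
            key = f"{g.symbol}:{pchange}"
            all_keys.append(key)
            latent_by_key[key] = "passenger"
    score_frame = pd.DataFrame(
        index=pd.Index(all_keys, name="variant_key"), dtype=float
    )
    is_driver = np.array([latent_by_key[k] == "driver" for k in all_keys])
    for midx, m in enumerate(config.methods):
        rng_m = _stream(seed, 7, midx)
        s = np.empty(len(all_keys))
        nb = is_driver.sum()
        s[is_driver] = rng_m.beta(*m.pathogenic_beta, size=nb)
        s[~is_driver] = rng_m.beta(*m.benign_beta, size=len(all_keys) - nb)
        if m.orientation == "lower_pathogenic":
            s = 1.0 - s
        miss = rng_m.random(len(all_keys)) < m.missing_rate
        s[miss] = np.nan
        score_frame[m.name] = s
    scores = ScoreMatrix(score_frame)

    # --- survival -----------------------------------------------------------
    log_h = np.log(config.baseline_hazard) + haz_shift
    # per-patient class carriage from the emitted mutations
    onco_carrier = np.zeros((n, len(gene_names)), dtype=bool)
    pvus_carrier = np.zeros((n, len(gene_names)), dtype=bool)
    ben_carrier = np.zeros((n, len(gene_names)), dtype=bool)
    for m in mutations:
        i = int(m.patient_id[1:])
        gidx = gene_idx[m.gene]
        if m.oncokb_class == "oncogenic":
            onco_carrier[i, gidx] = True
        elif variant_latent[m.variant_key][1] == "driver":
            pvus_carrier[i, gidx] = True
        else:
            ben_carrier[i, gidx] = True
    for g in config.genes:
        gidx = gene_idx[g.symbol]
        log_h += np.where(onco_carrier[:, gidx], g.loghr_oncogenic, 0.0)
        log_h += np.where(pvus_carrier[:, gidx], g.loghr_pathogenic_vus, 0.0)
        log_h += np.where(ben_carrier[:, gidx], g.loghr_benign_vus, 0.0)
    hazard = np.exp(log_h)
    entry = _stream(seed, 8, 0).uniform(0.0, config.entry_max, size=n)
    # exponential memorylessness: T | T > entry  =  entry + Exp(hazard)
    t_death = entry + _stream(seed, 8, 1).exponential(1.0, size=n) / hazard
    horizon = config.censor_horizon
    event = t_death <= horizon
    t_end = np.minimum(t_death, horizon)

    patients: List[PatientRecord] = []
    for i in range(n):
        patients.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                cohort_id="sim",
                panel_id="panel_B" if on_panel_b[i] else "panel_A",
                covariates={
                    "age": float(age[i]),
                    "male": float(male[i]),
                    "stage_iv": float(stage_iv[i]),
                    "smoker": float(smoker[i]),
                },
                tmb=float(tmb[i]),
                msi_score=float(msi[i]),
                t_dx=0.0,
                t_entry=float(entry[i]),
                t_end=float(t_end[i]),
                event=bool(event[i]),
            )
        )

    truth = TruthRecord(
        variant_class=pd.DataFrame(
            [
                {"variant_key": k, "gene": k.split(":", 1)[0], "latent_class": c}
                for k, c in sorted(latent_by_key.items())
            ]
        ),
        gene_loghrs=pd.DataFrame(
            [
                {
                    "gene": g.symbol,
                    "loghr_oncogenic": g.loghr_oncogenic,
                    "loghr_pathogenic_vus": g.loghr_pathogenic_vus,
                    "loghr_benign_vus": g.loghr_benign_vus,
                }
                for g in config.genes
            ]
        ),
        driver_propensity=pd.DataFrame(
            p_driver_mat,
            index=pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id"),
            columns=gene_names,
        ),
        confounder_score=pd.Series(
            mut_shift, index=pd.Index([f"P{i:05d}" for i in range(n)])
        ),
    )
    pathway_specs = [
        PathwaySpec(name=pw.name, genes=tuple(pw.genes)) for pw in config.pathways
    ]
    return SimulatedCohort(
        patients=patients,
        mutations=mutations,
        scores=scores,
        binding_map=binding_map,
        pathways=pathway_specs,
        truth=truth,
        coverage=coverage,
        config=config,
    )
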