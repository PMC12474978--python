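"""Binding-residue enrichment benchmark.

Missense mutations are partitioned by whether they hit a residue involved
in ligand binding or a protein-protein-interaction hotspot (from curated
structural databases, supplied as a gene -> residue map).  A VEP that
separates VUSs well should call binding-residue VUSs pathogenic far more
often than non-binding ones: the summary statistic is OR_binding, the
pooled odds ratio of reclassified-pathogenic (vs reclassified-benign) VUSs
occurring at binding residues across all mapped genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .calibration import bh_adjust
from .contingency import (
    ZeroMarginError,
    check_margins,
    fisher_two_sided_p,
    sample_odds_ratio,
    validate_table,
    woolf_ci,
)
from .types import BindingResidueMap, MutationRecord

logger = logging.getLogger(__name__)


def partition_binding(
    mutations: Sequence[MutationRecord], binding_map: BindingResidueMap
) -> Dict[str, str]:
    """variant_key -> 'binding' / 'non_binding' / 'unmapped'.

    Genes without structural data, and variants whose protein change does
    not parse to a residue index, are 'unmapped' — a category, not an
    error — and are excluded from enrichment denominators downstream.
    """
    out: Dict[str, str] = {}
    n_unparseable = 0
    for m in mutations:
        key = m.variant_key
        if not binding_map.has_gene(m.gene):
            out[key] = "unmapped"
            continue
        residue = m.residue
        if residue is None:
            out[key] = "unmapped"
            n_unparseable += 1
            continue
        out[key] = (
            "binding" if binding_map.is_binding(m.gene, residue) else "non_binding"
        )
    if n_unparseable:
        logger.warning(
            "partition_binding: %d variants with unparseable protein change",
            n_unparseable,
        )
    return out


@dataclass
class EnrichmentResult:
    group: str
    a: int  # pathogenic & binding
    b: int  # pathogenic & non-binding
    c: int  # benign & binding
    d: int  # benign & non-binding
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    q: Optional[float] = None

    @property
    def table(self) -> List[List[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def binding_fisher(
    table: Sequence[Sequence[int]], group: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher exact test on a binding 2x2.

    Rows are classes (e.g. pathogenic / benign), columns binding /
    non-binding.  Zero margins are an error: with an empty row or column
    the test is undefined.
    """
    t = validate_table(table)
    check_margins(t)
    p = fisher_two_sided_p(t)
    or_point = sample_odds_ratio(t)
    lo, hi = woolf_ci(t)
    return EnrichmentResult(
        group, int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]),
        or_point, lo, hi, p,
    )


def or_binding(
    classifications: Mapping[str, str],
    binding: Mapping[str, str],
    group: str = "",
) -> EnrichmentResult:
    """Pooled all-genes OR_binding for one method.

    *classifications* should cover the VUSs reclassified by the method;
    only 'pathogenic'/'benign' calls on binding-mapped variants enter the
    2x2.  Raises when either reclassified class is empty after exclusions.
    """
    a = b = c = d = 0
    for key, call in classifications.items():
        loc = binding.get(key, "unmapped")
        if loc == "unmapped":
            continue
        if call == "pathogenic":
            if loc == "binding":
                a += 1
            else:
                b += 1
        elif call == "benign":
            if loc == "binding":
                c += 1
            else:
                d += 1
    if a + b == 0 or c + d == 0:
        raise ValueError(
            "OR_binding undefined: a reclassified class is empty after "
            "excluding unmapped variants"
        )
    return binding_fisher([[a, b], [c, d]], group=group)


def enrichment_battery(
    results: Sequence[EnrichmentResult],
) -> List[EnrichmentResult]:
    """BH-correct p-values across one family of enrichment results."""
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return list(results)


def per_gene_binding_tables(
    classifications: Mapping[str, str], binding: Mapping[str, str]
) -> Dict[str, List[List[int]]]:
    """Diagnostic per-gene 2x2 tables underlying the pooled OR_binding."""
    tables: Dict[str, np.ndarray] = {}
    for key, call in classifications.items():
        loc = binding.get(key, "unmapped")
        if loc == "unmapped" or call not in ("pathogenic", "benign"):
            continue
        gene = key.split(":", 1)[0]
        t = tables.setdefault(gene, np.zeros((2, 2), dtype=int))
        t[0 if call == "pathogenic" else 1, 0 if loc == "binding" else 1] += 1
    return {g: t.tolist() for g, t in sorted(tables.items())}
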