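"""Trinucleotide-context (SBS96) profiles and neutral-variant simulation.

Somatic single-base substitutions are classified into the standard 96
categories: the substituted base reported on the pyrimidine strand (C or T
reference), with its immediate 5' and 3' flanking bases.  Purine-reference
changes are reverse-complemented into the pyrimidine frame, as in the
COSMIC mutational-signature convention.

The neutral-variant simulator draws tumor-type-matched "passenger-like"
substitutions i.i.d. from an estimated profile, giving a negative-control
variant set whose context composition matches the observed mutational
process rather than germline variation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import BASES, MutationRecord, ScoreMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PYRIMIDINES = ("C", "T")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _build_categories() -> List[Tuple[str, str]]:
    cats = []
    for ref in PYRIMIDINES:
        for alt in [b for b in "ACGT" if b != ref]:
            for five in "ACGT":
                for three in "ACGT":
                    cats.append((five + ref + three, alt))
    return cats


#: canonical ordering of the 96 (context3, alt) categories
SBS96_CATEGORIES: Tuple[Tuple[str, str], ...] = tuple(_build_categories())
_CATEGORY_INDEX: Dict[Tuple[str, str], int] = {
    c: i for i, c in enumerate(SBS96_CATEGORIES)
}


def canonical_category(context3: str, ref: str, alt: str) -> Tuple[str, str]:
    """Map any SNV to its pyrimidine-centered (context3, alt) category.

    Raises ``ValueError`` when the context middle base disagrees with ref.
    """
    if len(context3) != 3 or any(b not in BASES for b in context3):
        raise ValueError(f"bad context3 {context3!r}")
    if context3[1] != ref:
        raise ValueError(f"context3 middle base {context3[1]!r} != ref {ref!r}")
    if ref == alt or alt not in BASES:
        raise ValueError(f"bad substitution {ref}>{alt}")
    if ref in PYRIMIDINES:
        return context3, alt
    return revcomp(context3), _COMPLEMENT[alt]


@dataclass
class ContextProfile:
    """96 probabilities over SBS96 categories for one tumor type."""

    probabilities: np.ndarray
    tumor_type: str = "pan"
    n_source_mutations: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (96,):
            raise ValueError(f"profile must have 96 entries, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("profile entries must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile must sum to 1 (got {p.sum()!r})")
        self.probabilities = p

    def probability(self, context3: str, alt: str) -> float:
        return float(self.probabilities[_CATEGORY_INDEX[(context3, alt)]])

    @classmethod
    def uniform(cls, tumor_type: str = "pan") -> "ContextProfile":
        return cls(np.full(96, 1.0 / 96.0), tumor_type=tumor_type)

    @classmethod
    def from_counts(
        cls, counts: Mapping[Tuple[str, str], float], tumor_type: str = "pan"
    ) -> "ContextProfile":
        vec = np.zeros(96)
        for cat, n in counts.items():
            vec[_CATEGORY_INDEX[cat]] = n
        total = vec.sum()
        if total <= 0:
            raise ValueError("no counts supplied")
        return cls(vec / total, tumor_type=tumor_type, n_source_mutations=int(total))


def estimate_context_profile(
    mutations: Sequence[MutationRecord], tumor_type: str = "pan"
) -> ContextProfile:
    """Empirical SBS96 profile of the eligible SNVs in *mutations*.

    Eligible records carry ``context3``/``ref``/``alt``; records whose
    context middle base disagrees with ref are rejected and logged.
    Raises when nothing is eligible.
    """
    counts = np.zeros(96)
    n_used = 0
    n_rejected = 0
    for m in mutations:
        if m.context3 is None or m.ref is None or m.alt is None:
            continue
        try:
            cat = canonical_category(m.context3, m.ref, m.alt)
        except ValueError as exc:
            n_rejected += 1
            logger.debug("rejected mutation for profile: %s", exc)
            continue
        counts[_CATEGORY_INDEX[cat]] += 1
        n_used += 1
    if n_rejected:
        logger.warning(
            "estimate_context_profile: rejected %d inconsistent records", n_rejected
        )
    if n_used == 0:
        raise ValueError("no eligible SNVs with trinucleotide context")
    return ContextProfile(
        counts / counts.sum(), tumor_type=tumor_type, n_source_mutations=n_used
    )


def simulate_neutral_variants(
    profile: ContextProfile,
    n: int,
    seed: int,
    opportunities: Optional[Mapping[Tuple[str, str], int]] = None,
) -> List[Tuple[str, str, str]]:
    """Draw *n* neutral variants (context3, ref, alt) i.i.d. from *profile*.

    *opportunities* maps categories to available genomic site counts; every
    category with nonzero profile mass must have at least one site (uniform
    opportunities are assumed when omitted).  Reproducible under *seed*.
    """
    p = profile.probabilities
    if opportunities is not None:
        for i, cat in enumerate(SBS96_CATEGORIES):
            if p[i] > 0 and opportunities.get(cat, 0) <= 0:
                raise ValueError(
                    f"no available sites for category {cat[0]}>{cat[1]} "
                    "with nonzero profile mass"
                )
    rng = np.random.default_rng(seed)
    draws = rng.choice(96, size=int(n), p=p)
    out = []
    for i in draws:
        context3, alt = SBS96_CATEGORIES[i]
        out.append((context3, context3[1], alt))
    return out


def select_annotation_rich_negatives(
    candidates: Sequence[str], scores: ScoreMatrix, k: int
) -> List[str]:
    """The *k* candidate variants with the most non-missing method scores.

    Emulates picking a negative-control set restricted to variants that
    most methods actually annotate.  Ties at the k-th rank break by
    lexicographically smaller variant key (deterministic).
    """
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    counts = scores.annotation_counts()
    ranked = sorted(
        candidates, key=lambda key: (-int(counts.get(key, 0)), key)
    )
    return ranked[:k]
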