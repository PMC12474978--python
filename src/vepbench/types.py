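"""Domain types shared by all benchmarks.

The central objects are per-occurrence somatic :class:`MutationRecord`\\ s,
per-patient clinical/survival :class:`PatientRecord`\\ s, a wide
``(variant, method)`` :class:`ScoreMatrix`, and the small specification
objects describing how each variant effect predictor (VEP) is oriented and
calibrated.  Variant identity throughout the package is the pair
``(gene, protein_change)`` — the benchmarks operate on protein-level
missense changes; the genomic key is a fallback when the protein change is
absent.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

ONCOKB_CLASSES = (
    "oncogenic",
    "likely_oncogenic",
    "neutral",
    "likely_neutral",
    "vus",
    "unknown",
)

GENE_ROLES = ("OG", "TSG", "OG_TSG", "other")

#: classes counted as "known oncogenic" when stratifying patients
ONCOGENIC_CLASSES = frozenset({"oncogenic", "likely_oncogenic"})
#: classes counted as VUS (the reclassification target); absent/unknown
#: annotations are handled like VUSs downstream but retained for reporting
VUS_CLASSES = frozenset({"vus", "unknown"})

_HGVSP_RE = re.compile(
    r"^p\.\(?([A-Z](?:[a-z]{2})?|\*)(\d+)([A-Z](?:[a-z]{2})?|\*)\)?$"
)


def parse_protein_position(protein_change: Optional[str]) -> Optional[int]:
    """Residue index from an HGVS p. short string, or ``None``.

    Only the simple missense-like pattern ``p.<AA><pos><AA>`` is recognized
    (e.g. ``"p.V600E"`` -> 600); anything else — ``"p.?"``, frameshifts with
    complex suffixes, empty strings — yields ``None``.
    """
    if not protein_change:
        return None
    m = _HGVSP_RE.match(protein_change.strip())
    if m is None:
        return None
    return int(m.group(2))


class RecordValidationError(ValueError):
    """A record or table violated a structural invariant."""


@dataclass
class MutationRecord:
    """One somatic mutation occurrence in one sample.

    ``oncokb_class`` carries the knowledge-base annotation; values outside
    the known vocabulary map to ``"unknown"`` at read time.
    """

    patient_id: str
    sample_id: str
    gene: str
    protein_change: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    context3: Optional[str] = None
    is_missense: bool = False
    oncokb_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise RecordValidationError("patient_id must be non-empty")
        if not self.gene:
            raise RecordValidationError("gene must be non-empty")
        if self.oncokb_class not in ONCOKB_CLASSES:
            raise RecordValidationError(
                f"unknown oncokb_class {self.oncokb_class!r}"
            )
        if (self.ref is None) != (self.alt is None):
            raise RecordValidationError("ref and alt must be given together")
        if self.ref is not None:
            if self.ref not in BASES or self.alt not in BASES:
                raise RecordValidationError(
                    f"ref/alt must be single bases, got {self.ref!r}/{self.alt!r}"
                )
            if self.ref == self.alt:
                raise RecordValidationError("ref and alt must differ")
        if self.context3 is not None:
            if len(self.context3) != 3 or any(b not in BASES for b in self.context3):
                raise RecordValidationError(
                    f"context3 must be a 3-mer over ACGT, got {self.context3!r}"
                )
            if self.ref is not None and self.context3[1] != self.ref:
                raise RecordValidationError(
                    "context3 middle base must equal ref "
                    f"({self.context3!r} vs {self.ref!r})"
                )

    @property
    def variant_key(self) -> str:
        """``gene:protein_change``; genomic key when protein_change absent."""
        if self.protein_change:
            return f"{self.gene}:{self.protein_change}"
        return f"{self.gene}:g.{self.chrom}:{self.pos}{self.ref}>{self.alt}"

    @property
    def residue(self) -> Optional[int]:
        return parse_protein_position(self.protein_change)


@dataclass
class PatientRecord:
    """Covariates plus survival timeline for one patient.

    Times are months from a common origin (diagnosis); the cohort-entry
    time ``t_entry`` is the first tumor sequencing, and survival analyses
    left-truncate there.  Invariant: ``t_dx <= t_entry <= t_end``.
    """

    patient_id: str
    cohort_id: str = "cohort"
    panel_id: str = "panel"
    covariates: Dict[str, float] = field(default_factory=dict)
    tmb: Optional[float] = None
    msi_score: Optional[float] = None
    t_dx: float = 0.0
    t_entry: float = 0.0
    t_end: float = 0.0
    event: bool = False

    def __post_init__(self) -> None:
        if not (self.t_dx <= self.t_entry <= self.t_end):
            raise RecordValidationError(
                f"times must satisfy t_dx <= t_entry <= t_end for "
                f"{self.patient_id}: {self.t_dx}, {self.t_entry}, {self.t_end}"
            )
        if self.tmb is not None and not (np.isfinite(self.tmb) and self.tmb >= 0):
            raise RecordValidationError(f"tmb must be finite and >= 0, got {self.tmb}")


def derive_clinical_flags(
    patient: PatientRecord,
) -> Tuple[Optional[bool], Optional[bool]]:
    """(tmb_high, msi_high) for one patient.

    TMB-high is ``tmb >= 10`` mutations/Mb (boundary included); MSI-high is
    a strictly greater ``msi_score > 10``.  A missing input leaves the
    corresponding flag ``None`` (undefined), never ``False``.
    """
    tmb_high = None if patient.tmb is None else bool(patient.tmb >= 10.0)
    msi_high = None if patient.msi_score is None else bool(patient.msi_score > 10.0)
    return tmb_high, msi_high


@dataclass(frozen=True)
class GeneInfo:
    symbol: str
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in GENE_ROLES:
            raise RecordValidationError(f"unknown gene role {self.role!r}")


class PanelCoverage:
    """panel_id -> set of covered gene symbols."""

    def __init__(self, panels: Mapping[str, Iterable[str]]):
        self.panels: Dict[str, Set[str]] = {
            pid: set(genes) for pid, genes in panels.items()
        }
        for pid, genes in self.panels.items():
            if not genes:
                raise RecordValidationError(f"panel {pid!r} covers no genes")

    def covers(self, panel_id: str, gene: str) -> bool:
        if panel_id not in self.panels:
            raise KeyError(f"unknown panel_id {panel_id!r}")
        return gene in self.panels[panel_id]

    def __contains__(self, panel_id: str) -> bool:
        return panel_id in self.panels


def filter_panel(
    patients: Sequence[PatientRecord],
    coverage: PanelCoverage,
    gene: str,
) -> List[PatientRecord]:
    """Patients whose sequencing panel covers *gene*, input order kept.

    Gene-level analyses only admit patients whose assay could have detected
    a mutation in the gene; everyone else is silently out of cohort.
    """
    kept = [p for p in patients if coverage.covers(p.panel_id, gene)]
    return kept


@dataclass(frozen=True)
class MethodSpec:
    """How one VEP's raw scores become classifications.

    orientation
        ``"higher_pathogenic"`` or ``"lower_pathogenic"``.
    calibration_mode
        ``"builtin_classes"`` (verbatim class_map), ``"qvalue_threshold"``
        (Benjamini–Hochberg on per-variant p-values), ``"learned_cutoff"``
        (sensitivity+specificity-maximizing threshold learned per dataset),
        or ``"class_selection"`` (pick the built-in uncertainty class with
        the best AUROC, as for tiered classifiers).
    """

    name: str
    orientation: str = "higher_pathogenic"
    calibration_mode: str = "learned_cutoff"
    threshold: Optional[float] = None
    class_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_pathogenic", "lower_pathogenic"):
            raise RecordValidationError(f"bad orientation {self.orientation!r}")
        if self.calibration_mode not in (
            "builtin_classes",
            "qvalue_threshold",
            "learned_cutoff",
            "class_selection",
        ):
            raise RecordValidationError(
                f"bad calibration_mode {self.calibration_mode!r}"
            )
        if self.calibration_mode == "builtin_classes" and self.class_map is None:
            raise RecordValidationError("builtin_classes requires class_map")


class ScoreMatrix:
    """(variant_key, method) -> raw score, with missingness.

    Backed by a float DataFrame indexed by variant_key with one column per
    method; NaN encodes a missing annotation.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.astype(float)
        finite = frame.to_numpy()
        if np.any(np.isinf(finite)):
            raise RecordValidationError("scores must be finite or missing")
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Mapping[str, Mapping[str, float]], methods: Sequence[str]
    ) -> "ScoreMatrix":
        frame = pd.DataFrame.from_dict(dict(records), orient="index")
        frame = frame.reindex(columns=list(methods))
        frame.index.name = "variant_key"
        return cls(frame)

    @property
    def methods(self) -> List[str]:
        return list(self.frame.columns)

    @property
    def variant_keys(self) -> List[str]:
        return list(self.frame.index)

    def scores(self, method: str) -> pd.Series:
        return self.frame[method]

    def annotation_counts(self) -> pd.Series:
        """Number of non-missing method scores per variant."""
        return self.frame.notna().sum(axis=1)

    def __len__(self) -> int:
        return len(self.frame)


class BindingResidueMap:
    """gene -> {residue -> source tag}, sources 'ligand' / 'ppi_hotspot'.

    A residue may carry both tags; membership queries pool the sources
    (binding means ligand-binding OR protein-protein-interaction hotspot).
    """

    SOURCES = ("ligand", "ppi_hotspot")

    def __init__(self) -> None:
        self._map: Dict[str, Dict[int, Set[str]]] = {}

    def add(self, gene: str, residue: int, source: str) -> None:
        if residue < 1:
            raise RecordValidationError(f"residue index must be >= 1, got {residue}")
        if source not in self.SOURCES:
            raise RecordValidationError(f"unknown binding source {source!r}")
        self._map.setdefault(gene, {}).setdefault(residue, set()).add(source)

    def residues(self, gene: str) -> Set[int]:
        return set(self._map.get(gene, {}))

    def has_gene(self, gene: str) -> bool:
        return gene in self._map

    def is_binding(self, gene: str, residue: int) -> bool:
        return residue in self._map.get(gene, {})

    @property
    def genes(self) -> List[str]:
        return sorted(self._map)

    def items(self):
        for gene, residues in self._map.items():
            for residue, sources in residues.items():
                for source in sorted(sources):
                    yield gene, residue, source


@dataclass(frozen=True)
class PathwaySpec:
    """A named oncogenic signaling pathway and its member genes."""

    name: str
    genes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise RecordValidationError(f"pathway {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise RecordValidationError(f"pathway {self.name!r} has duplicate genes")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into a DataFrame (one covariate per column)."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "cohort_id": p.cohort_id,
            "panel_id": p.panel_id,
            "tmb": p.tmb,
            "msi_score": p.msi_score,
            "t_dx": p.t_dx,
            "t_entry": p.t_entry,
            "t_end": p.t_end,
            "event": int(p.event),
        }
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def mutations_to_frame(mutations: Sequence[MutationRecord]) -> pd.DataFrame:
    rows = []
    for m in mutations:
        rows.append(
            {
                "patient_id": m.patient_id,
                "sample_id": m.sample_id,
                "gene": m.gene,
                "protein_change": m.protein_change,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "context3": m.context3,
                "is_missense": m.is_missense,
                "oncokb_class": m.oncokb_class,
                "variant_key": m.variant_key,
            }
        )
    return pd.DataFrame(rows)
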