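"""Readers and writers for the tab-separated table dialects.

All tables are TSV with a header row; ``.gz`` paths are transparently
decompressed.  Readers reject individual malformed rows (logging a summary
count) rather than aborting a whole run on dirty data, but a structurally
broken table — a missing required column, conflicting duplicate scores —
raises immediately with the offending name in the message.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    BASES,
    BindingResidueMap,
    MethodSpec,
    MutationRecord,
    ONCOKB_CLASSES,
    PanelCoverage,
    PathwaySpec,
    PatientRecord,
    RecordValidationError,
    ScoreMatrix,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MAF_REQUIRED = (
    "Hugo_Symbol",
    "HGVSp_Short",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)


class MissingColumnError(RecordValidationError):
    """A required column is absent; ``.column`` names it."""

    def __init__(self, column: str, path: PathLike):
        self.column = column
        super().__init__(f"required column {column!r} missing from {path}")


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # pandas infers gzip from the suffix
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value if value not in ("", ".", "NA", "nan") else None


def read_mutation_table(path: PathLike, dialect: str = "maf") -> List[MutationRecord]:
    """Parse a MAF-style mutation TSV into records.

    ``Variant_Classification == "Missense_Mutation"`` sets ``is_missense``;
    unknown values in the optional ``oncokb_class`` column map to
    ``"unknown"``.  Rows that violate record invariants (e.g. a two-base
    ref allele) are dropped individually; the dropped count is logged.
    """
    if dialect != "maf":
        raise ValueError(f"unknown mutation table dialect {dialect!r}")
    df = _read_tsv(path)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(col, path)
    records: List[MutationRecord] = []
    n_rejected = 0
    has_onco = "oncokb_class" in df.columns
    for _, row in df.iterrows():
        onco = row["oncokb_class"].strip().lower() if has_onco else "unknown"
        if onco not in ONCOKB_CLASSES:
            onco = "unknown"
        pos = _opt(row["Start_Position"]) if "Start_Position" in df.columns else None
        try:
            rec = MutationRecord(
                patient_id=_opt(row["Patient_ID"]) or row["Tumor_Sample_Barcode"]
                if "Patient_ID" in df.columns
                else row["Tumor_Sample_Barcode"],
                sample_id=row["Tumor_Sample_Barcode"],
                gene=row["Hugo_Symbol"],
                protein_change=_opt(row["HGVSp_Short"]),
                chrom=_opt(row["Chromosome"]) if "Chromosome" in df.columns else None,
                pos=int(pos) if pos is not None else None,
                ref=_opt(row["Reference_Allele"])
                if "Reference_Allele" in df.columns
                else None,
                alt=_opt(row["Tumor_Seq_Allele2"])
                if "Tumor_Seq_Allele2" in df.columns
                else None,
                context3=_opt(row["Ref_Tri"]) if "Ref_Tri" in df.columns else None,
                is_missense=row["Variant_Classification"] == "Missense_Mutation",
                oncokb_class=onco,
            )
        except (RecordValidationError, ValueError) as exc:
            n_rejected += 1
            logger.debug("rejected mutation row: %s", exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("read_mutation_table: rejected %d malformed rows", n_rejected)
    read_mutation_table.last_rejected = n_rejected  # type: ignore[attr-defined]
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: PathLike) -> None:
    rows = []
    for m in records:
        rows.append(
            {
                "Hugo_Symbol": m.gene,
                "HGVSp_Short": m.protein_change or "",
                "Variant_Classification": "Missense_Mutation"
                if m.is_missense
                else "Other",
                "Tumor_Sample_Barcode": m.sample_id,
                "Patient_ID": m.patient_id,
                "Chromosome": m.chrom or "",
                "Start_Position": "" if m.pos is None else str(m.pos),
                "Reference_Allele": m.ref or "",
                "Tumor_Seq_Allele2": m.alt or "",
                "Ref_Tri": m.context3 or "",
                "oncokb_class": m.oncokb_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


CLINICAL_REQUIRED = ("patient_id", "t_dx", "t_entry", "t_end", "event")

_NON_COVARIATE = {
    "patient_id",
    "cohort_id",
    "panel_id",
    "tmb",
    "msi_score",
    "t_dx",
    "t_entry",
    "t_end",
    "event",
}


def read_clinical_table(path: PathLike) -> List[PatientRecord]:
    """Parse the clinical/survival TSV.

    Times are months from diagnosis.  Rows violating the time ordering
    ``t_dx <= t_entry <= t_end`` are rejected and logged; a non-numeric
    ``tmb`` is a hard error.
    """
    df = _read_tsv(path)
    if df.empty and not set(CLINICAL_REQUIRED) <= set(df.columns):
        logger.warning("read_clinical_table: empty file %s", path)
        return []
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(col, path)
    cov_cols = [c for c in df.columns if c not in _NON_COVARIATE]
    patients: List[PatientRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        tmb_raw = _opt(row["tmb"]) if "tmb" in df.columns else None
        if tmb_raw is not None:
            try:
                tmb = float(tmb_raw)
            except ValueError as exc:
                raise RecordValidationError(
                    f"non-numeric tmb {tmb_raw!r} for patient {row['patient_id']!r}"
                ) from exc
        else:
            tmb = None
        msi_raw = _opt(row["msi_score"]) if "msi_score" in df.columns else None
        covariates = {}
        for c in cov_cols:
            v = _opt(row[c])
            if v is None:
                continue
            try:
                covariates[c] = float(v)
            except ValueError:
                covariates[c] = v  # categorical covariates stay as strings
        try:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    cohort_id=_opt(row["cohort_id"]) or "cohort"
                    if "cohort_id" in df.columns
                    else "cohort",
                    panel_id=_opt(row["panel_id"]) or "panel"
                    if "panel_id" in df.columns
                    else "panel",
                    covariates=covariates,
                    tmb=tmb,
                    msi_score=float(msi_raw) if msi_raw is not None else None,
                    t_dx=float(row["t_dx"]),
                    t_entry=float(row["t_entry"]),
                    t_end=float(row["t_end"]),
                    event=bool(int(float(row["event"]))),
                )
            )
        except RecordValidationError as exc:
            n_rejected += 1
            logger.warning("rejected patient row: %s", exc)
    if n_rejected:
        logger.warning("read_clinical_table: rejected %d rows", n_rejected)
    read_clinical_table.last_rejected = n_rejected  # type: ignore[attr-defined]
    if not patients:
        logger.warning("read_clinical_table: no valid patients in %s", path)
    return patients


def write_clinical_table(patients: Sequence[PatientRecord], path: PathLike) -> None:
    from .types import patients_to_frame

    patients_to_frame(patients).to_csv(path, sep="\t", index=False)


def read_score_table(
    path: PathLike, methods: Sequence[MethodSpec]
) -> ScoreMatrix:
    """Parse a dbNSFP-style wide score TSV into a :class:`ScoreMatrix`.

    One column per method plus ``gene`` and ``protein_change`` key columns;
    ``"."`` or empty cells are missing.  Duplicate variant keys with
    identical scores deduplicate silently; conflicting duplicates raise,
    listing the keys.
    """
    df = _read_tsv(path)
    for col in ("gene", "protein_change"):
        if col not in df.columns:
            raise MissingColumnError(col, path)
    names = [m.name for m in methods]
    for name in names:
        if name not in df.columns:
            raise MissingColumnError(name, path)
    df = df.assign(variant_key=df["gene"] + ":" + df["protein_change"])
    parsed = df[["variant_key"]].copy()
    for name in names:
        parsed[name] = pd.to_numeric(
            df[name].map(lambda v: _opt(v)), errors="raise"
        )
    dedup = parsed.drop_duplicates()
    conflicts = dedup["variant_key"][dedup["variant_key"].duplicated()].unique()
    if len(conflicts):
        raise RecordValidationError(
            "conflicting duplicate scores for variant keys: "
            + ", ".join(sorted(conflicts))
        )
    dedup = dedup.set_index("variant_key")
    for name in names:
        logger.info(
            "read_score_table: %s has %d non-missing scores",
            name,
            int(dedup[name].notna().sum()),
        )
    return ScoreMatrix(dedup)


def write_score_table(matrix: ScoreMatrix, path: PathLike) -> None:
    out = matrix.frame.copy()
    keys = out.index.to_series().str.split(":", n=1, expand=True)
    out.insert(0, "gene", keys[0].to_numpy())
    out.insert(1, "protein_change", keys[1].to_numpy())
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_panel_table(path: PathLike) -> PanelCoverage:
    """Two-column TSV (panel_id, gene) -> :class:`PanelCoverage`."""
    df = _read_tsv(path)
    for col in ("panel_id", "gene"):
        if col not in df.columns:
            raise MissingColumnError(col, path)
    panels: Dict[str, set] = {}
    for _, row in df.iterrows():
        panels.setdefault(row["panel_id"], set()).add(row["gene"])
    return PanelCoverage(panels)


def write_panel_table(coverage: PanelCoverage, path: PathLike) -> None:
    rows = [
        {"panel_id": pid, "gene": g}
        for pid, genes in sorted(coverage.panels.items())
        for g in sorted(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pathway_table(path: PathLike) -> List[PathwaySpec]:
    """Two-column TSV (pathway, gene) -> pathway specs."""
    df = _read_tsv(path)
    for col in ("pathway", "gene"):
        if col not in df.columns:
            raise MissingColumnError(col, path)
    out = []
    for name, grp in df.groupby("pathway", sort=True):
        out.append(PathwaySpec(name=name, genes=tuple(dict.fromkeys(grp["gene"]))))
    return out


def write_pathway_table(pathways: Sequence[PathwaySpec], path: PathLike) -> None:
    rows = [{"pathway": p.name, "gene": g} for p in pathways for g in p.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_binding_table(path: PathLike) -> BindingResidueMap:
    """Three-column TSV (gene, residue, source) -> binding-residue map."""
    df = _read_tsv(path)
    for col in ("gene", "residue", "source"):
        if col not in df.columns:
            raise MissingColumnError(col, path)
    bmap = BindingResidueMap()
    for _, row in df.iterrows():
        bmap.add(row["gene"], int(row["residue"]), row["source"])
    return bmap


def read_profile_table(path: PathLike):
    """96-row TSV (context, alt, probability) -> :class:`ContextProfile`."""
    from .sbs96 import ContextProfile, SBS96_CATEGORIES

    df = _read_tsv(path)
    for col in ("context", "alt", "probability"):
        if col not in df.columns:
            raise MissingColumnError(col, path)
    probs = {
        (row["context"], row["alt"]): float(row["probability"])
        for _, row in df.iterrows()
    }
    vec = np.array([probs.get(cat, 0.0) for cat in SBS96_CATEGORIES])
    return ContextProfile(vec / vec.sum())


def write_profile_table(profile, path: PathLike) -> None:
    from .sbs96 import SBS96_CATEGORIES

    rows = [
        {"context": ctx, "alt": alt, "probability": profile.probabilities[i]}
        for i, (ctx, alt) in enumerate(SBS96_CATEGORIES)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_binding_table(bmap: BindingResidueMap, path: PathLike) -> None:
    rows = [
        {"gene": g, "residue": r, "source": s} for g, r, s in sorted(bmap.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
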