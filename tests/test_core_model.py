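"""Domain types, readers/writers, derived flags, panel filtering."""
import numpy as np
import pandas as pd
import pytest

from vepbench import io as vio
from vepbench.types import (
    MutationRecord,
    PanelCoverage,
    PatientRecord,
    RecordValidationError,
    ScoreMatrix,
    derive_clinical_flags,
    filter_panel,
    parse_protein_position,
)


class TestMutationRecord:
    def test_invariants_rejected(self):
        with pytest.raises(RecordValidationError):
            MutationRecord("p1", "s1", "KRAS", ref="AC", alt="T")
        with pytest.raises(RecordValidationError):
            MutationRecord("p1", "s1", "KRAS", ref="A", alt="A")
        with pytest.raises(RecordValidationError):
            MutationRecord("p1", "s1", "KRAS", ref="A", alt="T", context3="GCT")
        with pytest.raises(RecordValidationError):
            MutationRecord("p1", "s1", "")

    def test_variant_key_prefers_protein_change(self):
        m = MutationRecord("p1", "s1", "BRAF", protein_change="p.V600E")
        assert m.variant_key == "BRAF:p.V600E"
        assert m.residue == 600

    @pytest.mark.parametrize(
        "pchange,expected",
        [("p.V600E", 600), ("p.?", None), (None, None), ("p.M1fs", None)],
    )
    def test_protein_position_parsing(self, pchange, expected):
        assert parse_protein_position(pchange) == expected


class TestClinicalFlags:
    @pytest.mark.parametrize(
        "tmb,msi,expect",
        [
            (10.0, 1.0, (True, False)),  # TMB boundary inclusive
            (9.99, 10.0, (False, False)),  # MSI boundary strict
            (15.0, 10.01, (True, True)),
            (None, None, (None, None)),  # undefined, not False
        ],
    )
    def test_boundary_semantics(self, tmb, msi, expect):
        p = PatientRecord("p1", tmb=tmb, msi_score=msi, t_end=1.0)
        assert derive_clinical_flags(p) == expect


class TestPanelFilter:
    def test_filters_and_preserves_order(self, toy_patients):
        cov = PanelCoverage(
            {"panel": {"KEAP1", "TP53"}, "small": {"TP53"}}
        )
        toy_patients[2].panel_id = "small"
        kept = filter_panel(toy_patients, cov, "KEAP1")
        assert [p.patient_id for p in kept] == [
            p.patient_id for p in toy_patients if p.panel_id == "panel"
        ]
        # idempotent, never grows
        assert filter_panel(kept, cov, "KEAP1") == kept
        assert filter_panel(toy_patients, cov, "TP53") == toy_patients
        assert filter_panel(toy_patients, cov, "EGFR") == []

    def test_unknown_panel_errors(self, toy_patients):
        cov = PanelCoverage({"other": {"KEAP1"}})
        with pytest.raises(KeyError):
            filter_panel(toy_patients, cov, "KEAP1")


class TestMutationTableIO:
    def _write(self, tmp_path, rows, columns):
        path = tmp_path / "muts.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    def test_round_trip(self, tmp_path):
        records = [
            MutationRecord(
                "p1", "s1", "BRAF", protein_change="p.V600E",
                chrom="7", pos=140753336, ref="A", alt="T", context3="CAC",
                is_missense=True, oncokb_class="oncogenic",
            ),
            MutationRecord("p2", "s2", "KRAS", protein_change="p.G12D",
                           is_missense=True, oncokb_class="vus"),
        ]
        path = tmp_path / "rt.tsv"
        vio.write_mutation_table(records, path)
        back = vio.read_mutation_table(path)
        assert len(back) == 2
        assert back[0] == records[0]
        assert back[1] == records[1]

    def test_missing_required_column_named(self, tmp_path):
        path = self._write(
            tmp_path,
            [["p.V600E", "Missense_Mutation", "s1"]],
            ["HGVSp_Short", "Variant_Classification", "Tumor_Sample_Barcode"],
        )
        with pytest.raises(vio.MissingColumnError, match="Hugo_Symbol"):
            vio.read_mutation_table(path)

    def test_malformed_base_rejected_row_level(self, tmp_path):
        cols = [
            "Hugo_Symbol", "HGVSp_Short", "Variant_Classification",
            "Tumor_Sample_Barcode", "Reference_Allele", "Tumor_Seq_Allele2",
        ]
        rows = [
            ["BRAF", "p.V600E", "Missense_Mutation", "s1", "A", "T"],
            ["KRAS", "p.G12D", "Missense_Mutation", "s2", "AC", "T"],  # bad ref
            ["TP53", "p.R175H", "Missense_Mutation", "s3", "G", "A"],
        ]
        path = self._write(tmp_path, rows, cols)
        records = vio.read_mutation_table(path)
        assert [r.gene for r in records] == ["BRAF", "TP53"]
        assert vio.read_mutation_table.last_rejected == 1

    def test_unknown_oncokb_value_maps_to_unknown(self, tmp_path):
        cols = [
            "Hugo_Symbol", "HGVSp_Short", "Variant_Classification",
            "Tumor_Sample_Barcode", "oncokb_class",
        ]
        path = self._write(
            tmp_path, [["BRAF", "p.V600E", "Missense_Mutation", "s1", "weird"]], cols
        )
        assert vio.read_mutation_table(path)[0].oncokb_class == "unknown"

    def test_gzip_tolerated(self, tmp_path):
        records = [MutationRecord("p1", "s1", "BRAF", protein_change="p.V600E")]
        path = tmp_path / "rt.tsv.gz"
        vio.write_mutation_table(records, path)
        assert vio.read_mutation_table(path)[0].gene == "BRAF"


class TestClinicalTableIO:
    def test_accept_and_reject_by_time_order(self, tmp_path):
        path = tmp_path / "clin.tsv"
        pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "t_dx": [0.0, 0.0],
                "t_entry": [3.0, 25.0],
                "t_end": [20.0, 20.0],  # b violates t_entry <= t_end
                "event": [1, 0],
                "tmb": [4.0, 2.0],
            }
        ).to_csv(path, sep="\t", index=False)
        patients = vio.read_clinical_table(path)
        assert [p.patient_id for p in patients] == ["a"]
        assert vio.read_clinical_table.last_rejected == 1

    def test_empty_file_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert vio.read_clinical_table(path) == []

    def test_non_numeric_tmb_is_hard_error(self, tmp_path):
        path = tmp_path / "clin.tsv"
        pd.DataFrame(
            {
                "patient_id": ["a"], "t_dx": [0.0], "t_entry": [1.0],
                "t_end": [2.0], "event": [1], "tmb": ["high"],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(RecordValidationError, match="tmb"):
            vio.read_clinical_table(path)


class TestScoreTableIO:
    def _path(self, tmp_path, df):
        path = tmp_path / "scores.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def _specs(self):
        from vepbench.types import MethodSpec

        return [MethodSpec("m1"), MethodSpec("m2")]

    def test_missing_cell_and_dedup(self, tmp_path):
        df = pd.DataFrame(
            {
                "gene": ["G1", "G1", "G2"],
                "protein_change": ["p.A1V", "p.A1V", "p.C2F"],
                "m1": [0.5, 0.5, "."],
                "m2": [0.1, 0.1, 0.9],
            }
        )
        matrix = vio.read_score_table(self._path(tmp_path, df), self._specs())
        assert len(matrix) == 2  # identical duplicate dropped silently
        assert np.isnan(matrix.scores("m1").loc["G2:p.C2F"])

    def test_conflicting_duplicates_error(self, tmp_path):
        df = pd.DataFrame(
            {
                "gene": ["G1", "G1"],
                "protein_change": ["p.A1V", "p.A1V"],
                "m1": [0.5, 0.6],
                "m2": [0.1, 0.1],
            }
        )
        with pytest.raises(RecordValidationError, match="G1:p.A1V"):
            vio.read_score_table(self._path(tmp_path, df), self._specs())

    def test_round_trip(self, tmp_path, small_scores):
        path = tmp_path / "scores.tsv"
        vio.write_score_table(small_scores, path)
        back = vio.read_score_table(
            path, [__import__("vepbench").MethodSpec("m1"),
                   __import__("vepbench").MethodSpec("m2")]
        )
        pd.testing.assert_frame_equal(
            back.frame.sort_index(), small_scores.frame.sort_index()
        )


class TestSmallTableIO:
    def test_pathway_binding_panel_round_trip(self, tmp_path):
        from vepbench.types import BindingResidueMap, PathwaySpec

        pws = [PathwaySpec("NRF2", ("KEAP1", "NFE2L2"))]
        vio.write_pathway_table(pws, tmp_path / "pw.tsv")
        assert vio.read_pathway_table(tmp_path / "pw.tsv") == pws

        bmap = BindingResidueMap()
        bmap.add("KEAP1", 333, "ligand")
        bmap.add("KEAP1", 334, "ppi_hotspot")
        vio.write_binding_table(bmap, tmp_path / "b.tsv")
        back = vio.read_binding_table(tmp_path / "b.tsv")
        assert back.residues("KEAP1") == {333, 334}

        cov = PanelCoverage({"pA": {"KEAP1", "TP53"}, "pB": {"TP53"}})
        vio.write_panel_table(cov, tmp_path / "p.tsv")
        assert vio.read_panel_table(tmp_path / "p.tsv").panels == cov.panels
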