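"""Mutual-exclusivity tables, exact tests, pathway rate, OR_mutex, logistic."""
import numpy as np
import pytest

from vepbench.mutex import (
    MutexResult,
    build_mutex_table,
    mutex_battery,
    mutex_fisher,
    or_mutex,
    pathway_rate,
    tmb_adjusted_logistic,
)
from vepbench.types import MutationRecord, PathwaySpec, PatientRecord


NRF2 = PathwaySpec("NRF2", ("KEAP1", "NFE2L2", "CUL3"))


@pytest.fixture
def keap1_classifications():
    return {
        "KEAP1:p.R320Q": "pathogenic",
        "KEAP1:p.G333C": "pathogenic",
    }


class TestBuildMutexTable:
    def test_eight_patient_fixture(
        self, toy_mutations, toy_patients, keap1_classifications
    ):
        table = build_mutex_table(
            "KEAP1", NRF2, keap1_classifications, toy_patients, toy_mutations
        )
        # hand count: p3 pathogenic+pathway-oncogenic; p1,p2 pathogenic only;
        # p4,p5,p6 oncogenic only; p7,p8 neither
        assert table == [[1, 2], [3, 2]]

    def test_no_pathogenic_carriers_zero_row(
        self, toy_mutations, toy_patients
    ):
        table = build_mutex_table("KEAP1", NRF2, {}, toy_patients, toy_mutations)
        assert table[0] == [0, 0]

    def test_single_gene_pathway(self, toy_mutations, toy_patients):
        pw = PathwaySpec("solo", ("KEAP1",))
        table = build_mutex_table("KEAP1", pw, {}, toy_patients, toy_mutations)
        # only p6 carries an oncogenic KEAP1 mutation
        assert table == [[0, 0], [1, 7]]

    def test_gene_not_in_pathway_raises(self, toy_mutations, toy_patients):
        with pytest.raises(ValueError):
            build_mutex_table("BRAF", NRF2, {}, toy_patients, toy_mutations)


class TestMutexFisher:
    def test_exclusive_table_significant(self):
        res = mutex_fisher([[0, 5], [5, 0]])
        assert res.p == pytest.approx(2 / 252, abs=1e-12)
        assert res.log_or < 0
        mutex_battery([res])
        assert res.significant

    def test_flat_table_not_significant(self):
        res = mutex_fisher([[10, 10], [10, 10]])
        mutex_battery([res])
        assert res.log_or == 0.0 and not res.significant

    def test_positive_log_or_never_significant(self):
        res = mutex_fisher([[5, 0], [0, 5]])
        mutex_battery([res])
        assert res.p < 0.01 and res.log_or > 0
        assert not res.significant

    def test_zero_margin_skipped(self):
        assert mutex_fisher([[0, 0], [3, 4]]) is None


class TestPathwayRate:
    def test_denominator_is_all_genes(self):
        results = [
            MutexResult("KEAP1", "NRF2", [[0, 5], [5, 0]], -2.0, 0.001, q=0.01),
            MutexResult("NFE2L2", "NRF2", [[2, 2], [2, 2]], 0.0, 1.0, q=1.0),
        ]
        # CUL3 untestable, still in the denominator
        assert pathway_rate(results, NRF2) == pytest.approx(1 / 3)
        assert pathway_rate([], NRF2) == 0.0

    def test_monotone_in_significant_results(self):
        base = [
            MutexResult("KEAP1", "NRF2", [[0, 5], [5, 0]], -2.0, 0.001, q=0.01)
        ]
        more = base + [
            MutexResult("CUL3", "NRF2", [[0, 4], [6, 0]], -2.0, 0.001, q=0.01)
        ]
        assert pathway_rate(more, NRF2) >= pathway_rate(base, NRF2)


class TestOrMutex:
    def _cohort(self, n_path_comut, n_path_free, n_ben_comut, n_ben_free):
        patients, mutations = [], []
        cls = {}
        i = 0
        for count, call, comut in [
            (n_path_comut, "pathogenic", True),
            (n_path_free, "pathogenic", False),
            (n_ben_comut, "benign", True),
            (n_ben_free, "benign", False),
        ]:
            for _ in range(count):
                pid = f"p{i}"
                i += 1
                patients.append(PatientRecord(pid, t_end=10.0))
                pchange = f"p.R{i}Q"
                mutations.append(
                    MutationRecord(pid, pid, "KEAP1", protein_change=pchange,
                                   oncokb_class="vus")
                )
                cls[f"KEAP1:{pchange}"] = call
                if comut:
                    mutations.append(
                        MutationRecord(pid, pid, "NFE2L2",
                                       protein_change="p.E79Q",
                                       oncokb_class="oncogenic")
                    )
        return patients, mutations, cls

    def test_exclusive_drivers_or_below_one(self):
        patients, mutations, cls = self._cohort(0, 10, 10, 0)
        res = or_mutex(cls, patients, mutations, "KEAP1", NRF2)
        assert (res.a, res.b, res.c, res.d) == (0, 10, 10, 0)
        assert res.or_point == pytest.approx(1 / 441)

    def test_identical_rates_or_one(self):
        patients, mutations, cls = self._cohort(5, 5, 5, 5)
        res = or_mutex(cls, patients, mutations, "KEAP1", NRF2)
        assert res.or_point == pytest.approx(1.0)

    def test_underpowered_returns_none(self):
        patients, mutations, cls = self._cohort(3, 3, 0, 0)
        assert or_mutex(cls, patients, mutations, "KEAP1", NRF2) is None

    def test_focal_gene_excluded_from_column(self):
        # a KEAP1 oncogenic co-mutation must NOT count: column is "other genes"
        patients = [PatientRecord("p0", t_end=5.0), PatientRecord("p1", t_end=5.0)]
        mutations = [
            MutationRecord("p0", "p0", "KEAP1", protein_change="p.R1Q",
                           oncokb_class="vus"),
            MutationRecord("p0", "p0", "KEAP1", protein_change="p.G480W",
                           oncokb_class="oncogenic"),
            MutationRecord("p1", "p1", "KEAP1", protein_change="p.R2Q",
                           oncokb_class="vus"),
            MutationRecord("p1", "p1", "NFE2L2", protein_change="p.E79Q",
                           oncokb_class="oncogenic"),
        ]
        cls = {"KEAP1:p.R1Q": "pathogenic", "KEAP1:p.R2Q": "benign"}
        res = or_mutex(cls, patients, mutations, "KEAP1", NRF2)
        # p0's KEAP1 oncogenic co-mutation does not count; p1's NFE2L2 does
        assert (res.a, res.b, res.c, res.d) == (0, 1, 1, 0)


class TestTmbAdjustedLogistic:
    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        n = 2000
        tmb_high = rng.random(n) < 0.3
        mut = rng.random(n) < 0.2
        outcome = rng.random(n) < 0.4
        res = tmb_adjusted_logistic(list(zip(outcome, mut, tmb_high)))
        assert not res.separation
        assert abs(res.coef_mutation) < 0.15

    def test_recovers_negative_association(self):
        rng = np.random.default_rng(5)
        n = 5000
        tmb_high = rng.random(n) < 0.3
        mut = rng.random(n) < 0.25
        logit = -0.2 + 1.0 * tmb_high - 1.0 * mut
        outcome = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = tmb_adjusted_logistic(list(zip(outcome, mut, tmb_high)))
        assert res.coef_mutation == pytest.approx(-1.0, abs=0.2)
        assert res.coef_tmb_high == pytest.approx(1.0, abs=0.2)

    def test_separation_flagged(self):
        rows = [(bool(i % 2), False, bool(i % 2)) for i in range(40)]
        res = tmb_adjusted_logistic(rows)
        assert res.separation and np.isnan(res.coef_mutation)

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError):
            tmb_adjusted_logistic([(True, False, False)] * 20)


class TestCalibrationUnderIndependence:
    def test_type_one_and_power(self):
        # under OR = 1 the significance rate stays near nominal; under a
        # strong exclusivity OR = 0.1 at n = 1000 the test has high power
        from vepbench.simulate import sample_exclusive_pair

        rng = np.random.default_rng(6)
        results_null, results_alt = [], []
        for i in range(100):
            a, b = sample_exclusive_pair(0.15, 0.3, 1.0, rng)
            a, b = (
                rng.random(1000) < 0.15,
                rng.random(1000) < 0.3,
            )
            t = [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
            results_null.append(mutex_fisher(t, gene=f"g{i}"))
            a2, b2 = sample_exclusive_pair(
                np.full(1000, 0.15), np.full(1000, 0.3), 0.1, rng
            )
            t2 = [
                [int((a2 & b2).sum()), int((a2 & ~b2).sum())],
                [int((~a2 & b2).sum()), int((~a2 & ~b2).sum())],
            ]
            results_alt.append(mutex_fisher(t2, gene=f"g{i}"))
        mutex_battery(results_null)
        mutex_battery(results_alt)
        null_rate = np.mean([r.significant for r in results_null])
        power = np.mean([r.significant for r in results_alt])
        assert null_rate <= 0.12
        assert power >= 0.9
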