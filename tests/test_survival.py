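"""Gene strata, IPTW, weighted left-truncated Cox/KM, RR, two-stage FDR."""
import numpy as np
import pandas as pd
import pytest

from vepbench.survival import (
    CoxResult,
    PositivityError,
    assign_gene_strata,
    discovery_confirmation,
    double_mutant_analysis,
    estimate_iptw,
    rr_survival,
    weighted_cox,
    weighted_km,
)
from vepbench.types import (
    MutationRecord,
    PanelCoverage,
    PatientRecord,
)


def _patient(pid, entry=0.0, end=10.0, event=True, **cov):
    return PatientRecord(
        pid, covariates=cov, t_dx=0.0, t_entry=entry, t_end=end, event=event
    )


class TestAssignGeneStrata:
    def _muts(self):
        return [
            MutationRecord("p1", "s", "KEAP1", protein_change="p.G480W",
                           oncokb_class="oncogenic"),
            MutationRecord("p1", "s", "KEAP1", protein_change="p.R320Q",
                           oncokb_class="vus"),
            MutationRecord("p2", "s", "KEAP1", protein_change="p.R320Q",
                           oncokb_class="vus"),
            MutationRecord("p3", "s", "KEAP1", protein_change="p.G333C",
                           oncokb_class="vus"),
            MutationRecord("p4", "s", "KEAP1", protein_change="p.A510V",
                           oncokb_class="vus"),
        ]

    def test_precedence_and_groups(self):
        patients = [_patient(f"p{i}") for i in range(1, 6)]
        cls = {
            "KEAP1:p.R320Q": "pathogenic",
            "KEAP1:p.G333C": "benign",
            "KEAP1:p.A510V": "uncertain",
        }
        strata = assign_gene_strata(patients, self._muts(), cls, "KEAP1")
        assert strata.groups["p1"] == "oncogenic"  # oncogenic beats pathogenic
        assert strata.groups["p2"] == "reclassified_pathogenic"
        assert strata.groups["p3"] == "reclassified_benign"
        assert strata.groups["p4"] == "no_mutation"  # uncertain does not promote
        assert strata.groups["p5"] == "no_mutation"

    def test_panel_uncovered_excluded(self):
        patients = [_patient("p1"), _patient("p2")]
        patients[1].panel_id = "small"
        cov = PanelCoverage({"panel": {"KEAP1"}, "small": {"TP53"}})
        strata = assign_gene_strata(patients, self._muts(), {}, "KEAP1", cov)
        assert strata.groups["p2"] == "excluded"


class TestEstimateIptw:
    def test_hand_computed_stabilized_weights(self):
        # x=0: 1 treated / 2 ref; x=1: 2 treated / 1 ref
        # e(0)=1/3, e(1)=2/3, marginal 1/2
        patients = [
            _patient("t0", x=0.0), _patient("r0a", x=0.0), _patient("r0b", x=0.0),
            _patient("t1a", x=1.0), _patient("t1b", x=1.0), _patient("r1", x=1.0),
        ]
        group = {"t0": True, "r0a": False, "r0b": False,
                 "t1a": True, "t1b": True, "r1": False}
        ws = estimate_iptw(patients, group, ["x"])
        w = ws.weights
        assert w["t0"] == pytest.approx(1.5, abs=1e-6)
        assert w["t1a"] == pytest.approx(0.75, abs=1e-6)
        assert w["r0a"] == pytest.approx(0.75, abs=1e-6)
        assert w["r1"] == pytest.approx(1.5, abs=1e-6)
        assert 0.8 <= ws.mean_weight <= 1.2

    def test_no_confounding_weights_near_one(self):
        rng = np.random.default_rng(0)
        patients = [
            _patient(f"p{i}", x=float(rng.normal())) for i in range(200)
        ]
        group = {p.patient_id: bool(i % 2) for i, p in enumerate(patients)}
        ws = estimate_iptw(patients, group, ["x"])
        assert np.allclose(ws.weights, 1.0, atol=0.35)
        assert ws.balance["smd_after"].abs().max() < 0.25

    def test_perfect_predictor_positivity_error(self):
        patients = [_patient(f"p{i}", x=float(i < 10)) for i in range(20)]
        group = {p.patient_id: p.covariates["x"] == 1.0 for p in patients}
        with pytest.raises(PositivityError):
            estimate_iptw(patients, group, ["x"])


def _lifelines_fit(patients, group, weights=None, entry=True, robust=False):
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "t": [p.t_end - p.t_dx for p in patients],
            "e": [int(p.event) for p in patients],
            "g": [int(group[p.patient_id]) for p in patients],
        }
    )
    if entry:
        df["entry"] = [p.t_entry - p.t_dx for p in patients]
    if weights is not None:
        df["w"] = [weights[p.patient_id] for p in patients]
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="t",
        event_col="e",
        entry_col="entry" if entry else None,
        weights_col="w" if weights is not None else None,
        robust=robust,
        formula="g",
    )
    return float(cph.params_.iloc[0]), float(cph.standard_errors_.iloc[0])


@pytest.fixture
def survival_cohort():
    rng = np.random.default_rng(42)
    patients, group = [], {}
    for i in range(150):
        g = i % 2 == 0
        t = float(rng.exponential(10.0 / (2.0 if g else 1.0)))
        end = min(t, 25.0)
        patients.append(
            _patient(f"p{i}", entry=0.0, end=max(end, 1e-3), event=t <= 25.0)
        )
        group[f"p{i}"] = g
    return patients, group


class TestWeightedCox:
    def test_identical_arms_hr_one(self):
        patients = []
        group = {}
        for i in range(10):
            for arm in ("a", "b"):
                pid = f"{arm}{i}"
                patients.append(_patient(pid, end=float(i + 1), event=i % 2 == 0))
                group[pid] = arm == "a"
        res = weighted_cox(patients, group)
        assert res.hr == pytest.approx(1.0, abs=1e-8)

    def test_matches_untruncated_reference(self, survival_cohort):
        # unit weights and t_entry = t_dx: agree with lifelines to 1e-8
        patients, group = survival_cohort
        res = weighted_cox(patients, group, robust=False)
        ref_beta, ref_se = _lifelines_fit(patients, group, entry=False)
        assert res.log_hr == pytest.approx(ref_beta, abs=1e-8)
        assert res.se == pytest.approx(ref_se, abs=1e-6)

    def test_matches_lifelines_with_truncation_and_weights(self, survival_cohort):
        patients, group = survival_cohort
        rng = np.random.default_rng(1)
        for p in patients:  # delayed entry, still before exit
            p.t_entry = float(rng.uniform(0, 0.8) * p.t_end)
        weights = {p.patient_id: float(rng.uniform(0.5, 2.0)) for p in patients}
        res = weighted_cox(patients, group, weights, robust=True)
        ref_beta, _ = _lifelines_fit(
            patients, group, weights, entry=True, robust=True
        )
        assert res.log_hr == pytest.approx(ref_beta, abs=1e-6)
        # robust SE frozen from R survival::coxph(Surv(entry,t,e) ~ g,
        # weights=w, robust=TRUE, ties="breslow", id=id) on this fixture
        assert res.se == pytest.approx(0.1670917, abs=1e-6)

    def test_delayed_entry_risk_sets_hand_example(self):
        # 6 patients; entry times chosen so the risk sets at the three
        # event times are, by hand (entry < t <= exit):
        #   t=4: {A, C, D, E}; t=6: {B, C, D, E}; t=9: {E, F}
        # B enters only at 5 (late entry) and F only at 8
        spec = [
            ("A", 0.0, 4.0, True, 1),
            ("B", 5.0, 7.0, False, 1),
            ("C", 1.0, 6.0, True, 0),
            ("D", 2.0, 6.5, False, 0),
            ("E", 3.0, 9.0, True, 1),
            ("F", 8.0, 12.0, False, 0),
        ]
        patients = [
            _patient(pid, entry=en, end=ex, event=ev) for pid, en, ex, ev, _ in spec
        ]
        group = {pid: bool(g) for pid, _, _, _, g in spec}
        x = {pid: g for pid, _, _, _, g in spec}
        risk_sets = [
            ("A", ["A", "C", "D", "E"]),
            ("C", ["B", "C", "D", "E"]),
            ("E", ["E", "F"]),
        ]

        def neg_loglik(beta):
            ll = 0.0
            for dead, rs in risk_sets:
                ll += beta * x[dead] - np.log(
                    sum(np.exp(beta * x[pid]) for pid in rs)
                )
            return -ll

        from scipy.optimize import minimize_scalar

        ref = minimize_scalar(neg_loglik, bounds=(-5, 5), method="bounded")
        res = weighted_cox(patients, group)
        assert res.log_hr == pytest.approx(ref.x, abs=1e-5)

    def test_no_events_or_single_arm_errors(self):
        patients = [_patient("a", event=False), _patient("b", event=False)]
        with pytest.raises(ValueError):
            weighted_cox(patients, {"a": True, "b": False})
        patients = [_patient("a"), _patient("b")]
        with pytest.raises(ValueError):
            weighted_cox(patients, {"a": True, "b": True})


class TestWeightedKm:
    def test_product_limit_by_hand(self):
        pats = [
            _patient(f"p{i}", end=float(t), event=True)
            for i, t in enumerate([1, 2, 3])
        ]
        km = weighted_km({"s": pats}, min_stratum=1)["s"]
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_weight_scale_invariance(self):
        pats = [
            _patient(f"p{i}", end=float(t), event=i % 2 == 0)
            for i, t in enumerate([1, 2, 3, 4, 5])
        ]
        w1 = {p.patient_id: 1.3 for p in pats}
        w2 = {p.patient_id: 2.6 for p in pats}
        km1 = weighted_km({"s": pats}, w1, min_stratum=1)["s"]
        km2 = weighted_km({"s": pats}, w2, min_stratum=1)["s"]
        np.testing.assert_allclose(km1["survival"], km2["survival"])

    def test_unit_weights_match_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        pats = [
            _patient(
                f"p{i}",
                entry=float(rng.uniform(0, 2)),
                end=float(rng.uniform(2.5, 20)),
                event=bool(rng.random() < 0.7),
            )
            for i in range(60)
        ]
        km = weighted_km({"s": pats}, min_stratum=1)["s"]
        kmf = KaplanMeierFitter()
        kmf.fit(
            [p.t_end for p in pats],
            [int(p.event) for p in pats],
            entry=[p.t_entry for p in pats],
        )
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-10
            )

    def test_small_stratum_dropped(self):
        big = [_patient(f"b{i}", end=float(i + 1)) for i in range(12)]
        small = [_patient(f"s{i}", end=float(i + 1)) for i in range(9)]
        km = weighted_km({"big": big, "small": small})
        assert "small" not in km and "big" in km
        with pytest.raises(ValueError):
            weighted_km({"small": small})


class TestRRSurvival:
    def _cox(self, hr, gene="KEAP1", contrast="c"):
        return CoxResult(gene, contrast, hr, hr / 2, hr * 2, 0.01, 50, 50, True,
                         float(np.log(hr)), 0.1)

    def test_ratio_identity(self):
        refit = lambda rng: (2.0, 1.25)
        res = rr_survival(self._cox(2.0), self._cox(1.25), refit, 20, seed=1)
        assert res.rr == pytest.approx(1.6)
        res = rr_survival(self._cox(1.5), self._cox(1.5), refit, 20, seed=1)
        assert res.rr == pytest.approx(1.0)

    def test_excess_dropped_replicates_error(self):
        calls = iter(range(100))
        refit = lambda rng: None if next(calls) % 2 == 0 else (2.0, 1.0)
        with pytest.raises(ValueError, match="dropped"):
            rr_survival(self._cox(2.0), self._cox(1.0), refit, 40, seed=1)


class TestDoubleMutant:
    def _setup(self):
        patients = [_patient(f"p{i}", end=float(5 + i)) for i in range(30)]
        muts = []
        cls = {}

        def add(pid, gene, pchange, onco):
            muts.append(
                MutationRecord(pid, pid, gene, protein_change=pchange,
                               oncokb_class="oncogenic" if onco else "vus")
            )
            if not onco:
                cls[f"{gene}:{pchange}"] = "pathogenic"

        add("p0", "KEAP1", "p.R1Q", False)
        add("p0", "STK11", "p.F2L", False)  # double
        add("p1", "KEAP1", "p.R1Q", False)  # KEAP1 only
        add("p2", "STK11", "p.F2L", False)  # STK11 only
        add("p3", "KEAP1", "p.G480W", True)
        add("p3", "STK11", "p.F2L", False)  # oncogenic in KEAP1 -> excluded
        return patients, muts, cls

    def test_strata_and_oncogenic_exclusion(self):
        patients, muts, cls = self._setup()
        res = double_mutant_analysis(
            "KEAP1", "STK11", cls, patients, muts, min_stratum=1
        )
        assert res.strata_sizes["double"] == 1
        assert res.strata_sizes["KEAP1_only"] == 1
        assert res.strata_sizes["STK11_only"] == 1
        assert res.strata_sizes["neither"] == 26  # p3 excluded entirely
        assert res.n_excluded_oncogenic == 1

    def test_additive_hazards_recovered(self):
        # generator with additive log-hazards: the double stratum's log-HR
        # is near beta_a + beta_b
        rng = np.random.default_rng(7)
        n = 4000
        beta_a, beta_b = 0.5, 0.7
        a = rng.random(n) < 0.25
        b = rng.random(n) < 0.25
        lam = 0.05 * np.exp(beta_a * a + beta_b * b)
        t = rng.exponential(1 / lam)
        horizon = 40.0
        patients, muts, cls = [], [], {}
        for i in range(n):
            pid = f"p{i}"
            patients.append(
                _patient(pid, end=float(min(t[i], horizon)), event=t[i] <= horizon)
            )
            if a[i]:
                muts.append(
                    MutationRecord(pid, pid, "KEAP1", protein_change="p.R1Q",
                                   oncokb_class="vus")
                )
            if b[i]:
                muts.append(
                    MutationRecord(pid, pid, "STK11", protein_change="p.F2L",
                                   oncokb_class="vus")
                )
        cls = {"KEAP1:p.R1Q": "pathogenic", "STK11:p.F2L": "pathogenic"}
        res = double_mutant_analysis("KEAP1", "STK11", cls, patients, muts)
        assert res.cox["double"].log_hr == pytest.approx(
            beta_a + beta_b, abs=0.2
        )


class TestDiscoveryConfirmation:
    def _res(self, p, gene="G"):
        return CoxResult(gene, "c", 2.0, 1.5, 2.5, p, 50, 50, True, 0.7, 0.1)

    def test_bh_hand_example_all_pass(self):
        results = [self._res(p, f"g{i}") for i, p in
                   enumerate([0.01, 0.02, 0.04, 0.05])]
        rep = discovery_confirmation(results, fdr=0.1)
        assert len(rep.discovery_significant) == 4
        assert [round(r.q, 10) for r in rep.discovery] == [0.04, 0.04, 0.05, 0.05]

    def test_no_hits_skips_confirmation(self):
        rep = discovery_confirmation([self._res(0.9)], lambda r: self._res(0.01))
        assert rep.discovery_significant == [] and rep.confirmation == []

    def test_single_hit_confirmation_family_of_one(self):
        results = [self._res(0.001, "hit"), self._res(0.9, "miss")]
        rep = discovery_confirmation(
            results, lambda r: self._res(0.03, r.gene), fdr=0.1
        )
        assert [r.gene for r in rep.discovery_significant] == ["hit"]
        assert len(rep.confirmation) == 1
        assert rep.confirmation[0].q == pytest.approx(0.03)
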