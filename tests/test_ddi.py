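"""Interaction math: inhibition/induction factors, static equation, dynamic
co-simulation and the static-vs-dynamic oracle."""
import warnings

import numpy as np
import pytest

from pbpkddi import (DosingRegimen, build_clearance_model,
                     competitive_inhibition_factor, compute_pathway_fractions,
                     convert_concentration, induction_factor, make_fixture,
                     margin_report, simulate, simulate_subject_pair,
                     static_auc_ratio)
from pbpkddi.engine import compute_pk_metrics
from pbpkddi.fixtures import FixtureSpec


class TestFactors:
    @pytest.mark.parametrize("i,ki,expected", [
        (0.0, 0.205, 1.0),        # no inhibitor
        (0.205, 0.205, 0.5),      # half-inhibition point
        (0.118, 0.205, 0.6346),   # clinical Cmax,u vs OAT3 Ki
    ])
    def test_competitive_inhibition(self, i, ki, expected):
        assert competitive_inhibition_factor(i, ki) == pytest.approx(
            expected, abs=1e-3)

    def test_unbound_cmax_against_oat3_ki(self):
        # fu,p 0.006 × (8.0 µg/mL → µM) = 0.118 µM
        i_u = 0.006 * convert_concentration(8.0, 405.4)
        assert i_u == pytest.approx(0.118, abs=0.001)
        assert competitive_inhibition_factor(i_u, 0.205) == pytest.approx(
            0.634, abs=0.002)

    @pytest.mark.parametrize("i,ind_max,ind_c50,expected", [
        (0.0, 9.0, 1.0, 1.0),
        (1e9, 9.0, 1.0, 10.0),    # saturation → 1 + ind_max
        (1.0, 9.0, 1.0, 5.5),     # i = IndC50
    ])
    def test_induction(self, i, ind_max, ind_c50, expected):
        assert induction_factor(i, ind_max, ind_c50) == pytest.approx(
            expected, rel=1e-6)


class TestStaticEquation:
    def test_no_interaction_is_unity(self):
        assert static_auc_ratio({"a": 0.6, "b": 0.4}, {}) == 1.0

    def test_complete_inhibition_of_major_pathway(self):
        # fm 0.59 fully inhibited → 1/(1−0.59) = 2.44
        ratio = static_auc_ratio({"UGT1A1": 0.59, "rest": 0.41}, {"UGT1A1": 0.0})
        assert ratio == pytest.approx(2.439, abs=0.001)

    def test_poor_metabolizer_halving(self):
        # UGT1A1 activity halved on fm 0.59 → 1/(1−0.59×0.5) = 1.418
        ratio = static_auc_ratio({"UGT1A1": 0.59, "rest": 0.41}, {"UGT1A1": 0.5})
        assert ratio == pytest.approx(1.418, abs=0.001)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            static_auc_ratio({"a": 0.5, "b": 0.3}, {})


class TestMarginReport:
    def test_exposure_at_cap_has_unit_margin(self):
        assert margin_report(100.0, 270.0, 270.0) == pytest.approx(1.0)

    def test_reported_clinical_margin(self):
        # baseline AUC 145 µg·h/mL, cap 2.7×, DDI ratio 1.11 → 2.43 remaining
        baseline = 145.0
        assert margin_report(baseline, baseline * 1.11, 2.7 * baseline) == \
            pytest.approx(2.43, abs=0.005)

    def test_margin_monotone_in_ddi_ratio(self):
        margins = [margin_report(145.0, 145.0 * r, 2.7 * 145.0)
                   for r in (1.0, 1.1, 1.3)]
        assert margins[0] > margins[1] > margins[2]


@pytest.fixture(scope="module")
def oat3_victim():
    return make_fixture(FixtureSpec(role="oat3_victim", fe=0.8,
                                    secretion_split={"OAT3": 1.0}))


class TestDynamicDDI:
    def test_null_perpetrator_gives_unit_ratios(self, oat3_victim, ref_subject):
        null = make_fixture(FixtureSpec(role="null_compound"))
        with pytest.warns(UserWarning, match="no targets"):
            _, _, ratios = simulate_subject_pair(
                oat3_victim, null, ref_subject,
                DosingRegimen(dose=10.0, start_time=26.0),
                DosingRegimen(dose=30.0, n_doses=3, interval=24.0),
                grid_dt=0.25)
        assert ratios.auc_ratio == pytest.approx(1.0, rel=1e-9)
        assert ratios.cmax_ratio == pytest.approx(1.0, rel=1e-9)

    def test_constant_exposure_matches_static_oracle(self, oat3_victim,
                                                     ref_subject):
        # perpetrator clamped at constant unbound I: dynamic AUCR = static
        cl = build_clearance_model(oat3_victim, ref_subject)
        fractions = compute_pathway_fractions(cl)
        ki, i_u = 0.205, 0.4     # µM
        factor = competitive_inhibition_factor(i_u, ki)
        # decompose renal into filtration + OAT3 secretion sub-pathways
        scale = fractions["renal"] / cl.renal.cl_total
        static_fracs = {k: v for k, v in fractions.items() if k != "renal"}
        static_fracs["filtration"] = cl.renal.filtration * scale
        static_fracs["OAT3"] = cl.renal.secretion["OAT3"] * scale
        expected = static_auc_ratio(static_fracs, {"OAT3": factor})

        regimen = DosingRegimen(dose=10.0)
        base = simulate(oat3_victim, ref_subject, regimen, grid_dt=0.25)
        inhibited = simulate(oat3_victim, ref_subject, regimen,
                             modifiers={"OAT3": lambda t: factor},
                             grid_dt=0.25)
        aucr = (compute_pk_metrics(inhibited).auc_0_inf
                / compute_pk_metrics(base).auc_0_inf)
        assert aucr == pytest.approx(expected, rel=0.01)

    def test_saturation_bound(self, oat3_victim, ref_subject):
        # infinitely potent inhibition of OAT3 → AUCR → 1/(1−f_OAT3)
        cl = build_clearance_model(oat3_victim, ref_subject)
        f_oat3 = (cl.renal.secretion["OAT3"] * (1 - cl.renal.freab)
                  / cl.total_cl_plasma)
        regimen = DosingRegimen(dose=10.0)
        base = simulate(oat3_victim, ref_subject, regimen, grid_dt=0.25)
        blocked = simulate(oat3_victim, ref_subject, regimen,
                           modifiers={"OAT3": lambda t: 0.0}, grid_dt=0.25)
        aucr = (compute_pk_metrics(blocked).auc_0_inf
                / compute_pk_metrics(base).auc_0_inf)
        assert aucr == pytest.approx(1.0 / (1.0 - f_oat3), rel=0.01)

    def test_dynamic_ratio_within_static_bound_at_cmax(self, oat3_victim, cab,
                                                       ref_subject):
        # steady-state perpetrator: 1 ≤ AUCR ≤ static ratio at Cmax,u
        victim_regimen = DosingRegimen(dose=10.0, start_time=9 * 24.0 + 2.0)
        perp_regimen = DosingRegimen(dose=30.0, n_doses=14, interval=24.0)
        base, ddi, ratios = simulate_subject_pair(
            oat3_victim, cab, ref_subject, victim_regimen, perp_regimen,
            grid_dt=0.25)
        perp = simulate(cab, ref_subject, perp_regimen,
                        t_end=victim_regimen.start_time + 240.0, grid_dt=0.25)
        i_max = float(perp.unbound_systemic_um().max())
        factor = competitive_inhibition_factor(i_max, 0.205)
        cl = build_clearance_model(oat3_victim, ref_subject)
        fractions = compute_pathway_fractions(cl)
        scale = fractions["renal"] / cl.renal.cl_total
        static_fracs = {k: v for k, v in fractions.items() if k != "renal"}
        static_fracs["filtration"] = cl.renal.filtration * scale
        static_fracs["OAT3"] = cl.renal.secretion["OAT3"] * scale
        bound = static_auc_ratio(static_fracs, {"OAT3": factor})
        assert 1.0 < ratios.auc_ratio <= bound * 1.001

    def test_stagger_insensitivity_at_steady_state(self, oat3_victim, cab,
                                                   ref_subject):
        # perpetrator t½ ≫ τ: moving the victim dose ±2 h barely moves AUCR
        perp_regimen = DosingRegimen(dose=30.0, n_doses=14, interval=24.0)
        aucrs = []
        for stagger in (0.0, 2.0, 4.0):
            victim_regimen = DosingRegimen(dose=10.0,
                                           start_time=9 * 24.0 + stagger)
            _, _, ratios = simulate_subject_pair(
                oat3_victim, cab, ref_subject, victim_regimen, perp_regimen,
                grid_dt=0.25)
            aucrs.append(ratios.auc_ratio)
        spread = (max(aucrs) - min(aucrs)) / aucrs[1]
        assert spread < 0.02

    def test_induction_reduces_exposure(self, ref_subject):
        victim = make_fixture(FixtureSpec(role="null_compound", fm_map={
            "UGT1A1": 1.0}))
        inducer = make_fixture(FixtureSpec(
            role="ugt_inducer", induction_map={"UGT1A1": (9.0, 1.0)},
            cl_total=3.0, fu=0.2))
        _, _, ratios = simulate_subject_pair(
            victim, inducer, ref_subject,
            DosingRegimen(dose=10.0, start_time=7 * 24.0),
            DosingRegimen(dose=600.0, n_doses=10, interval=24.0),
            grid_dt=0.25)
        assert ratios.auc_ratio < 1.0
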