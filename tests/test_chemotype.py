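"""Chemotype rule engine, aMLG grouping and mating-type summaries."""

import itertools

import numpy as np
import pytest

from clonoscope.chemotype import (
    assign_amlg,
    chemotype_report,
    mating_summary,
    predict_chemotype,
)
from clonoscope.types import (
    ABSENT,
    DEFAULT_PANEL,
    MarkerState,
    MatingType,
    PRESENT,
    PSEUDOGENE,
    UNTESTED,
)

from .conftest import make_profile


def _profile(present=(), pseudogene_idtF=False, untested=(), **kw):
    states = {m: ABSENT for m in DEFAULT_PANEL.alkaloid_markers}
    for m in present:
        states[m] = PRESENT
    if pseudogene_idtF:
        states["idtF"] = PSEUDOGENE
    for m in untested:
        states[m] = UNTESTED
    return make_profile(**kw, **{k: v for k, v in states.items()})


EAS_ALL = ("dmaW", "easC", "easA", "cloA", "lpsB")
PPZ_ALL = ("perA5", "perAT2", "perAR")
IDT_FULL = ("idtG", "idtQ", "idtP", "idtF", "idtK", "idtJ")


class TestPredictChemotype:
    def test_complete_eas_without_reductase_predicts_erv_ppza2(self):
        # the dominant Faroese genotype: all EAS, perA5+perAT2, no IDT
        p = _profile(present=EAS_ALL + ("perA5", "perAT2"))
        assert predict_chemotype(p).label == "ERV/PPZA2"

    def test_full_panel_minus_idtJ_predicts_terpendole_c(self):
        # the dominant Spanish genotype: everything but idtJ functional
        p = _profile(present=EAS_ALL + PPZ_ALL + ("idtG", "idtQ", "idtP", "idtF", "idtK"))
        assert predict_chemotype(p).label == "ERV/PER/TDC"

    def test_pseudogene_idtF_stalls_at_terpendole_i(self):
        # the dominant Finnish genotype: early IDT with a pseudogene idtF
        p = _profile(
            present=EAS_ALL + ("perA5", "perAT2", "idtG", "idtQ", "idtP", "idtK"),
            pseudogene_idtF=True,
        )
        assert predict_chemotype(p).label == "ERV/PPZA2/TDI"

    def test_partial_eas_with_full_idt_gives_chanoclavine_and_lolitrem(self):
        p = _profile(present=("dmaW", "easC", "cloA") + PPZ_ALL + IDT_FULL)
        assert predict_chemotype(p).label == "CC/PER/LTB"

    def test_all_absent_predicts_nothing(self):
        p = _profile()
        pred = predict_chemotype(p)
        assert pred.label == ""
        assert pred.eas_product == pred.idt_product == "NONE"

    def test_untested_never_satisfies_a_requirement(self):
        # idtG present, idtQ absent, idtP untested: no paspaline call
        p = _profile(present=("idtG",), untested=("idtP",))
        assert predict_chemotype(p).idt_product == "NONE"

    def test_paspaline_keyed_on_idtP_in_default_rules(self):
        p = _profile(present=("idtG", "idtP"))
        assert predict_chemotype(p).idt_product == "PAS"
        # the prose variant keys paspaline on idtQ instead
        assert predict_chemotype(p, "methods_text").idt_product == "NONE"
        q = _profile(present=("idtG", "idtQ"))
        assert predict_chemotype(q, "methods_text").idt_product == "PAS"

    def test_methods_text_requires_functional_idtF_for_terpendole_i(self):
        p = _profile(present=("idtG", "idtQ"), pseudogene_idtF=True)
        assert predict_chemotype(p).idt_product == "TDI"
        assert predict_chemotype(p, "methods_text").idt_product == "PAS"

    def test_unknown_rule_set_rejected(self):
        with pytest.raises(ValueError):
            predict_chemotype(_profile(), "guesswork")

    def test_lolines_require_all_four_genes(self):
        p = _profile(present=("lolC", "lolA", "lolO", "lolP"))
        assert predict_chemotype(p).lol_product == "LOL"
        q = _profile(present=("lolC", "lolA", "lolO"))
        assert predict_chemotype(q).lol_product == "NONE"

    def test_class_exclusivity_over_random_profiles(self):
        rng = np.random.default_rng(83)
        states = [PRESENT, ABSENT]
        for _ in range(200):
            markers = {
                m: states[rng.integers(2)] for m in DEFAULT_PANEL.alkaloid_markers
            }
            if rng.random() < 0.3:
                markers["idtF"] = PSEUDOGENE
            pred = predict_chemotype(make_profile(**markers))
            label_parts = pred.label.split("/") if pred.label else []
            assert len(label_parts) == len(set(label_parts))
            assert not {"ERV", "CC"} <= set(label_parts)
            assert not {"PER", "PPZA2"} <= set(label_parts)
            assert len({"PAS", "TDI", "TDC", "LTB"} & set(label_parts)) <= 1

    def test_pure_function(self):
        p = _profile(present=EAS_ALL)
        assert predict_chemotype(p) == predict_chemotype(p)

    def test_upgrade_monotonicity_along_idt_ladder(self):
        """Adding a PRESENT IDT marker only upgrades PAS -> TDI -> TDC -> LTB."""
        ladder = ["NONE", "PAS", "TDI", "TDC", "LTB"]
        rng = np.random.default_rng(89)
        idt_markers = ("idtG", "idtQ", "idtP", "idtF", "idtK", "idtJ")
        for _ in range(100):
            base_states = {
                m: (PRESENT if rng.random() < 0.5 else ABSENT) for m in idt_markers
            }
            prof = make_profile(**base_states)
            before = predict_chemotype(prof).idt_product
            absent = [m for m in idt_markers if base_states[m] is ABSENT]
            if not absent:
                continue
            flip = absent[rng.integers(len(absent))]
            upgraded = dict(base_states)
            upgraded[flip] = PRESENT
            after = predict_chemotype(make_profile(**upgraded)).idt_product
            assert ladder.index(after) >= ladder.index(before)


class TestAssignAmlg:
    def test_identical_profiles_one_group(self):
        profiles = [_profile(present=EAS_ALL, isolate_id=f"i{k}") for k in range(4)]
        assert assign_amlg(profiles).n_mlg == 1

    def test_pseudogene_and_untested_are_distinct_states(self):
        a = _profile(present=("idtG",), isolate_id="a")
        b = _profile(present=("idtG",), pseudogene_idtF=True, isolate_id="b")
        c = _profile(present=("idtG",), untested=("idtF",), isolate_id="c")
        assert assign_amlg([a, b, c]).n_mlg == 3

    def test_matches_bruteforce_dedupe(self):
        rng = np.random.default_rng(97)
        profiles = []
        for k in range(25):
            markers = {
                m: (PRESENT if rng.random() < 0.5 else ABSENT)
                for m in DEFAULT_PANEL.alkaloid_markers[:6]
            }
            profiles.append(make_profile(isolate_id=f"i{k}", **markers))
        got = assign_amlg(profiles).n_mlg
        expected = len({p.state_tuple() for p in profiles})
        assert got == expected


class TestMatingSummary:
    def test_region_counts_and_ratio(self):
        profiles = [
            make_profile(isolate_id=f"a{k}", region="Faroe", mating_type=MatingType.A)
            for k in range(55)
        ] + [
            make_profile(isolate_id=f"b{k}", region="Faroe", mating_type=MatingType.B)
            for k in range(5)
        ]
        (summary,) = mating_summary(profiles, "region")
        assert (summary.n_a, summary.n_b) == (55, 5)
        assert summary.ratio_ab == pytest.approx(11.0)

    def test_equal_types_ratio_one(self):
        profiles = [
            make_profile(isolate_id="a", mating_type=MatingType.A),
            make_profile(isolate_id="b", mating_type=MatingType.B),
        ]
        (s,) = mating_summary(profiles, "region")
        assert s.ratio_ab == pytest.approx(1.0)

    def test_all_A_ratio_not_computable_and_nd_counted(self):
        profiles = [
            make_profile(isolate_id="a", mating_type=MatingType.A),
            make_profile(isolate_id="b", mating_type=MatingType.ND),
        ]
        (s,) = mating_summary(profiles, "region")
        assert s.ratio_ab is None
        assert s.n_nd == 1
        assert s.n == 2


class TestChemotypeReport:
    def test_percentages_normalised_within_group(self):
        profiles = [
            _profile(present=EAS_ALL, isolate_id=f"n{k}", region="north")
            for k in range(3)
        ] + [
            _profile(present=("dmaW", "easC"), isolate_id="s0", region="south")
        ]
        report = chemotype_report(profiles, group_by="region")
        eas = report.product_counts
        erv_north = eas[(eas["group"] == "north") & (eas["product"] == "ERV")]
        assert erv_north["percent"].iloc[0] == pytest.approx(100.0)
        cc_south = eas[(eas["group"] == "south") & (eas["product"] == "CC")]
        assert cc_south["percent"].iloc[0] == pytest.approx(100.0)
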