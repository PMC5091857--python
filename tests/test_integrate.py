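"""Reconciliation, candidate-species classification, richness arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from delimkit.abgd import Partition
from delimkit.errors import ClassificationError, InputError
from delimkit.integrate import (
    EvidenceTable,
    LineageInfo,
    PairEvidence,
    acoustic_differentiable,
    classify_units,
    reconcile_partitions,
    richness_stats,
)


def ev_table(labels, pairs=None, named=(), has_data=True):
    info = {
        lab: LineageInfo(
            nominal_name=f"Genus {lab}" if lab in named else None,
            has_morph_data=has_data,
            has_acoustic_data=has_data,
        )
        for lab in labels
    }
    ev = EvidenceTable(lineage_info=info)
    for (a, b), flags in (pairs or {}).items():
        ev.set_pair(a, b, PairEvidence(*flags))
    return ev


class TestAcousticDifferentiable:
    def test_disjoint_ranges_yes(self):
        a = {"note_duration": (0.10, 0.15)}
        b = {"note_duration": (0.20, 0.30)}
        assert acoustic_differentiable(a, b) == "yes"

    def test_identical_parameters_no(self):
        a = {"note_duration": (0.1, 0.2), "pulse_rate": (50, 80)}
        assert acoustic_differentiable(a, dict(a)) == "no"

    def test_no_shared_parameter_unknown(self):
        assert acoustic_differentiable({"note_duration": (0.1, 0.2)}, {}) == "unknown"
        assert acoustic_differentiable(
            {"note_duration": (0.1, 0.2)}, {"pulse_rate": (40, 60)}
        ) == "unknown"

    def test_negative_parameter_rejected(self):
        with pytest.raises(InputError, match="negative"):
            acoustic_differentiable({"pulse_rate": (-1, 5)}, {"pulse_rate": (1, 2)})

    def test_relative_rule(self):
        a = {"fundamental_frequency": (1000, 1100)}
        b = {"fundamental_frequency": (1050, 1600)}
        # ranges overlap -> "no" under the default rule
        assert acoustic_differentiable(a, b) == "no"
        assert acoustic_differentiable(a, b, rule="relative", rel_threshold=0.15) == "yes"


class TestReconcile:
    def test_identical_partitions_pass_through(self):
        p = Partition.from_groups([["a", "b"], ["c"]])
        ev = ev_table("abc")
        cons, log = reconcile_partitions(p, p, ev)
        assert cons.as_frozensets() == p.as_frozensets()
        assert all(entry["rule"] == "concordant" for entry in log)

    def test_split_without_evidence_goes_coarse(self):
        fine = Partition.from_groups([["a"], ["b"], ["c"]])
        coarse = Partition.from_groups([["a", "b"], ["c"]])
        ev = ev_table("abc", {("a", "b"): ("no", "unknown", "unknown")})
        cons, log = reconcile_partitions(fine, coarse, ev)
        assert cons.as_frozensets() == coarse.as_frozensets()
        assert any(e["rule"] == "conservative" for e in log)

    @pytest.mark.parametrize("channel", range(3))
    def test_split_with_positive_evidence_goes_fine(self, channel):
        fine = Partition.from_groups([["a"], ["b"], ["c"]])
        coarse = Partition.from_groups([["a", "b"], ["c"]])
        flags = ["unknown"] * 3
        flags[channel] = "yes"
        ev = ev_table("abc", {("a", "b"): tuple(flags)})
        cons, log = reconcile_partitions(fine, coarse, ev)
        assert cons.as_frozensets() == fine.as_frozensets()
        assert any(e["rule"] == "evidence_override" for e in log)

    def test_mixture_across_independent_components(self):
        fine = Partition.from_groups([["a"], ["b"], ["c"], ["d"]])
        coarse = Partition.from_groups([["a", "b"], ["c", "d"]])
        ev = ev_table("abcd", {("a", "b"): ("yes", "unknown", "unknown")})
        cons, _ = reconcile_partitions(fine, coarse, ev)
        assert cons.as_frozensets() == frozenset(
            [frozenset(["a"]), frozenset(["b"]), frozenset(["c", "d"])]
        )

    def test_non_nested_conflict_falls_back_to_component(self):
        pa = Partition.from_groups([["a", "b"], ["c", "d"]])
        pb = Partition.from_groups([["a", "c"], ["b", "d"]])
        ev = ev_table("abcd")
        cons, log = reconcile_partitions(pa, pb, ev)
        assert cons.as_frozensets() == frozenset([frozenset("abcd")])
        assert any(e["rule"] == "non_nested_fallback" for e in log)

    def test_id_mismatch_lists_symmetric_difference(self):
        pa = Partition.from_groups([["a", "b"]])
        pb = Partition.from_groups([["a", "c"]])
        with pytest.raises(InputError, match="\\['b', 'c'\\]"):
            reconcile_partitions(pa, pb, ev_table("abc"))

    def test_output_units_present_in_an_input(self):
        pa = Partition.from_groups([["a"], ["b"], ["c", "d"], ["e"]])
        pb = Partition.from_groups([["a", "b"], ["c", "d", "e"]])
        ev = ev_table("abcde", {("c", "e"): ("yes", "unknown", "unknown")})
        cons, _ = reconcile_partitions(pa, pb, ev)
        allowed = pa.as_frozensets() | pb.as_frozensets()
        assert cons.as_frozensets() <= allowed


class TestClassify:
    def test_named_unit_is_ns(self):
        units = Partition.from_groups([["chi"], ["x"]])
        ev = ev_table(["chi", "x"], {("chi", "x"): ("yes", "unknown", "unknown")},
                      named=["chi"])
        cls = classify_units(units, ev)
        assert cls.category["chi"] == "NS" and cls.category["x"] == "CCS"

    def test_acoustic_yes_sets_ccs(self):
        units = Partition.from_groups([["n"], ["u"]])
        ev = ev_table(["n", "u"], {("n", "u"): ("unknown", "yes", "unknown")},
                      named=["n"])
        cls = classify_units(units, ev)
        assert cls.category["u"] == "CCS"

    def test_dcl_attaches_to_nominal_species(self):
        units = Partition.from_groups([["n"], ["d"]])
        ev = ev_table(["n", "d"], {("n", "d"): ("no", "no", "unknown")}, named=["n"])
        cls = classify_units(units, ev)
        assert cls.category["d"] == "DCL"
        assert cls.dcl_attachment["d"] == "n"

    def test_no_data_unit_is_ucs(self):
        units = Partition.from_groups([["n"], ["u"]])
        ev = ev_table(["n", "u"], named=["n"])  # no pair rows at all
        cls = classify_units(units, ev)
        assert cls.category["u"] == "UCS"

    def test_unmatched_unit_raises_with_snapshot(self):
        # morphology fails but acoustics untested: neither DCL nor UCS
        units = Partition.from_groups([["n"], ["w"]])
        ev = ev_table(["n", "w"], {("n", "w"): ("no", "unknown", "unknown")},
                      named=["n"])
        with pytest.raises(ClassificationError, match="morph_diff"):
            classify_units(units, ev)

    def test_missing_lineage_info_rejected(self):
        units = Partition.from_groups([["a"], ["zzz"]])
        ev = ev_table(["a"])
        with pytest.raises(InputError, match="zzz"):
            classify_units(units, ev)

    def test_deterministic(self):
        units = Partition.from_groups([["n"], ["d"], ["c"]])
        ev = ev_table(
            ["n", "d", "c"],
            {("n", "d"): ("no", "no", "unknown"), ("n", "c"): ("yes", "unknown", "unknown")},
            named=["n"],
        )
        c1, c2 = classify_units(units, ev), classify_units(units, ev)
        assert c1.category == c2.category and c1.decision_log == c2.decision_log


@pytest.fixture(scope="module")
def outcome(case_study):
    cons, log = reconcile_partitions(
        case_study.abgd, case_study.gmyc, case_study.evidence
    )
    cls = classify_units(cons, case_study.evidence)
    return cons, log, cls


class TestCaseStudy:
    """The bundled Amazonian treefrog worked example."""

    def test_focal_counts(self, case_study, outcome):
        _, _, cls = outcome
        counts = cls.counts(restrict_ids=case_study.focal_ids)
        assert counts == {"NS": 2, "CCS": 7, "UCS": 2, "DCL": 1, "n_units": 12}

    def test_counting_identity(self, case_study, outcome):
        _, _, cls = outcome
        counts = cls.counts(restrict_ids=case_study.focal_ids)
        assert counts["NS"] + counts["CCS"] + counts["UCS"] + counts["DCL"] == 12
        # species-level taxa exclude the deep conspecific lineage
        assert counts["n_units"] - counts["DCL"] == 11

    def test_discordance_resolutions(self, outcome):
        cons, log, _ = outcome
        units = cons.as_frozensets()
        # lumped: the two chiquitanus lineages (similar calls and morphology)
        assert frozenset(
            ["Scinax_chiquitanus_BRA", "Scinax_chiquitanus_BOL"]
        ) in units
        # lumped: the two data-free ruber_F lineages (conservatism)
        assert frozenset(["Scinax_ruber_F1", "Scinax_ruber_F2"]) in units
        # split: ruber_PM separated on reference evidence
        assert frozenset(["Scinax_ruber_PM"]) in units
        assert any(e["rule"] == "evidence_override" for e in log)
        assert any(e["rule"] == "conservative" for e in log)

    def test_dcl_attached_to_cruentommus(self, outcome):
        _, _, cls = outcome
        dcl_units = [u for u, c in cls.category.items() if c == "DCL"]
        assert len(dcl_units) == 1
        anchor = cls.dcl_attachment[dcl_units[0]]
        assert "cruentommus" in anchor

    def test_encoded_method_unit_counts(self, case_study):
        # the two molecular delimitations restricted to the focal region
        assert case_study.abgd.restrict(case_study.focal_ids).n_units == 13
        assert case_study.gmyc.restrict(case_study.focal_ids).n_units == 12


class TestRichness:
    @pytest.mark.parametrize(
        "u,d,undesc,incr",
        [(9, 2, 82, 450), (9, 21, 30, 43)],
    )
    def test_worked_examples(self, u, d, undesc, incr):
        rs = richness_stats({"CCS": u, "UCS": 0}, d)
        assert rs.percent_undescribed == undesc
        assert rs.percent_increase == incr

    def test_zero_undescribed(self):
        rs = richness_stats({"CCS": 0, "UCS": 0}, 5)
        assert rs.percent_undescribed == 0 and rs.percent_increase == 0

    def test_baseline_zero_rejected(self):
        with pytest.raises(InputError):
            richness_stats({"CCS": 1, "UCS": 0}, 0)

    def test_rounding_half_up(self):
        # 100*1/8 = 12.5 rounds up to 13; 100*1/3 = 33.33 stays 33
        assert richness_stats({"CCS": 1, "UCS": 0}, 7).percent_undescribed == 13
        assert richness_stats({"CCS": 1, "UCS": 0}, 3).percent_increase == 33

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_undescribed_below_increase(self, u, d):
        rs = richness_stats({"CCS": u, "UCS": 0}, d)
        # 100 U/(U+D) < 100 U/D before rounding; rounded values never invert
        assert rs.percent_undescribed <= rs.percent_increase
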