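import math

import pytest

from lncnet.data import (
    LNCRNA,
    DiffRecord,
    GeneModule,
    LncPriorityRecord,
    RegulatoryAnnotation,
)
from lncnet.datasets import PUBLISHED_ROWS, published_lnc_case_study
from lncnet.errors import AnalysisError
from lncnet.prioritize import (
    exclude_no_deg_targets,
    filter_by_fc,
    module_coverage,
    prioritize_full_coverage,
    render_priority_table,
    require_validated_mirnas,
    resolve_targets,
    run_cascade,
)


def _lnc_record(lnc_id, fc):
    log2fc = math.copysign(math.log2(abs(fc)), fc)
    return DiffRecord(lnc_id, LNCRNA, log2fc, 1e-6, 1e-4, selected=True)


def _module(label, members):
    return GeneModule(label=label, members=frozenset(members),
                      seed_gene=sorted(members)[0], density=1.0,
                      score=float(len(members)))


class TestFcFilter:
    @pytest.mark.parametrize("fc, kept", [
        (-9.0, True), (3.9, False), (4.0, True), (5.23, True), (-4.52, True),
    ])
    def test_inclusive_magnitude_threshold(self, fc, kept):
        record = _lnc_record("L", fc)
        assert (filter_by_fc([record], 4.0) == {"L"}) is kept


class TestMirnaRequirement:
    def test_requires_at_least_one_pair(self):
        annotation = RegulatoryAnnotation(
            lnc_to_mirna=frozenset({("L1", "miR-a")}),
            lnc_to_gene=frozenset(), mirna_to_gene=frozenset())
        assert require_validated_mirnas({"L1", "L2"}, annotation) == {"L1"}


class TestResolveTargets:
    def test_hand_worked_set_algebra(self):
        annotation = RegulatoryAnnotation(
            lnc_to_mirna=frozenset({("L1", "a"), ("L1", "b")}),
            lnc_to_gene=frozenset({("L1", "g9")}),
            mirna_to_gene=frozenset({("a", "g1"), ("a", "g2"),
                                     ("b", "g2"), ("b", "g3")}))
        mirnas, targets = resolve_targets("L1", annotation, {"g1", "g2"})
        assert mirnas == {"a", "b"}
        assert targets == {"g1", "g2"}  # g9, g3 are not coding DEGs

    def test_no_annotation_edges(self):
        annotation = RegulatoryAnnotation(frozenset(), frozenset(),
                                          frozenset())
        assert resolve_targets("L1", annotation, {"g1"}) == (set(), set())

    def test_direct_targets_count_without_mirna_route(self):
        annotation = RegulatoryAnnotation(
            lnc_to_mirna=frozenset(),
            lnc_to_gene=frozenset({("L1", "g1")}),
            mirna_to_gene=frozenset())
        _, targets = resolve_targets("L1", annotation, {"g1"})
        assert targets == {"g1"}


class TestCoverage:
    def test_exclude_records_without_deg_targets(self):
        keep = LncPriorityRecord("L1", 5.0, targeted_degs={"g1"})
        drop = LncPriorityRecord("L2", 5.0)
        assert exclude_no_deg_targets([keep, drop]) == [keep]
        assert exclude_no_deg_targets([]) == []

    def test_covered_modules_by_intersection(self):
        modules = [_module("M3", {"x", "y"}), _module("M5", {"z", "w"}),
                   _module("M6", {"q", "r"})]
        record = LncPriorityRecord("L", 5.0, targeted_degs={"x", "z", "k"})
        module_coverage(record, modules)
        assert record.covered_modules == {"M3", "M5"}
        assert record.module_associated_degs == {"x", "z"}

    def test_disjoint_targets_cover_nothing(self):
        record = LncPriorityRecord("L", 5.0, targeted_degs={"k"})
        module_coverage(record, [_module("M1", {"x", "y"})])
        assert record.covered_modules == set()

    def test_empty_module_list_rejected(self):
        with pytest.raises(AnalysisError, match="module"):
            module_coverage(LncPriorityRecord("L", 5.0), [])

    def test_partial_coverage_not_prioritized(self):
        modules = [_module(f"M{i}", {f"g{i}"}) for i in range(1, 7)]
        record = LncPriorityRecord(
            "L", 5.0, targeted_mirnas={"m"},
            targeted_degs={f"g{i}" for i in range(1, 6)},
            passed_fc=True, passed_mirna=True, passed_deg=True)
        module_coverage(record, modules)
        assert prioritize_full_coverage([record], modules) == []
        assert not record.prioritized


class TestPublishedCaseStudy:
    def test_reproduces_published_counts_and_priorities(self):
        study = published_lnc_case_study()
        records = run_cascade(study.lnc_records, study.annotation,
                              set(study.coding_degs), study.modules)
        by_id = {r.lnc_id: r for r in records}
        for lnc, fc, n_mirna, n_deg, n_mod_deg, covered in PUBLISHED_ROWS:
            rec = by_id[lnc]
            assert rec.fc == pytest.approx(fc)
            assert len(rec.targeted_mirnas) == n_mirna
            assert len(rec.targeted_degs) == n_deg
            assert len(rec.module_associated_degs) == n_mod_deg
            assert rec.covered_modules == set(covered)
        prioritized = sorted(r.lnc_id for r in records if r.prioritized)
        assert prioritized == ["AC009299.3", "RP11-747H7.3"]

    def test_cascade_composition_equals_intersection(self):
        study = published_lnc_case_study()
        records = run_cascade(study.lnc_records, study.annotation,
                              set(study.coding_degs), study.modules)
        fc_set = filter_by_fc(study.lnc_records, 4.0)
        mirna_set = require_validated_mirnas(
            {r.feature_id for r in study.lnc_records}, study.annotation)
        for rec in records:
            assert rec.passed_fc == (rec.lnc_id in fc_set)
            assert rec.passed_mirna == (rec.lnc_id in mirna_set)
            survivors = rec.passed_fc and rec.passed_mirna and rec.passed_deg
            assert rec.lnc_id in (fc_set & mirna_set
                                  & {x.lnc_id for x in
                                     exclude_no_deg_targets(records)}
                                  ) or not survivors


class TestRenderTable:
    def test_empty_sets_render_none(self):
        record = LncPriorityRecord("L", -5.05, targeted_mirnas={"m"})
        table = render_priority_table([record])
        row = table.iloc[0]
        assert row["targeted_degs"] == "none"
        assert row["module_associated_degs"] == "none"
        assert row["targeted_modules"] == "none"

    def test_empty_record_list_gives_header_only(self):
        table = render_priority_table([])
        assert len(table) == 0
        assert "lncRNA" in table.columns

    def test_row_permutation_invariance(self):
        study = published_lnc_case_study()
        records = run_cascade(study.lnc_records, study.annotation,
                              set(study.coding_degs), study.modules)
        forward = render_priority_table(records)
        backward = render_priority_table(list(reversed(records)))
        assert forward.equals(backward)
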