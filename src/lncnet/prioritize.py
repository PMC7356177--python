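"""lncRNA prioritization cascade.

Starting from the lncRNAs that passed the differential-expression filter,
the cascade applies, in order:

1. strong modulation: ``|FC| >= 4`` (inclusive);
2. at least one experimentally validated lncRNA->miRNA interaction;
3. at least one targeted DEG — a coding DEG reached either directly
   (lncRNA->gene) or through a targeted miRNA (lncRNA->miRNA->gene);
4. module coverage: the set of detected modules whose members intersect
   the lncRNA's targeted DEGs.

A lncRNA is *prioritized* when it passes 1-3 and its covered modules
equal the full label set of ALL detected modules — the full-coverage
rule that singles out regulators reaching every dense region of the
disease network.
"""

from __future__ import annotations

from .data import DiffRecord, GeneModule, LncPriorityRecord, RegulatoryAnnotation
from .errors import AnalysisError

import pandas as pd


def _module_key(label: str):
    # natural order for M1...M10 style labels
    return (len(label), label)


def filter_by_fc(lnc_degs: list[DiffRecord], fc_min: float = 4.0) -> set[str]:
    """Retain lncRNAs with ``|fc| >= fc_min`` (inclusive boundary)."""
    return {r.feature_id for r in lnc_degs if abs(r.fc) >= fc_min}


def require_validated_mirnas(lncs: set[str],
                             annotation: RegulatoryAnnotation) -> set[str]:
    """Retain lncRNAs with at least one annotated miRNA interaction."""
    with_mirna = {l for l, _ in annotation.lnc_to_mirna}
    return lncs & with_mirna


def resolve_targets(lnc: str, annotation: RegulatoryAnnotation,
                    coding_degs: set[str]) -> tuple[set[str], set[str]]:
    """Targeted miRNAs and targeted DEGs of one lncRNA.

    Targeted DEGs are the union of direct lncRNA->gene targets and the
    gene targets of every targeted miRNA, intersected with the coding DEG
    set (set union, so a gene reached both ways counts once).
    """
    mirnas = annotation.mirnas_of(lnc)
    genes = set(annotation.direct_targets_of(lnc))
    for m in mirnas:
        genes |= annotation.targets_of_mirna(m)
    return mirnas, genes & coding_degs


def exclude_no_deg_targets(records: list[LncPriorityRecord]
                           ) -> list[LncPriorityRecord]:
    """Drop records whose resolved targeted-DEG set is empty."""
    return [r for r in records if r.targeted_degs]


def module_coverage(record: LncPriorityRecord,
                    modules: list[GeneModule]) -> LncPriorityRecord:
    """Fill ``module_associated_degs`` and ``covered_modules`` in place."""
    if not modules:
        raise AnalysisError("module coverage undefined with no modules")
    module_genes: set[str] = set()
    covered: set[str] = set()
    for mod in modules:
        hit = record.targeted_degs & mod.members
        if hit:
            covered.add(mod.label)
            module_genes |= hit
    record.module_associated_degs = module_genes
    record.covered_modules = covered
    return record


def prioritize_full_coverage(records: list[LncPriorityRecord],
                             modules: list[GeneModule]
                             ) -> list[LncPriorityRecord]:
    """Flag records covering every detected module; return them by |fc|.

    ``prioritized`` requires all upstream pass flags plus full coverage,
    so the flag set of a returned record is internally consistent.
    """
    all_labels = {m.label for m in modules}
    hits = []
    for rec in records:
        rec.prioritized = (rec.passed_fc and rec.passed_mirna
                           and rec.passed_deg
                           and bool(all_labels)
                           and rec.covered_modules == all_labels)
        if rec.prioritized:
            hits.append(rec)
    hits.sort(key=lambda r: (-abs(r.fc), r.lnc_id))
    return hits


def run_cascade(lnc_degs: list[DiffRecord], annotation: RegulatoryAnnotation,
                coding_degs: set[str], modules: list[GeneModule],
                fc_min: float = 4.0) -> list[LncPriorityRecord]:
    """Run the full cascade, returning one record per input lncRNA.

    Every record carries its pass flags and resolved sets regardless of
    where it falls out of the cascade, so the reporting table can show
    why each lncRNA was excluded. Each flag reflects its own filter
    alone, so composing the filters in cascade order equals intersecting
    the individual pass sets.
    """
    passed_fc = filter_by_fc(lnc_degs, fc_min=fc_min)
    records = []
    for deg in sorted(lnc_degs, key=lambda r: (-abs(r.fc), r.feature_id)):
        mirnas, targets = resolve_targets(deg.feature_id, annotation,
                                          coding_degs)
        rec = LncPriorityRecord(
            lnc_id=deg.feature_id, fc=deg.fc,
            targeted_mirnas=mirnas, targeted_degs=targets,
            passed_fc=deg.feature_id in passed_fc,
            passed_mirna=bool(mirnas),
            passed_deg=bool(targets))
        if modules:
            module_coverage(rec, modules)
        records.append(rec)
    prioritize_full_coverage(records, modules)
    return records


def render_priority_table(records: list[LncPriorityRecord]) -> pd.DataFrame:
    """Summary table: one row per lncRNA, counts plus covered-module list.

    Empty sets render as the string ``"none"``. Rows are ordered by
    descending signed fold change.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (-r.fc, r.lnc_id)):
        covered = " ".join(sorted(rec.covered_modules, key=_module_key))
        rows.append({
            "lncRNA": rec.lnc_id,
            "fc": rec.fc,
            "targeted_mirnas": len(rec.targeted_mirnas) or "none",
            "targeted_degs": len(rec.targeted_degs) or "none",
            "module_associated_degs": len(rec.module_associated_degs) or "none",
            "targeted_modules": covered or "none",
            "passed_fc": rec.passed_fc,
            "passed_mirna": rec.passed_mirna,
            "passed_deg": rec.passed_deg,
            "prioritized": rec.prioritized,
        })
    columns = ["lncRNA", "fc", "targeted_mirnas", "targeted_degs",
               "module_associated_degs", "targeted_modules", "passed_fc",
               "passed_mirna", "passed_deg", "prioritized"]
    return pd.DataFrame(rows, columns=columns)
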