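"""Core in-memory containers shared by all pipeline stages.

The pipeline moves a small number of objects between stages: a log2
expression matrix with sample groups and feature classes, a regulatory
annotation (lncRNA->miRNA, lncRNA->gene, miRNA->gene pair sets), gene-set
collections for enrichment, per-feature differential-expression records,
detected network modules and per-lncRNA prioritization records.

Identifiers (genes, lncRNAs, miRNAs, samples) are opaque case-sensitive
strings throughout; no aliasing or ID mapping is attempted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

CASE = "case"
CONTROL = "control"
CODING = "coding"
LNCRNA = "lncRNA"

GROUPS = (CASE, CONTROL)
FEATURE_CLASSES = (CODING, LNCRNA)


@dataclass
class ExpressionMatrix:
    """A normalized log2 expression matrix with sample and feature metadata.

    Parameters
    ----------
    values
        ``features x samples`` DataFrame of log2-scale intensities.
    group_of
        Map ``sample_id -> {"case", "control"}`` covering every column.
    class_of
        Map ``feature_id -> {"coding", "lncRNA"}`` covering every row.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        for name, labels in (("feature", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise FormatError(f"duplicate {name} identifier {dup[0]!r}")
        for s in cols:
            if s not in self.group_of:
                raise FormatError(f"sample {s!r} has no group label")
            if self.group_of[s] not in GROUPS:
                raise FormatError(
                    f"sample {s!r} has unknown group {self.group_of[s]!r}"
                )
        for f in idx:
            if f not in self.class_of:
                raise FormatError(f"feature {f!r} has no class label")
            if self.class_of[f] not in FEATURE_CLASSES:
                raise FormatError(
                    f"feature {f!r} has unknown class {self.class_of[f]!r}"
                )
        if not self.samples_in_group(CASE) or not self.samples_in_group(CONTROL):
            raise FormatError("both case and control groups must be non-empty")
        bad = self.values.columns[
            [not pd.api.types.is_numeric_dtype(self.values[c]) for c in cols]
        ]
        if len(bad):
            raise FormatError(f"non-numeric values in sample column {bad[0]!r}")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def features_of_class(self, cls: str) -> list[str]:
        return [f for f in self.values.index if self.class_of[f] == cls]


@dataclass(frozen=True)
class RegulatoryAnnotation:
    """Validated regulatory pair sets linking lncRNAs, miRNAs and genes."""

    lnc_to_mirna: frozenset[tuple[str, str]]
    lnc_to_gene: frozenset[tuple[str, str]]
    mirna_to_gene: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for name in ("lnc_to_mirna", "lnc_to_gene", "mirna_to_gene"):
            pairs = getattr(self, name)
            object.__setattr__(self, name, frozenset(pairs))
            for a, b in getattr(self, name):
                if not a or not b:
                    raise FormatError(f"empty identifier in {name} pair ({a!r}, {b!r})")

    def mirnas_of(self, lnc: str) -> set[str]:
        return {m for l, m in self.lnc_to_mirna if l == lnc}

    def direct_targets_of(self, lnc: str) -> set[str]:
        return {g for l, g in self.lnc_to_gene if l == lnc}

    def targets_of_mirna(self, mirna: str) -> set[str]:
        return {g for m, g in self.mirna_to_gene if m == mirna}


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the gene universe used for enrichment testing.

    Set members need not all lie in the universe; membership is intersected
    with the universe at test time.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in self.sets.items()}
        )
        object.__setattr__(self, "universe", frozenset(self.universe))
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")


def signed_fold_change(log2fc: float) -> float:
    """Signed linear fold change from a log2 fold change.

    Down-regulation is reported as a negative reciprocal (log2fc = -2 maps
    to -4.0); a log2fc of exactly 0 maps to +1.0.
    """
    if log2fc == 0:
        return 1.0
    magnitude = 2.0 ** abs(log2fc)
    return math.copysign(magnitude, log2fc)


@dataclass
class DiffRecord:
    """Per-feature differential-expression result."""

    feature_id: str
    feature_class: str
    log2fc: float
    p_raw: float
    q_fdr: float = float("nan")
    selected: bool = False

    @property
    def fc(self) -> float:
        """Signed linear fold change (magnitude >= 1, sign = direction)."""
        return signed_fold_change(self.log2fc)


@dataclass(frozen=True)
class GeneModule:
    """A dense region of the DEG interaction network.

    ``score = density * size`` ranks modules; labels M1, M2, ... follow
    descending score.
    """

    label: str
    members: frozenset[str]
    seed_gene: str
    density: float
    score: float


@dataclass
class LncPriorityRecord:
    """One row of the lncRNA prioritization table (cascade bookkeeping)."""

    lnc_id: str
    fc: float
    targeted_mirnas: set[str] = field(default_factory=set)
    targeted_degs: set[str] = field(default_factory=set)
    module_associated_degs: set[str] = field(default_factory=set)
    covered_modules: set[str] = field(default_factory=set)
    passed_fc: bool = False
    passed_mirna: bool = False
    passed_deg: bool = False
    prioritized: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("targeted_mirnas", "targeted_degs", "module_associated_degs",
                  "covered_modules"):
            d[k] = sorted(d[k])
        return d
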