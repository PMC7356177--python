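"""Differential-expression calling on a log2 expression matrix.

Per feature, a Welch two-sample t-test compares case versus control log2
intensities; the log2 fold change is the difference of group means, and
the signed linear fold change follows the negative-reciprocal convention
(down-regulation of 4x reported as -4.0). Multiplicity is controlled by
Benjamini-Hochberg across ALL features jointly — coding genes and lncRNAs
form one family, the conservative reading when a single filtering rule is
applied to both classes.

The test statistic is isolated behind :func:`welch_tests` so a different
two-group test can be swapped in without touching the selection logic.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CASE, CONTROL, CODING, LNCRNA, DiffRecord, ExpressionMatrix
from .errors import AnalysisError, ParameterError

log = logging.getLogger(__name__)


def welch_tests(case: np.ndarray, control: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-tests; returns (log2fc, p_raw).

    Rows that are constant in both groups get p = 1 when the group means
    agree (no evidence either way) and p = 0 when they differ exactly
    (the zero-noise limit); these degenerate rows are counted in the log.
    """
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    var0 = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    if var0.any():
        log.info("%d features constant within both groups", int(var0.sum()))
        p[var0 & (log2fc == 0)] = 1.0
        p[var0 & (log2fc != 0)] = 0.0
    return log2fc, p


def adjust_fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    if len(p_values) == 0:
        return np.asarray([], dtype=float)
    return multipletests(p_values, method="fdr_bh")[1]


def compute_differential(matrix: ExpressionMatrix) -> list[DiffRecord]:
    """Per-feature differential expression for case versus control.

    Requires at least two samples per group. Returns one
    :class:`~lncnet.data.DiffRecord` per feature, in matrix row order,
    with BH q-values computed across all features jointly and the
    ``selected`` flag left False (see :func:`select_degs`).
    """
    case_ids = matrix.samples_in_group(CASE)
    control_ids = matrix.samples_in_group(CONTROL)
    for name, ids in ((CASE, case_ids), (CONTROL, control_ids)):
        if len(ids) < 2:
            raise AnalysisError(
                f"group {name!r} has {len(ids)} samples; need >= 2")
    case = matrix.values[case_ids].to_numpy(dtype=float)
    control = matrix.values[control_ids].to_numpy(dtype=float)
    log2fc, p_raw = welch_tests(case, control)
    q_fdr = adjust_fdr_bh(p_raw)
    return [
        DiffRecord(feature_id=f, feature_class=matrix.class_of[f],
                   log2fc=float(lfc), p_raw=float(p), q_fdr=float(q))
        for f, lfc, p, q in zip(matrix.feature_ids, log2fc, p_raw, q_fdr)
    ]


def select_degs(records: list[DiffRecord], fc_min: float = 1.5,
                q_max: float = 0.01) -> set[str]:
    """Apply the fold-change / FDR selection rule, both boundaries inclusive.

    A feature is selected iff ``|fc| >= fc_min`` and ``q_fdr <= q_max``.
    The ``selected`` flag is written back onto each record and the set of
    selected feature ids is returned.
    """
    if fc_min < 1:
        raise ParameterError(f"fc_min must be >= 1, got {fc_min}")
    if not 0 < q_max <= 1:
        raise ParameterError(f"q_max must be in (0, 1], got {q_max}")
    selected = set()
    for rec in records:
        rec.selected = abs(rec.fc) >= fc_min and rec.q_fdr <= q_max
        if rec.selected:
            selected.add(rec.feature_id)
    return selected


def split_by_class(records: list[DiffRecord]) -> tuple[set[str], set[str]]:
    """Partition the selected features into (coding, lncRNA) id sets."""
    coding = {r.feature_id for r in records
              if r.selected and r.feature_class == CODING}
    lnc = {r.feature_id for r in records
           if r.selected and r.feature_class == LNCRNA}
    return coding, lnc
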