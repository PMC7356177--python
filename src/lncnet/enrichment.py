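"""Over-representation analysis of gene lists against gene-set collections.

The test is one-sided (over-representation only): for a query of ``n``
genes drawn from a universe of ``N`` genes of which ``K`` belong to the
set, the raw p-value is the hypergeometric upper tail ``P[X >= k]`` at the
observed overlap ``k``. Two correction regimes are exposed, matching the
two conventions commonly used for GO biological processes (uncorrected,
strict ``p < alpha``) and for pathway collections (Bonferroni,
``p_adj <= alpha``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .data import GeneSetCollection
from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation test result."""

    set_name: str
    n_universe: int
    n_set: int
    n_query: int
    n_overlap: int
    p_raw: float
    p_adj: float
    significant: bool


def hypergeometric_enrichment(query: set[str], collection: GeneSetCollection,
                              correction: str = "bonferroni",
                              alpha: float = 0.05,
                              strict: bool = False) -> list[EnrichmentResult]:
    """Test every set in ``collection`` for over-representation in ``query``.

    Parameters
    ----------
    query
        Gene list of interest; members outside the universe are dropped
        (count logged).
    correction
        ``"none"`` or ``"bonferroni"`` (``p_adj = min(1, m * p_raw)`` over
        the ``m`` sets tested).
    alpha
        Significance level applied to ``p_adj`` (which equals ``p_raw``
        when correction is ``"none"``).
    strict
        Use ``p < alpha`` instead of ``p <= alpha``.

    Results are sorted by (p_adj, p_raw, set_name).
    """
    if correction not in ("none", "bonferroni"):
        raise ParameterError(f"unknown correction {correction!r}")
    universe = collection.universe
    if not universe:
        raise ParameterError("gene universe is empty")
    dropped = len(query - universe)
    if dropped:
        log.info("dropped %d query genes outside the universe", dropped)
    query_in = query & universe
    n_universe, n_query = len(universe), len(query_in)
    m = len(collection.sets)
    results = []
    for name, members in collection.sets.items():
        set_in = members & universe
        overlap = len(set_in & query_in)
        # P[X >= overlap]; sf(k-1) is the upper tail including k
        p_raw = float(hypergeom.sf(overlap - 1, n_universe, len(set_in),
                                   n_query))
        p_raw = min(1.0, max(0.0, p_raw))
        p_adj = min(1.0, m * p_raw) if correction == "bonferroni" else p_raw
        significant = (p_adj < alpha) if strict else (p_adj <= alpha)
        results.append(EnrichmentResult(
            set_name=name, n_universe=n_universe, n_set=len(set_in),
            n_query=n_query, n_overlap=overlap, p_raw=p_raw, p_adj=p_adj,
            significant=significant))
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.set_name))
    return results


def enrich_go_bp(query: set[str], collection: GeneSetCollection,
                 alpha: float = 0.05) -> list[EnrichmentResult]:
    """GO-biological-process regime: uncorrected p, strict ``p < alpha``."""
    return hypergeometric_enrichment(query, collection, correction="none",
                                     alpha=alpha, strict=True)


def enrich_pathways(query: set[str], collection: GeneSetCollection,
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """Pathway regime: Bonferroni-corrected, inclusive ``p_adj <= alpha``."""
    return hypergeometric_enrichment(query, collection,
                                     correction="bonferroni", alpha=alpha,
                                     strict=False)
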