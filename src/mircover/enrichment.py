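"""Over-representation analysis with exact hypergeometric tails and BH FDR.

For a query gene set of size *n* drawn from a universe of size *N*, and an
annotation term covering *K* universe genes, the over-representation
p-value of observing *k* or more query genes in the term is the
hypergeometric upper tail

    P[X >= k],   X ~ Hypergeometric(N, K, n),

computed in log space for numerical stability.  P-values across terms are
adjusted by the Benjamini–Hochberg step-up procedure and a term is called
significant when its FDR falls below the threshold (default 0.05).

The test is one-sided (over-representation only) and the p-values are
exact hypergeometric — deliberately not the modified Fisher/EASE score
some enrichment servers report, so numbers from those servers will differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation statistics for one annotation term."""

    term_id: str
    term_name: str
    count: int
    term_size: int
    universe_size: int
    query_size: int
    p_value: float
    fdr: float
    significant: bool


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(count: int, query_size: int, term_size: int, universe_size: int) -> float:
    """P[X >= count] for X ~ Hypergeometric(universe_size, term_size, query_size).

    Computed by log-space summation of the exact point masses.
    """
    if not (0 <= count <= query_size <= universe_size):
        raise ValueError(
            f"need 0 <= count <= query_size <= universe_size, "
            f"got ({count}, {query_size}, {universe_size})"
        )
    if not (count <= term_size <= universe_size):
        raise ValueError(
            f"need count <= term_size <= universe_size, "
            f"got ({count}, {term_size}, {universe_size})"
        )
    if count <= max(0, query_size + term_size - universe_size):
        return 1.0
    ks = np.arange(count, min(term_size, query_size) + 1)
    log_pmf = (
        _log_comb(term_size, ks)
        + _log_comb(universe_size - term_size, query_size - ks)
        - _log_comb(universe_size, query_size)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    Each p(i) (ascending) becomes min over j >= i of p(j)·m/j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def enrich(
    query: GeneSet,
    annotation: Dict[str, Set[str]],
    universe: Optional[GeneSet] = None,
    threshold: float = 0.05,
    term_names: Optional[Dict[str, str]] = None,
) -> List[EnrichmentResult]:
    """Test every annotation term for over-representation of the query.

    ``annotation`` maps term ids to gene sets (symbols are upper-cased on
    read).  When ``universe`` is omitted it defaults to the union of all
    annotated genes.  Terms are intersected with the universe before
    counting; only terms overlapping the query are returned, sorted by FDR
    then term id.
    """
    term_names = term_names or {}
    universe_genes: Set[str] = (
        set(universe.genes) if universe is not None else set().union(*annotation.values())
    )
    query_genes = set(query.genes)
    outside = sorted(query_genes - universe_genes)
    if outside:
        raise ValueError(f"query genes outside the universe: {outside}")

    rows = []
    for term_id in sorted(annotation):
        term_genes = annotation[term_id] & universe_genes
        count = len(term_genes & query_genes)
        if count == 0 or not term_genes:
            continue
        p = hypergeom_upper_tail(count, len(query_genes), len(term_genes), len(universe_genes))
        rows.append((term_id, count, len(term_genes), p))

    fdrs = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=term_names.get(term_id, term_id),
            count=count,
            term_size=term_size,
            universe_size=len(universe_genes),
            query_size=len(query_genes),
            p_value=p,
            fdr=fdr,
            significant=fdr < threshold,
        )
        for (term_id, count, term_size, p), fdr in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.term_id))
    return results
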