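"""Offline gene-set over-representation analysis.

A hypergeometric (one-sided, upper tail) test of the overlap between a
query list (e.g. the up-regulated proteins of one contrast) and each gene
set, against a stated background universe, with Benjamini-Hochberg control
of the false discovery rate across sets.  Identifiers are matched as
upper-cased gene symbols.  This is the standard offline replacement for
web-service pathway enrichment; it makes no use of interaction networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant_io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int          # overlap count
    K: int          # set size within universe
    N: int          # universe size
    n: int          # query size
    p_value: float
    q_value: float
    overlap_ids: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    @property
    def significant(self) -> bool:
        return self.q_value <= 0.05


def hypergeom_tail(k: int, K: int, N: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Survival-function evaluation is delegated to scipy, which computes the
    underlying pmf in log space, so small tails are accurate.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0  # P(X >= 0); also covers the degenerate N = 0 population
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    sets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every gene set for over-representation in the query.

    The query must be a subset of the universe (an id outside it is an
    error naming the offender).  Each set is intersected with the universe
    before testing; sets with empty intersection are not tested.  Records
    are sorted by (q, p).  Matching is case-insensitive on gene symbols.
    """
    universe_u = {str(u).upper() for u in universe}
    query_u = {str(q).upper() for q in query}
    if not query_u:
        raise ValueError("empty query: nothing to test")
    stray = query_u - universe_u
    if stray:
        raise ValueError(f"query ids outside the universe: {sorted(stray)[:10]}")

    N, n = len(universe_u), len(query_u)
    tested: list[EnrichmentRecord] = []
    in_no_set = set(query_u)
    for name, members in sets:
        members_u = {m.upper() for m in members} & universe_u
        if not members_u:
            continue
        overlap = members_u & query_u
        in_no_set -= overlap
        p = hypergeom_tail(len(overlap), len(members_u), N, n)
        tested.append(EnrichmentRecord(
            set_name=name, k=len(overlap), K=len(members_u), N=N, n=n,
            p_value=p, q_value=np.nan, overlap_ids=frozenset(overlap),
            description=sets.descriptions.get(name, ""),
        ))
    if in_no_set:
        logger.warning("%d query ids matched no tested gene set: %s",
                       len(in_no_set), sorted(in_no_set)[:10])
    if tested:
        qvals = bh_adjust([r.p_value for r in tested])
        for r, qv in zip(tested, qvals):
            r.q_value = float(qv)
    tested.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    n_sig = sum(r.q_value <= alpha for r in tested)
    logger.info("enrichment: %d/%d sets significant at q <= %g", n_sig, len(tested), alpha)
    return tested
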