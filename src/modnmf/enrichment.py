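"""Over-representation analysis: upper-tail hypergeometric test per gene set
with Benjamini-Hochberg adjustment across the tested sets of one call.

The universe is the pipeline's common mRNA axis, not the whole annotation:
module genes are drawn from the pipeline's gene space, and the test must
condition on that. Sets are intersected with the universe first; sets whose
intersection falls outside [min_set_size, max_set_size] are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_enrich"]


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    raw_p: float
    adjusted_p: float

    @property
    def fold_enrichment(self) -> float:
        expected = self.set_size * self.query_size / self.universe_size
        return self.overlap / expected if expected > 0 else float("nan")


def hypergeom_enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_set_size: int = 3,
    max_set_size: int = 2000,
) -> list[EnrichmentResult]:
    """Test every annotation set for over-representation in ``query``.

    raw_p is the upper tail P(X >= overlap) of the hypergeometric
    distribution with population ``|universe|``, ``|set|`` successes and
    ``|query|`` draws; adjusted_p is Benjamini-Hochberg across all sets
    tested in this call. One-sided over-representation only.
    """
    if not query:
        raise ValueError("empty query set")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query IDs outside the universe: {', '.join(sorted(stray)[:10])}")
    n_universe = len(universe)
    n_query = len(query)

    results: list[EnrichmentResult] = []
    raw_ps: list[float] = []
    for term_id in sorted(collection.sets):
        members = collection.sets[term_id] & universe
        if not (min_set_size <= len(members) <= max_set_size):
            continue
        overlap = len(members & query)
        # P(X >= overlap) == sf(overlap - 1)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        results.append(EnrichmentResult(
            term_id=term_id,
            overlap=overlap,
            set_size=len(members),
            query_size=n_query,
            universe_size=n_universe,
            raw_p=p,
            adjusted_p=p,
        ))
        raw_ps.append(p)

    if results:
        _, adj, _, _ = multipletests(raw_ps, method="fdr_bh")
        for res, a in zip(results, adj):
            res.adjusted_p = float(max(a, res.raw_p))
    return results
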