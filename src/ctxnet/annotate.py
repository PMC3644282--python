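"""Gene-set overlap and over-representation against annotation collections.

Annotation sources are user-supplied GMT collections (e.g. GO or MSigDB
exports); enrichment of a query gene set in a term is the upper-tail
hypergeometric probability of the observed overlap given the universe, with
optional Benjamini–Hochberg correction across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "jaccard_matrix", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One query-set × annotation-term over-representation test."""

    query: str
    term: str
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p: float
    fdr_p: float | None = None


def jaccard_matrix(sets: GeneSetCollection) -> np.ndarray:
    """Pairwise Jaccard similarity |A ∩ B| / |A ∪ B|, in collection order.

    Symmetric with unit diagonal (sets are non-empty by construction).
    """
    names = sets.names
    if not names:
        raise ValueError("collection is empty")
    n = len(names)
    out = np.ones((n, n))
    members = [sets[name] for name in names]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(members[i] & members[j])
            union = len(members[i] | members[j])
            out[i, j] = out[j, i] = inter / union
    return out


def enrich(
    query: Sequence[str],
    annotations: GeneSetCollection,
    universe: Sequence[str],
    p_theta: float = 0.01,
    fdr: bool = True,
    query_name: str = "query",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query set in each term.

    The query must lie within the universe; each term is intersected with
    the universe before testing. P is the upper tail P(X >= overlap) for
    drawing |query| genes from the universe with the term's genes as
    successes. With ``fdr`` set, P values are Benjamini–Hochberg corrected
    across all terms of the collection and results are filtered on the
    corrected value, otherwise on the raw one. Results below ``p_theta``
    are returned sorted by (corrected) p then term name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query)
    outside = q - uni
    if outside:
        raise ValueError(
            f"query contains genes outside the universe: {sorted(outside)[:5]}"
        )
    N = len(uni)
    n_draw = len(q)
    records: list[EnrichmentResult] = []
    for term in annotations.names:
        members = annotations[term] & uni
        if not members:
            continue
        K = len(members)
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, N, K, n_draw))
        records.append(
            EnrichmentResult(
                query=query_name,
                term=term,
                overlap=k,
                query_size=n_draw,
                term_size=K,
                universe_size=N,
                p=min(p, 1.0),
            )
        )
    if not records:
        return []
    if fdr:
        corrected = multipletests([r.p for r in records], method="fdr_bh")[1]
        records = [
            EnrichmentResult(
                query=r.query,
                term=r.term,
                overlap=r.overlap,
                query_size=r.query_size,
                term_size=r.term_size,
                universe_size=r.universe_size,
                p=r.p,
                fdr_p=float(c),
            )
            for r, c in zip(records, corrected)
        ]
        records = [r for r in records if r.fdr_p < p_theta]
        records.sort(key=lambda r: (r.fdr_p, r.term))
    else:
        records = [r for r in records if r.p < p_theta]
        records.sort(key=lambda r: (r.p, r.term))
    return records
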