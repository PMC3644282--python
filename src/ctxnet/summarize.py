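"""Collapse each gene set's member states to one UP/DOWN/NOCHANGE per sample.

A gene set is called UP in a sample when (a) strictly more than a fraction
``r`` of its members are UP there, and (b) that many UP members out of a set
of that size is hypergeometrically surprising given how many genes are UP in
the whole background matrix for that sample (upper-tail P < ``p_threshold``).
The rule for DOWN is symmetric; if neither direction satisfies both clauses
the summary is NOCHANGE. Defaults r = 0.5 and P < 0.05.

The background universe of the hypergeometric test is all genes of the input
matrix. For r >= 0.5 the two directional majorities are mutually exclusive,
so the result is unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import DOWN, NOCHANGE, UP, GeneSetCollection, TrinaryMatrix

__all__ = ["SummaryParams", "summarize_gene_set", "summarize_all"]


@dataclass(frozen=True)
class SummaryParams:
    """Majority fraction ``r`` in (0, 1] and hypergeometric significance level."""

    r: float = 0.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")


def _direction_call(
    k: int, set_size: int, K: int, N: int, params: SummaryParams
) -> bool:
    """Strict majority plus upper-tail hypergeometric significance.

    k observed members in the direction, from a set of ``set_size`` drawn
    out of ``N`` background genes of which ``K`` are in that direction.
    Tail probability is P(X >= k).
    """
    if k <= params.r * set_size:
        return False
    p_tail = float(hypergeom.sf(k - 1, N, K, set_size))
    return p_tail < params.p_threshold


def summarize_gene_set(
    genes_trinary: TrinaryMatrix,
    background: TrinaryMatrix,
    sample: str,
    params: SummaryParams = SummaryParams(),
) -> int:
    """Summary state of one gene set (rows of ``genes_trinary``) in one sample.

    ``genes_trinary`` holds the member genes only; ``background`` is the full
    quantized matrix from which the per-sample UP/DOWN background counts are
    taken. Every member must be present in the background.
    """
    if len(genes_trinary.row_ids) == 0:
        raise ValueError("gene set is empty")
    for g in genes_trinary.row_ids:
        if g not in background._row_index:
            raise ValueError(f"gene {g!r} of the set is absent from the background matrix")
    s_member = genes_trinary.sample_index(sample)
    s_bg = background.sample_index(sample)
    member_states = genes_trinary.values[:, s_member]
    bg_states = background.values[:, s_bg]
    N = len(background.row_ids)
    m = len(genes_trinary.row_ids)
    k_up = int(np.sum(member_states == UP))
    k_down = int(np.sum(member_states == DOWN))
    K_up = int(np.sum(bg_states == UP))
    K_down = int(np.sum(bg_states == DOWN))
    if _direction_call(k_up, m, K_up, N, params):
        return UP
    if _direction_call(k_down, m, K_down, N, params):
        return DOWN
    return NOCHANGE


def summarize_all(
    genes_trinary: TrinaryMatrix,
    sets: GeneSetCollection,
    params: SummaryParams = SummaryParams(),
    drop_flat: bool = False,
) -> TrinaryMatrix:
    """Gene-set × sample summary matrix, rows in collection order.

    With ``drop_flat`` set, gene sets summarized to NOCHANGE in every sample
    are removed from the output (they carry no signal for network learning).
    """
    n_samples = len(genes_trinary.sample_ids)
    names = sets.names
    values = np.zeros((len(names), n_samples), dtype=np.int8)
    bg = genes_trinary.values
    N = len(genes_trinary.row_ids)
    K_up = (bg == UP).sum(axis=0)
    K_down = (bg == DOWN).sum(axis=0)
    for i, name in enumerate(names):
        members = sorted(sets[name])
        rows = []
        for g in members:
            if g not in genes_trinary._row_index:
                raise ValueError(
                    f"gene {g!r} of set {name!r} is absent from the expression matrix"
                )
            rows.append(genes_trinary.row_index(g))
        sub = bg[rows, :]
        m = len(rows)
        k_up = (sub == UP).sum(axis=0)
        k_down = (sub == DOWN).sum(axis=0)
        for j in range(n_samples):
            if _direction_call(int(k_up[j]), m, int(K_up[j]), N, params):
                values[i, j] = UP
            elif _direction_call(int(k_down[j]), m, int(K_down[j]), N, params):
                values[i, j] = DOWN
    out = TrinaryMatrix(values, names, genes_trinary.sample_ids)
    if drop_flat:
        keep = [n for i, n in enumerate(names) if np.any(values[i, :] != NOCHANGE)]
        out = out.select_rows(keep)
    return out
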