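"""Condition-specific edges via a leave-condition-out ratio and permutations.

For a called edge i—j and a condition T_k with samples S_Tk out of the
universe S_U, the condition-effect ratio is::

    gamma = d_ij(S_U) / d_ij(S_U - S_Tk)

A gamma well above 1 means the condition's samples drive the dependency.
Its significance comes from a permutation test: M random subsets of size
|S_Tk| are removed instead of S_Tk, gamma is recomputed each time, and
P = H/M where H counts permutations with gamma at least as large as the
observed one (ties count toward H). The edge is declared specific to T_k
when gamma > gamma_theta and P < p_theta (defaults 2 and 0.05).

A zero leave-out likelihood is floored at 1/(R+1) — one pseudo-count at the
frequency resolution of the consensus — so gamma stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .io import ConditionTable, TrinaryMatrix
from .network import ConsensusNetwork, SearchConfig, consensus

__all__ = [
    "SpecificityParams",
    "SpecificityResult",
    "gamma",
    "specificity_test",
    "test_all",
    "classify_centricity",
]


@dataclass(frozen=True)
class SpecificityParams:
    """Thresholds and permutation budget of the specificity test.

    ``R_perm`` is the number of consensus runs used for each leave-out and
    permutation estimate; ``None`` means the same R as the observed network.
    It is exposed separately because the M × R_perm re-learning cost
    dominates the runtime of the whole pipeline.
    """

    gamma_theta: float = 2.0
    p_theta: float = 0.05
    M: int = 100
    R_perm: int | None = None

    def __post_init__(self) -> None:
        if self.gamma_theta <= 0:
            raise ValueError("gamma_theta must be positive")
        if not 0 < self.p_theta < 1:
            raise ValueError("p_theta must lie in (0, 1)")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.R_perm is not None and self.R_perm < 1:
            raise ValueError("R_perm must be >= 1")


@dataclass(frozen=True)
class SpecificityResult:
    """Outcome of one (edge, condition) specificity test."""

    edge: tuple[str, str]
    condition: str
    d_all: float
    d_without: float
    gamma: float
    H: int
    M: int
    p: float
    specific: bool


def gamma(d_all: float, d_without: float, R: int) -> float:
    """Condition-effect ratio with the zero-denominator floor 1/(R+1)."""
    if not 0 <= d_all <= 1 or not 0 <= d_without <= 1:
        raise ValueError("dependency likelihoods must lie in [0, 1]")
    return d_all / max(d_without, 1.0 / (R + 1))


def _validate_condition(data: TrinaryMatrix, samples: Sequence[str]) -> None:
    for s in samples:
        data.sample_index(s)
    n_out = len(data.sample_ids) - len(set(samples))
    if len(samples) < 1:
        raise ValueError("condition has no samples")
    if n_out == 0:
        raise ValueError("condition covers every sample; leave-out set empty")
    if n_out < 3:
        raise ValueError(
            f"only {n_out} samples would remain after leaving the condition "
            "out; need at least 3"
        )


def test_all(
    data: TrinaryMatrix,
    net: ConsensusNetwork,
    conditions: ConditionTable,
    params: SpecificityParams = SpecificityParams(),
    config: SearchConfig = SearchConfig(),
    seed: int = 0,
    edges: Sequence[tuple[str, str]] | None = None,
) -> list[SpecificityResult]:
    """Specificity of every (called edge, condition) pair.

    ``edges`` overrides the tested edge list (defaults to the called edges
    of ``net``); pairs are normalised to lexicographic order. One leave-out
    consensus is learned per condition and one per permutation subset, and
    its d matrix serves every tested edge at once; permutation subsets of
    equal size are likewise shared across conditions, since the null draw
    depends only on |S_Tk|. All draws derive from ``seed``, so results are
    deterministic and independent of condition or edge order.
    """
    if edges is None:
        edges = net.called_edges()
    edges = [tuple(sorted(e)) for e in edges]
    for a, b in edges:
        net.d_of(a, b)  # raises on unknown node
    R_perm = params.R_perm if params.R_perm is not None else config.R
    n_samples = len(data.sample_ids)

    for label in conditions.labels:
        _validate_condition(data, conditions.samples_of(label))

    # Leave-out consensus per condition.
    without_d: dict[str, np.ndarray] = {}
    for label in conditions.labels:
        sub = data.drop_samples(conditions.samples_of(label))
        cfg = replace(config, R=R_perm, base_seed=derive_seed(seed, "without", label))
        without_d[label] = consensus(sub, cfg, net.d_theta).d

    # Permutation consensus per (subset size, permutation index).
    sizes = sorted({len(conditions.samples_of(label)) for label in conditions.labels})
    perm_d: dict[tuple[int, int], np.ndarray] = {}
    for size in sizes:
        for m in range(params.M):
            rng = np.random.default_rng(derive_seed(seed, "permsubset", size, m))
            drop_ix = rng.choice(n_samples, size=size, replace=False)
            drop = [data.sample_ids[i] for i in drop_ix]
            cfg = replace(
                config, R=R_perm, base_seed=derive_seed(seed, "permrun", size, m)
            )
            perm_d[(size, m)] = consensus(data.drop_samples(drop), cfg, net.d_theta).d

    index = {v: i for i, v in enumerate(net.node_ids)}
    results: list[SpecificityResult] = []
    for label in conditions.labels:
        size = len(conditions.samples_of(label))
        for a, b in edges:
            ia, ib = index[a], index[b]
            d_all = net.d_of(a, b)
            d_wo = float(without_d[label][ia, ib])
            g_obs = gamma(d_all, d_wo, R_perm)
            H = 0
            for m in range(params.M):
                g_m = gamma(d_all, float(perm_d[(size, m)][ia, ib]), R_perm)
                if g_m >= g_obs:
                    H += 1
            p = H / params.M
            results.append(
                SpecificityResult(
                    edge=(a, b),
                    condition=label,
                    d_all=d_all,
                    d_without=d_wo,
                    gamma=g_obs,
                    H=H,
                    M=params.M,
                    p=p,
                    specific=bool(g_obs > params.gamma_theta and p < params.p_theta),
                )
            )
    return results


def specificity_test(
    data: TrinaryMatrix,
    edge: tuple[str, str],
    condition: str,
    samples: Sequence[str],
    net: ConsensusNetwork,
    params: SpecificityParams = SpecificityParams(),
    config: SearchConfig = SearchConfig(),
    seed: int = 0,
) -> SpecificityResult:
    """Specificity of one called edge to one condition.

    ``samples`` is the condition's sample subset S_Tk. The edge must be
    called in ``net`` (d above the threshold).
    """
    a, b = sorted(edge)
    if net.d_of(a, b) <= net.d_theta:
        raise ValueError(
            f"edge ({a}, {b}) is not called in the network "
            f"(d = {net.d_of(a, b)} <= d_theta = {net.d_theta})"
        )
    _validate_condition(data, samples)
    table = ConditionTable({condition: list(samples)}, list(data.sample_ids))
    (result,) = test_all(
        data, net, table, params, config, seed, edges=[(a, b)]
    )
    return result


def classify_centricity(
    net: ConsensusNetwork,
    spec_results: Sequence[SpecificityResult],
) -> dict[str, str]:
    """Label each gene set with at least one called edge.

    ``generic`` — none of its edges is specific to any condition;
    ``<T_k>-centric`` — every edge is specific, and only to the single
    condition T_k; ``mixed`` — anything else.
    """
    called = set(net.called_edges())
    for res in spec_results:
        if tuple(sorted(res.edge)) not in called:
            raise ValueError(f"result references uncalled edge {res.edge!r}")
    spec_conditions: dict[tuple[str, str], set[str]] = {e: set() for e in called}
    for res in spec_results:
        if res.specific:
            spec_conditions[tuple(sorted(res.edge))].add(res.condition)
    labels: dict[str, str] = {}
    for node in net.node_ids:
        incident = [e for e in called if node in e]
        if not incident:
            continue
        cond_sets = [spec_conditions[e] for e in incident]
        if all(len(c) == 0 for c in cond_sets):
            labels[node] = "generic"
            continue
        union = set().union(*cond_sets)
        if len(union) == 1 and all(len(c) == 1 for c in cond_sets):
            labels[node] = f"{next(iter(union))}-centric"
        else:
            labels[node] = "mixed"
    return labels
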