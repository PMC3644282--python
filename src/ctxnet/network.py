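"""Consensus dependency networks from repeated Bayesian-network searches.

The dependency likelihood between two gene sets i and j is estimated as the
fraction of R independent stochastic structure searches whose learned DAG
contains an edge between them in either direction::

    d_ij = (1/R) * sum_k F(BN_k, i <-> j)

Each search is a greedy hill climb (add / delete / reverse moves) over DAGs
scored with the BDeu marginal likelihood, started from a seeded random sparse
DAG; the run-to-run variability of the random start is the only stochastic
element, and is what makes the edge frequency informative. Edge direction is
ignored throughout. An edge is called when d_ij strictly exceeds the
threshold d_theta (default 0.5).

All variables are treated as three-state categorical (UP / DOWN / NOCHANGE),
whether or not all three states are observed. Variables constant across the
samples carry no dependency information and are excluded from the search;
they are reported with d = 0 to every partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from ._seeds import derive_seed
from .io import TrinaryMatrix

__all__ = [
    "SearchConfig",
    "DagStructure",
    "ConsensusNetwork",
    "family_score",
    "search_structure",
    "consensus",
    "call_edges",
    "write_network",
    "read_network",
]

N_STATES = 3  # UP / DOWN / NOCHANGE


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of one consensus estimate.

    Parameters
    ----------
    R
        Number of independent structure-search runs (default 1024).
    max_parents
        Parent limit per node during search.
    ess
        Equivalent sample size of the uniform Dirichlet prior in the BDeu
        score.
    restarts_per_run
        Random restarts within one run; the best-scoring local optimum wins.
    base_seed
        Seed from which all per-run seeds are derived.
    init_edge_prob
        Probability of including each forward edge of a random topological
        order in the initial DAG. ``None`` means ``min(2/(n-1), 0.5)``,
        which keeps random starts sparse for large node counts.
    """

    R: int = 1024
    max_parents: int = 5
    ess: float = 1.0
    restarts_per_run: int = 1
    base_seed: int = 0
    init_edge_prob: float | None = None

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.restarts_per_run < 1:
            raise ValueError("restarts_per_run must be >= 1")

    def edge_prob(self, n_nodes: int) -> float:
        if self.init_edge_prob is not None:
            return self.init_edge_prob
        if n_nodes < 2:
            return 0.0
        return min(2.0 / (n_nodes - 1), 0.5)


@dataclass
class DagStructure:
    """A directed acyclic structure: per-node parent sets."""

    node_ids: list[str]
    parents: dict[str, frozenset[str]]

    def edges(self) -> list[tuple[str, str]]:
        """Directed (parent, child) pairs, lexicographically sorted."""
        out = [(p, c) for c, ps in self.parents.items() for p in ps]
        return sorted(out)

    def undirected_edges(self) -> list[tuple[str, str]]:
        """Unordered pairs, each sorted lexicographically."""
        pairs = {tuple(sorted((p, c))) for p, c in self.edges()}
        return sorted(pairs)


class ConsensusNetwork:
    """Symmetric matrix of dependency likelihoods over gene-set nodes."""

    def __init__(
        self,
        node_ids: Sequence[str],
        d: np.ndarray,
        R: int,
        d_theta: float = 0.5,
    ) -> None:
        d = np.asarray(d, dtype=float)
        n = len(node_ids)
        if d.shape != (n, n):
            raise ValueError("d must be square over node_ids")
        if not np.allclose(d, d.T):
            raise ValueError("d must be symmetric")
        if (d < 0).any() or (d > 1).any():
            raise ValueError("dependency likelihoods must lie in [0, 1]")
        self.node_ids = list(node_ids)
        self.d = d
        np.fill_diagonal(self.d, 0.0)
        self.R = int(R)
        self.d_theta = float(d_theta)
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    def d_of(self, i: str, j: str) -> float:
        return float(self.d[self._index[i], self._index[j]])

    def called_edges(self) -> list[tuple[str, str]]:
        return call_edges(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ConsensusNetwork({len(self.node_ids)} nodes, R={self.R}, "
            f"d_theta={self.d_theta}, {len(self.called_edges())} called edges)"
        )


# ---------------------------------------------------------------------------
# BDeu scoring (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _family_score_nb(X, child, parents, ess):
    """BDeu log marginal likelihood of one child given its parent set.

    X is (n_samples, n_nodes) with entries in {0, 1, 2}; parents is an int64
    array of column indices. Dirichlet prior of total mass ``ess`` spread
    uniformly over the 3 * 3^|parents| cells.
    """
    n_samples = X.shape[0]
    p = parents.shape[0]
    q = 1
    for _ in range(p):
        q *= N_STATES
    counts = np.zeros(q * N_STATES, np.int64)
    for s in range(n_samples):
        code = 0
        for t in range(p):
            code = code * N_STATES + X[s, parents[t]]
        counts[code * N_STATES + X[s, child]] += 1
    a_j = ess / q
    a_jk = ess / (q * N_STATES)
    lg_a_j = math.lgamma(a_j)
    lg_a_jk = math.lgamma(a_jk)
    total = 0.0
    for j in range(q):
        n_j = 0
        for k in range(N_STATES):
            n_j += counts[j * N_STATES + k]
        if n_j > 0:
            total += lg_a_j - math.lgamma(a_j + n_j)
            for k in range(N_STATES):
                n_jk = counts[j * N_STATES + k]
                if n_jk > 0:
                    total += math.lgamma(a_jk + n_jk) - lg_a_jk
    return total


@njit(cache=True)
def _score_masked(X, child, pmask_row, ess):
    n_nodes = pmask_row.shape[0]
    p = 0
    for i in range(n_nodes):
        if pmask_row[i]:
            p += 1
    parents = np.empty(p, np.int64)
    t = 0
    for i in range(n_nodes):
        if pmask_row[i]:
            parents[t] = i
            t += 1
    return _family_score_nb(X, child, parents, ess)


@njit(cache=True)
def _path_exists(pmask, src, dst, excl_child, excl_parent):
    """Directed path src -> ... -> dst, optionally skipping one edge.

    pmask[child, parent] encodes parent -> child edges. The edge
    excl_parent -> excl_child is ignored (pass -1, -1 to disable).
    """
    n = pmask.shape[0]
    visited = np.zeros(n, np.bool_)
    stack = np.empty(n, np.int64)
    top = 0
    stack[top] = src
    top += 1
    visited[src] = True
    while top > 0:
        top -= 1
        x = stack[top]
        if x == dst:
            return True
        for y in range(n):
            if pmask[y, x] and not visited[y]:
                if x == excl_parent and y == excl_child:
                    continue
                visited[y] = True
                stack[top] = y
                top += 1
    return False


@njit(cache=True)
def _hill_climb(X, max_parents, ess, seed, p_edge):
    """One greedy hill climb from a seeded random sparse DAG.

    Moves: add, delete, reverse. Candidates are scanned in a fixed
    lexicographic order over (parent, child) with add before delete before
    reverse at each pair, and the first strictly-best move wins; a move is
    taken only if it strictly improves the score, so an exact tie between
    adding an edge and not adding it keeps the sparser structure.

    Returns (pmask, total_score) where pmask[child, parent] is the adjacency.
    """
    n_nodes = X.shape[1]
    np.random.seed(seed)
    order = np.random.permutation(n_nodes)
    pmask = np.zeros((n_nodes, n_nodes), np.bool_)
    npar = np.zeros(n_nodes, np.int64)
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            i = order[a]
            j = order[b]
            if npar[j] < max_parents and np.random.random() < p_edge:
                pmask[j, i] = True
                npar[j] += 1

    cur = np.empty(n_nodes)
    for j in range(n_nodes):
        cur[j] = _score_masked(X, j, pmask[j], ess)

    NEG = -np.inf
    add_delta = np.full((n_nodes, n_nodes), NEG)  # [child, parent]
    del_delta = np.full((n_nodes, n_nodes), NEG)
    stale = np.ones(n_nodes, np.bool_)

    while True:
        for j in range(n_nodes):
            if not stale[j]:
                continue
            for i in range(n_nodes):
                add_delta[j, i] = NEG
                del_delta[j, i] = NEG
                if i == j:
                    continue
                if pmask[j, i]:
                    pmask[j, i] = False
                    del_delta[j, i] = _score_masked(X, j, pmask[j], ess) - cur[j]
                    pmask[j, i] = True
                elif npar[j] < max_parents:
                    pmask[j, i] = True
                    add_delta[j, i] = _score_masked(X, j, pmask[j], ess) - cur[j]
                    pmask[j, i] = False
            stale[j] = False

        best = 0.0
        b_type = -1
        b_i = -1
        b_j = -1
        for i in range(n_nodes):
            for j in range(n_nodes):
                if i == j:
                    continue
                # add i -> j
                if not pmask[j, i]:
                    dlt = add_delta[j, i]
                    if dlt > best and not _path_exists(pmask, j, i, -1, -1):
                        best = dlt
                        b_type = 0
                        b_i = i
                        b_j = j
                else:
                    # delete i -> j
                    dlt = del_delta[j, i]
                    if dlt > best:
                        best = dlt
                        b_type = 1
                        b_i = i
                        b_j = j
                    # reverse i -> j into j -> i
                    if add_delta[i, j] > NEG:
                        dlt = del_delta[j, i] + add_delta[i, j]
                        if dlt > best and not _path_exists(pmask, i, j, j, i):
                            best = dlt
                            b_type = 2
                            b_i = i
                            b_j = j
        if b_type < 0:
            break
        if b_type == 0:
            pmask[b_j, b_i] = True
            npar[b_j] += 1
            cur[b_j] += add_delta[b_j, b_i]
            stale[b_j] = True
        elif b_type == 1:
            pmask[b_j, b_i] = False
            npar[b_j] -= 1
            cur[b_j] += del_delta[b_j, b_i]
            stale[b_j] = True
        else:
            cur[b_j] += del_delta[b_j, b_i]
            cur[b_i] += add_delta[b_i, b_j]
            pmask[b_j, b_i] = False
            npar[b_j] -= 1
            pmask[b_i, b_j] = True
            npar[b_i] += 1
            stale[b_i] = True
            stale[b_j] = True

    total = 0.0
    for j in range(n_nodes):
        total += cur[j]
    return pmask, total


@njit(cache=True)
def _consensus_counts(X, max_parents, ess, seeds, p_edge, restarts):
    """Undirected edge counts over one hill climb per seed row.

    seeds has shape (R, restarts); within a run the best-scoring restart's
    structure is counted.
    """
    n_nodes = X.shape[1]
    counts = np.zeros((n_nodes, n_nodes), np.int64)
    R = seeds.shape[0]
    for r in range(R):
        best_score = -np.inf
        best = np.zeros((n_nodes, n_nodes), np.bool_)
        for t in range(restarts):
            pmask, total = _hill_climb(X, max_parents, ess, seeds[r, t], p_edge)
            if total > best_score:
                best_score = total
                best = pmask
        for j in range(n_nodes):
            for i in range(n_nodes):
                if best[j, i]:
                    a, b = (i, j) if i < j else (j, i)
                    counts[a, b] += 1
    return counts


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _encode(data: TrinaryMatrix) -> np.ndarray:
    """Samples × nodes int64 matrix with states mapped {-1,0,1} -> {0,1,2}."""
    return (data.values.T.astype(np.int64) + 1).copy()


def family_score(
    data: TrinaryMatrix,
    child: str,
    parents: Iterable[str] = (),
    ess: float = 1.0,
) -> float:
    """BDeu log marginal-likelihood contribution of one node's family."""
    parents = list(parents)
    if child in parents:
        raise ValueError("child cannot be its own parent")
    X = _encode(data)
    child_ix = data.row_index(child)
    parent_ix = np.array([data.row_index(p) for p in parents], dtype=np.int64)
    return float(_family_score_nb(X, child_ix, parent_ix, float(ess)))


def search_structure(data: TrinaryMatrix, config: SearchConfig, seed: int) -> DagStructure:
    """One stochastic hill-climbing search; deterministic given (data, config, seed)."""
    if len(data.sample_ids) < 1:
        raise ValueError("need at least one sample")
    if len(data.row_ids) < 2:
        raise ValueError("need at least two nodes")
    X = _encode(data)
    p_edge = config.edge_prob(len(data.row_ids))
    best_score = -np.inf
    best = None
    for t in range(config.restarts_per_run):
        sub_seed = derive_seed(seed, "restart", t)
        pmask, total = _hill_climb(X, config.max_parents, config.ess, sub_seed, p_edge)
        if total > best_score:
            best_score = total
            best = pmask
    parents = {
        data.row_ids[j]: frozenset(
            data.row_ids[i] for i in np.flatnonzero(best[j])
        )
        for j in range(len(data.row_ids))
    }
    return DagStructure(list(data.row_ids), parents)


def consensus(
    data: TrinaryMatrix,
    config: SearchConfig,
    d_theta: float = 0.5,
) -> ConsensusNetwork:
    """Estimate all pairwise dependency likelihoods from R seeded runs.

    Per-run seeds derive from ``config.base_seed`` and the run index, so runs
    are independent and their order is immaterial. Constant variables are
    excluded from the search and get d = 0 to every partner.
    """
    node_ids = list(data.row_ids)
    n = len(node_ids)
    d = np.zeros((n, n), dtype=float)
    variable = [
        i for i in range(n)
        if np.unique(data.values[i, :]).size > 1
    ]
    if len(variable) >= 2 and len(data.sample_ids) >= 1:
        sub = data.select_rows([node_ids[i] for i in variable])
        X = _encode(sub)
        seeds = np.empty((config.R, config.restarts_per_run), dtype=np.int64)
        for r in range(config.R):
            for t in range(config.restarts_per_run):
                seeds[r, t] = derive_seed(config.base_seed, "run", r, "restart", t)
        counts = _consensus_counts(
            X,
            config.max_parents,
            config.ess,
            seeds,
            config.edge_prob(len(variable)),
            config.restarts_per_run,
        )
        for a in range(len(variable)):
            for b in range(a + 1, len(variable)):
                val = counts[a, b] / config.R
                d[variable[a], variable[b]] = val
                d[variable[b], variable[a]] = val
    return ConsensusNetwork(node_ids, d, config.R, d_theta)


def call_edges(net: ConsensusNetwork) -> list[tuple[str, str]]:
    """Pairs with d strictly above d_theta, lexicographically sorted."""
    edges = []
    n = len(net.node_ids)
    for a in range(n):
        for b in range(a + 1, n):
            if net.d[a, b] > net.d_theta:
                pair = tuple(sorted((net.node_ids[a], net.node_ids[b])))
                edges.append(pair)
    return sorted(edges)


# ---------------------------------------------------------------------------
# Network serialization (edge-list TSV and GraphML)
# ---------------------------------------------------------------------------

def write_network(
    net: ConsensusNetwork,
    spec_results: Sequence["SpecificityResult"] = (),  # noqa: F821
    path: str | Path = "network.tsv",
    fmt: str = "tsv",
    header_comment: str | None = None,
) -> None:
    """Write called edges with their d and any per-condition specificity.

    The TSV carries one row per called edge (set_i < set_j lexicographically,
    rows sorted), columns ``set_i``, ``set_j``, ``d`` and, for every tested
    condition, ``<cond>:gamma``, ``<cond>:p`` and ``<cond>:specific``.
    GraphML carries the same attributes on edges.
    """
    known = set(net.node_ids)
    by_edge: dict[tuple[str, str], dict[str, object]] = {}
    conditions: list[str] = []
    for res in spec_results:
        a, b = res.edge
        if a not in known or b not in known:
            raise ValueError(f"specificity record references unknown node in {res.edge!r}")
        pair = tuple(sorted((a, b)))
        if res.condition not in conditions:
            conditions.append(res.condition)
        rec = by_edge.setdefault(pair, {})
        rec[f"{res.condition}:gamma"] = res.gamma
        rec[f"{res.condition}:p"] = res.p
        rec[f"{res.condition}:specific"] = res.specific
    conditions.sort()

    edges = call_edges(net)
    columns = ["set_i", "set_j", "d"]
    for cond in conditions:
        columns += [f"{cond}:gamma", f"{cond}:p", f"{cond}:specific"]

    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# R={net.R}\td_theta={net.d_theta!r}\n")
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("\t".join(columns) + "\n")
            for a, b in edges:
                row = [a, b, repr(net.d_of(a, b))]
                rec = by_edge.get((a, b), {})
                for cond in conditions:
                    g = rec.get(f"{cond}:gamma")
                    p = rec.get(f"{cond}:p")
                    s = rec.get(f"{cond}:specific")
                    row.append("" if g is None else repr(float(g)))
                    row.append("" if p is None else repr(float(p)))
                    row.append("" if s is None else str(bool(s)))
                fh.write("\t".join(row) + "\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph(R=net.R, d_theta=net.d_theta)
        g.add_nodes_from(net.node_ids)
        for a, b in edges:
            attrs: dict[str, object] = {"d": net.d_of(a, b)}
            for key, val in by_edge.get((a, b), {}).items():
                attrs[key.replace(":", "_")] = val
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_network(path: str | Path) -> ConsensusNetwork:
    """Read an edge-list TSV written by :func:`write_network`.

    Only called edges are serialized, so the reconstructed matrix carries
    their d values exactly and zero elsewhere; R and d_theta come from the
    header comment.
    """
    R = None
    d_theta = 0.5
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tokens in line[1:].strip().split("\t"):
                    if tokens.startswith("R="):
                        R = int(tokens[2:])
                    elif tokens.startswith("d_theta="):
                        d_theta = float(tokens[8:])
                continue
            if not header_seen:
                header_seen = True
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            rows.append((fields[0], fields[1], float(fields[2])))
    if R is None:
        raise ValueError(f"{path}: missing '# R=...' header")
    node_ids: list[str] = []
    for a, b, _ in rows:
        for v in (a, b):
            if v not in node_ids:
                node_ids.append(v)
    n = len(node_ids)
    index = {v: i for i, v in enumerate(node_ids)}
    d = np.zeros((n, n))
    for a, b, val in rows:
        d[index[a], index[b]] = val
        d[index[b], index[a]] = val
    return ConsensusNetwork(node_ids, d, R, d_theta)
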