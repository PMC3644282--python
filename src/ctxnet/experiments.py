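"""Packaged validation experiments.

Each function here builds its own synthetic inputs, runs the pipeline and
measures a property of the method: recovery of the statins-perturbation
signature from the cholesterol boolean model, exact agreement of the
consensus with the score comparison on two variables, recovery of planted
condition-specific dependencies, the rank relation between the
condition-effect ratio and the within-condition edge frequency, and
agreement of the gene-set summarizer with a brute-force hypergeometric
oracle. They are deterministic given their seed and sized to run on one CPU
in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .boolsim import (
    SimulationDesign,
    cholesterol_fixture,
    generate_planted,
    sample_steady_states,
)
from .io import DOWN, NOCHANGE, UP, ConditionTable, TrinaryMatrix
from .network import SearchConfig, consensus, family_score
from .specificity import SpecificityParams, SpecificityResult, test_all
from .summarize import SummaryParams, summarize_gene_set

__all__ = [
    "statins_experiment",
    "two_node_oracle_check",
    "planted_recovery_experiment",
    "rank_monotonicity_experiment",
    "summarize_oracle_check",
]


# ---------------------------------------------------------------------------
# Statins perturbation on the cholesterol pathway
# ---------------------------------------------------------------------------

@dataclass
class StatinsOutcome:
    """Per-regulation specificity of the statins arm.

    ``flagged_pairs`` are regulations whose gamma and permutation P cross
    the thresholds; ``specific_pairs`` additionally requires the edge to be
    called in the learned network (d_all above d_theta), which is the
    declaration rule of the pipeline — specificity is a property of
    dependencies present in the network.
    """

    results: dict[tuple[str, str], SpecificityResult]
    flagged_pairs: list[tuple[str, str]]
    specific_pairs: list[tuple[str, str]]
    expected_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_samples: int = 0
    d_theta: float = 0.5


STATINS_PATH_PAIRS = [
    ("HMG_CoA_reductase", "Statins"),
    ("HMG_CoA_reductase", "Mevalonic_acid"),
]


def statins_experiment(
    seed: int,
    n_per_arm: int = 100,
    R: int = 1024,
    R_perm: int = 128,
    M: int = 100,
    ess: float | None = None,
) -> StatinsOutcome:
    """Reproduce the statins simulation: which pathway regulations are
    specific to the statins-perturbed condition?

    Generates ``n_per_arm`` attractor samples with statins clamped to 0 and
    to 1, learns the consensus network from the pooled samples, and tests
    every regulation of the pathway model for specificity to the statins
    arm (gamma with permutation P). The mechanistically expected outcome is
    that exactly the two regulations on the statins path — statins ⊣
    HMG-CoA reductase and HMG-CoA reductase → mevalonic acid — are
    statins-specific.
    """
    bool_net = cholesterol_fixture()
    design = SimulationDesign(
        arms={"statins_off": {"Statins": 0}, "statins_on": {"Statins": 1}},
        n_samples=n_per_arm,
        seed=derive_seed(seed, "statins-sim"),
    )
    data, arms = sample_steady_states(bool_net, design)
    ess_kw = {} if ess is None else {"ess": ess}
    config = SearchConfig(R=R, base_seed=derive_seed(seed, "statins-net"), **ess_kw)
    net = consensus(data, config)

    pairs = sorted({tuple(sorted(p)) for p in bool_net.regulations()})
    conditions = ConditionTable(
        {"statins_on": arms.samples_of("statins_on")}, list(data.sample_ids)
    )
    params = SpecificityParams(M=M, R_perm=R_perm)
    results = test_all(
        data,
        net,
        conditions,
        params,
        config,
        seed=derive_seed(seed, "statins-spec"),
        edges=pairs,
    )
    by_pair = {r.edge: r for r in results}
    flagged = sorted(e for e, r in by_pair.items() if r.specific)
    called_specific = sorted(e for e in flagged if by_pair[e].d_all > net.d_theta)
    return StatinsOutcome(
        results=by_pair,
        flagged_pairs=flagged,
        specific_pairs=called_specific,
        expected_pairs=sorted(tuple(sorted(p)) for p in STATINS_PATH_PAIRS),
        n_samples=2 * n_per_arm,
        d_theta=net.d_theta,
    )


# ---------------------------------------------------------------------------
# Exact oracle on two variables
# ---------------------------------------------------------------------------

def two_node_oracle_check(seed: int, n_datasets: int = 50) -> dict:
    """Consensus d on two variables versus the direct score comparison.

    With two variables the only structures are the empty graph and the
    single edge (whose two orientations score identically under BDeu), so
    every hill climb must land on the better of the two and the consensus
    d must be exactly the 0/1 indicator of the score difference. Datasets
    alternate between dependent (one variable copies the other with
    probability rho) and independent regimes at random sizes.
    """
    agree = 0
    records = []
    for t in range(n_datasets):
        rng = np.random.default_rng(derive_seed(seed, "twonode", t))
        n = int(rng.integers(40, 500))
        x = rng.integers(-1, 2, size=n).astype(np.int8)
        if t % 2 == 0:
            rho = 0.5 + 0.5 * rng.random()
            y = np.where(rng.random(n) < rho, x, rng.integers(-1, 2, size=n)).astype(np.int8)
        else:
            y = rng.integers(-1, 2, size=n).astype(np.int8)
        data = TrinaryMatrix(
            np.vstack([x, y]), ["X", "Y"], [f"s{i}" for i in range(n)]
        )
        config = SearchConfig(R=32, base_seed=derive_seed(seed, "twonode-net", t))
        d = consensus(data, config).d_of("X", "Y")
        score_edge = family_score(data, "X") + family_score(data, "Y", ["X"])
        score_empty = family_score(data, "X") + family_score(data, "Y")
        oracle = 1.0 if score_edge > score_empty else 0.0
        ok = d == oracle
        agree += ok
        records.append({"n": n, "d": d, "oracle": oracle, "agree": bool(ok)})
    return {
        "n_datasets": n_datasets,
        "n_agree": agree,
        "agreement": agree / n_datasets,
        "records": records,
    }


# ---------------------------------------------------------------------------
# Planted-dependency recovery
# ---------------------------------------------------------------------------

def _default_plant():
    return [
        (("S01", "S02"), "C1", 0.9),
        (("S03", "S04"), "C2", 0.9),
        (("S05", "S06"), "C3", 0.9),
    ]


def planted_recovery_experiment(
    seed: int,
    n_replicates: int = 40,
    n_sets: int = 20,
    n_samples: int = 200,
    n_blocks: int = 4,
    strength: float = 0.9,
    noise: float = 0.05,
    R: int = 256,
    R_perm: int = 64,
    M: int = 100,
    ess: float | None = None,
) -> dict:
    """Recovery of three planted condition-specific dependencies.

    Each replicate generates a fresh matrix with three variable pairs made
    dependent (at the given strength) inside one of four equal condition
    blocks, learns the consensus network and runs the full specificity test
    over every (called edge, block) pair. A replicate is recovered when all
    three planted pairs are called and declared specific to their true
    block. The false-specific rate pools the specific calls among all
    tested (edge, condition) pairs that are not planted truths.
    """
    planted = _default_plant()[:3]
    ess_kw = {} if ess is None else {"ess": ess}
    truth = {(tuple(sorted(pair)), label) for pair, label, _ in planted}
    n_recovered = 0
    false_specific = 0
    n_null_pairs = 0
    per_replicate = []
    for t in range(n_replicates):
        rep_seed = derive_seed(seed, "recovery", t)
        data, conditions, _ = generate_planted(
            n_sets=n_sets,
            n_samples=n_samples,
            conditions=n_blocks,
            planted_edges=[(pair, label, strength) for pair, label, _ in planted],
            noise=noise,
            seed=rep_seed,
        )
        config = SearchConfig(R=R, base_seed=derive_seed(rep_seed, "net"), **ess_kw)
        net = consensus(data, config)
        params = SpecificityParams(M=M, R_perm=R_perm)
        results = test_all(
            data, net, conditions, params, config, seed=derive_seed(rep_seed, "spec")
        )
        called = set(net.called_edges())
        hits = {
            (pair, label)
            for pair, label, _ in ((tuple(sorted(p)), l, s) for p, l, s in planted)
            if pair in called
            and any(
                r.specific and r.edge == pair and r.condition == label
                for r in results
            )
        }
        recovered = len(hits) == len(planted)
        n_recovered += recovered
        for r in results:
            if (r.edge, r.condition) not in truth:
                n_null_pairs += 1
                false_specific += r.specific
        per_replicate.append(
            {"recovered": recovered, "n_called": len(called), "n_hits": len(hits)}
        )
    return {
        "n_replicates": n_replicates,
        "n_recovered": n_recovered,
        "false_specific": false_specific,
        "n_null_pairs": n_null_pairs,
        "false_specific_rate": false_specific / n_null_pairs if n_null_pairs else 0.0,
        "per_replicate": per_replicate,
    }


# ---------------------------------------------------------------------------
# Rank relation between gamma and the within-condition edge frequency
# ---------------------------------------------------------------------------

def rank_monotonicity_experiment(
    seed: int,
    strengths: tuple[float, ...] = (0.28, 0.32, 0.36, 0.40, 0.44, 0.48, 0.52, 0.58),
    n_sets: int = 10,
    n_samples: int = 200,
    n_blocks: int = 2,
    n_replicates: int = 40,
    R: int = 128,
    R_perm: int = 128,
    ess: float | None = None,
) -> dict:
    """gamma versus the edge frequency estimated from the condition alone.

    The condition-effect ratio is, up to a constant, the dependency
    likelihood given only the condition's samples; across planted designs
    that vary the within-condition dependency strength the two quantities
    must therefore agree in rank. Each design point is the mean over
    ``n_replicates`` independently generated datasets (edge frequencies of
    borderline dependencies are the noisiest consensus estimates, so single
    datasets would compare ranks of noise); the strength grid concentrates
    where the score's detection transition lies. Returns both series and
    their Spearman correlation.
    """
    from scipy.stats import spearmanr

    from .specificity import gamma as gamma_fn

    ess_kw = {} if ess is None else {"ess": ess}
    pair = ("S01", "S02")
    gammas = []
    d_within = []
    for s_ix, strength in enumerate(strengths):
        g_rep = []
        w_rep = []
        for rep in range(n_replicates):
            design_seed = derive_seed(seed, "rank", s_ix, rep)
            data, conditions, _ = generate_planted(
                n_sets=n_sets,
                n_samples=n_samples,
                conditions=n_blocks,
                planted_edges=[(pair, "C1", strength)],
                noise=0.0,
                seed=design_seed,
            )
            config = SearchConfig(R=R, base_seed=derive_seed(design_seed, "net"), **ess_kw)
            net = consensus(data, config)
            d_all = net.d_of(*pair)
            sub = data.drop_samples(conditions.samples_of("C1"))
            cfg_wo = SearchConfig(R=R_perm, base_seed=derive_seed(design_seed, "without"), **ess_kw)
            d_wo = consensus(sub, cfg_wo).d_of(*pair)
            g_rep.append(gamma_fn(d_all, d_wo, R_perm))
            only = data.select_samples(conditions.samples_of("C1"))
            cfg_in = SearchConfig(R=R_perm, base_seed=derive_seed(design_seed, "within"), **ess_kw)
            w_rep.append(consensus(only, cfg_in).d_of(*pair))
        gammas.append(float(np.mean(g_rep)))
        d_within.append(float(np.mean(w_rep)))
    rho = float(spearmanr(gammas, d_within).statistic)
    return {
        "strengths": list(strengths),
        "gamma": gammas,
        "d_within": d_within,
        "spearman": rho,
    }


# ---------------------------------------------------------------------------
# Summarization versus brute-force hypergeometric oracle
# ---------------------------------------------------------------------------

def _hypergeom_tail_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric mass."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def _summary_oracle(
    member_states: np.ndarray, bg_states: np.ndarray, params: SummaryParams
) -> int:
    """Direct re-statement of the summarization rule on raw state vectors."""
    N = bg_states.size
    m = member_states.size
    for direction, state in ((UP, UP), (DOWN, DOWN)):
        k = int((member_states == state).sum())
        K = int((bg_states == state).sum())
        if k > params.r * m and _hypergeom_tail_bruteforce(k, N, K, m) < params.p_threshold:
            return direction
    return NOCHANGE


def summarize_oracle_check(
    seed: int, n_trials: int = 1000, max_set_size: int = 12
) -> dict:
    """Summarizer versus brute-force oracle on random backgrounds.

    Each trial draws a random background column (random size and state
    frequencies), a random member subset of size up to ``max_set_size``,
    and compares the package summarizer against an independent explicit
    summation of hypergeometric masses.
    """
    params = SummaryParams()
    agree = 0
    for t in range(n_trials):
        rng = np.random.default_rng(derive_seed(seed, "sumoracle", t))
        N = int(rng.integers(30, 1500))
        probs = rng.dirichlet((1.0, 1.0, 1.0))
        bg = rng.choice(np.array([DOWN, NOCHANGE, UP], dtype=np.int8), size=N, p=probs)
        m = int(rng.integers(1, max_set_size + 1))
        # bias half the trials toward coherent sets so both branches are hit
        if t % 2 == 0:
            direction = UP if rng.random() < 0.5 else DOWN
            pool = np.flatnonzero(bg == direction)
            take = min(m, pool.size)
            members = list(rng.choice(pool, size=take, replace=False))
            rest = [i for i in range(N) if i not in set(members)]
            members += list(rng.choice(rest, size=m - take, replace=False))
            members = np.array(members)
        else:
            members = rng.choice(N, size=m, replace=False)
        gene_ids = [f"g{i}" for i in range(N)]
        background = TrinaryMatrix(bg[:, None], gene_ids, ["s1"])
        subset = background.select_rows([gene_ids[i] for i in members])
        got = summarize_gene_set(subset, background, "s1", params)
        want = _summary_oracle(bg[members], bg, params)
        agree += got == want
    return {"n_trials": n_trials, "n_agree": agree, "agreement": agree / n_trials}
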