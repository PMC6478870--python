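"""Pathway enrichment statistics and multiple-testing correction.

Two enrichment modes are provided: a plain upper-tail hypergeometric test of
a selected metabolite (or gene) set against pathway membership sets, and a
rank-based iterative hypergeometric test asking whether a pathway's members
concentrate toward the top of a ranking — the minimum hypergeometric p over
all prefixes ending at a member rank, calibrated by random rank
permutations.

Multiple-testing correction uses Storey q-values (pi0 estimated from the
p-value distribution); with too few tests for a stable pi0 estimate the
correction falls back to Benjamini-Hochberg with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    """One pathway's enrichment against a selection or ranking."""

    pathway: str
    overlap: int        # k
    set_size: int       # K (restricted to the universe)
    selected_size: int  # n
    universe_size: int  # N
    p: float
    q: float = np.nan
    direction: str = "none"


def hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric: P(X >= k) drawing n from N with K marked."""
    if K == 0 or n == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    selected: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    direction: str = "none",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a selection in each pathway.

    Pathway members are restricted to the universe; ``selected`` must be a
    subset of the universe. Storey q-values are appended across pathways.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected ids must be a subset of the universe")
    N, n = len(universe), len(selected)
    out = []
    for name, members in sets.items():
        mem = members & universe
        k = len(mem & selected)
        out.append(EnrichmentResult(
            pathway=name, overlap=k, set_size=len(mem), selected_size=n,
            universe_size=N, p=hypergeom_p(k, N, len(mem), n), direction=direction,
        ))
    if out:
        qs = storey_q(np.array([r.p for r in out]))
        for r, q in zip(out, qs):
            r.q = float(q)
    return out


def directional_enrichment(
    scores: pd.Series,
    sets: dict[str, set[str]],
    threshold: float,
) -> list[EnrichmentResult]:
    """Set enrichment run separately on positive and negative selections.

    ``scores`` maps ids to a signed statistic (e.g. correlation with flux);
    ids with score > ``threshold`` form the positive selection, score <
    -``threshold`` the negative one.
    """
    universe = set(scores.index)
    pos = set(scores.index[scores > threshold])
    neg = set(scores.index[scores < -threshold])
    results = hypergeom_enrichment(pos, sets, universe, direction="positive")
    results += hypergeom_enrichment(neg, sets, universe, direction="negative")
    return results


def iterative_rank_enrichment(
    ranked: list[str],
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Min-over-prefixes hypergeometric test of top-rank concentration.

    For each pathway, every prefix of the ranking ending at one of its
    members yields an upper-tail hypergeometric p; the pathway score is the
    minimum over prefixes. Because the minimum is itself selected, its
    significance is calibrated against ``n_perm`` random permutations of the
    ranking (fraction of null minima <= observed). Pathways with no member
    in the ranking are skipped. Storey q-values appended.
    """
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranking contains duplicate ids")
    N = len(ranked)
    pos = {x: i for i, x in enumerate(ranked)}
    rng = np.random.default_rng(seed)

    def min_p(member_ranks: np.ndarray, K: int) -> float:
        # prefix ending at the j-th member's rank r contains k=j+1 members
        ranks = np.sort(member_ranks)
        ks = np.arange(1, K + 1)
        ps = stats.hypergeom.sf(ks - 1, N, K, ranks + 1)
        return float(ps.min())

    out = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        mem = [m for m in members if m in pos]
        K = len(mem)
        if K == 0:
            continue
        obs = min_p(np.array([pos[m] for m in mem]), K)
        if K not in null_cache:
            nulls = np.empty(n_perm)
            for b in range(n_perm):
                nulls[b] = min_p(np.sort(rng.choice(N, size=K, replace=False)), K)
            null_cache[K] = nulls
        p_cal = float((null_cache[K] <= obs).mean())
        p_cal = max(p_cal, 1.0 / n_perm)  # permutation resolution floor
        out.append(EnrichmentResult(
            pathway=name, overlap=K, set_size=K, selected_size=N,
            universe_size=N, p=p_cal,
        ))
    if out:
        qs = storey_q(np.array([r.p for r in out]))
        for r, q in zip(out, qs):
            r.q = float(q)
    return out


def storey_q(p: np.ndarray, lambdas: np.ndarray | None = None, min_tests: int = 10) -> np.ndarray:
    """Storey q-values with a smoothed pi0 estimate.

    pi0 is estimated on a lambda grid as #{p > lambda} / (m (1 - lambda))
    and extrapolated to lambda -> 1 with a cubic polynomial smoother. With
    fewer than ``min_tests`` p-values the pi0 estimate is unstable and the
    function falls back to Benjamini-Hochberg (pi0 = 1) with a warning.
    q-values are monotone non-decreasing in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()

    if m < min_tests:
        warnings.warn(f"only {m} tests: falling back to Benjamini-Hochberg correction")
        pi0 = 1.0
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.95, 0.05)
        pi0_l = np.array([(p > l).mean() / (1.0 - l) for l in lambdas])
        if np.allclose(pi0_l, pi0_l[0]):
            pi0 = float(pi0_l[0])
        else:
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
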