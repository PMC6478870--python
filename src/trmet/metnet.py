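"""Distances between enzymes / TR targets and metabolites on a bipartite
stoichiometric graph, with randomized-network significance.

The graph has metabolite and reaction nodes; an edge marks participation of
a metabolite in a reaction (direction ignored). The distance from an enzyme
to a metabolite is the number of reaction nodes on the shortest alternating
path starting from any reaction the enzyme catalyzes, inclusive of that
starting reaction: a metabolite of the enzyme's own reaction has distance 1.
A TR's distance to a metabolite is the minimum over its enzyme targets.

Observed distance-vs-correlation curves are compared against the same curve
on degree-preserving randomized graphs (bipartite double-edge swaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

UNREACHABLE = -1


@dataclass
class MetabolicGraph:
    """Bipartite metabolite/reaction graph with an enzyme -> reaction map."""

    graph: nx.Graph
    gene_reactions: dict[str, list[str]]

    def __post_init__(self) -> None:
        for n, d in self.graph.nodes(data=True):
            if d.get("bipartite") not in (0, 1):
                raise ValueError(f"node {n!r} lacks a bipartite label")
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["bipartite"] == self.graph.nodes[v]["bipartite"]:
                raise ValueError(f"edge within one node class: {(u, v)}")
        rxns = set(self.reactions)
        for gene, rlist in self.gene_reactions.items():
            missing = set(rlist) - rxns
            if missing:
                raise ValueError(f"gene {gene!r} maps to unknown reactions {sorted(missing)}")

    @property
    def metabolites(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["bipartite"] == 0)

    @property
    def reactions(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["bipartite"] == 1)

    @classmethod
    def from_reaction_table(cls, table: pd.DataFrame) -> "MetabolicGraph":
        """Build from a table with columns reaction_id, gene_ids, substrates,
        products (ids ;-separated)."""
        g = nx.Graph()
        gene_reactions: dict[str, list[str]] = {}
        for row in table.itertuples(index=False):
            rxn = row.reaction_id
            g.add_node(rxn, bipartite=1)
            mets = set()
            for fieldval in (row.substrates, row.products):
                if isinstance(fieldval, str) and fieldval:
                    mets.update(fieldval.split(";"))
            for m in mets:
                g.add_node(m, bipartite=0)
                g.add_edge(m, rxn)
            if isinstance(row.gene_ids, str) and row.gene_ids:
                for gene in row.gene_ids.split(";"):
                    gene_reactions.setdefault(gene, []).append(rxn)
        return cls(graph=g, gene_reactions=gene_reactions)

    def edge_list(self) -> list[tuple[str, str]]:
        """(metabolite, reaction) edges."""
        out = []
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["bipartite"] == 0:
                out.append((u, v))
            else:
                out.append((v, u))
        return out


def _distance_matrix(
    mets: list[str], rxns: list[str], edges: list[tuple[str, str]], source_rxns: list[str]
) -> np.ndarray:
    """Reaction-count distances from each source reaction to all metabolites.

    BFS on the bipartite adjacency; a path from a reaction to a metabolite
    has an odd number of edges 2d-1 where d is the reaction count, so
    d = (edges + 1) / 2. Unreachable pairs get +inf.
    """
    m_idx = {m: i for i, m in enumerate(mets)}
    r_idx = {r: i + len(mets) for i, r in enumerate(rxns)}
    n = len(mets) + len(rxns)
    rows, cols = [], []
    for m, r in edges:
        rows += [m_idx[m], r_idx[r]]
        cols += [r_idx[r], m_idx[m]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    sources = [r_idx[r] for r in source_rxns]
    if not sources:
        return np.full((0, len(mets)), np.inf)
    d = dijkstra(adj, directed=False, unweighted=True, indices=sources)
    return (d[:, : len(mets)] + 1.0) / 2.0


def enzyme_metabolite_distance(graph: MetabolicGraph, enzyme: str, metabolite: str) -> int:
    """Minimum number of reactions separating an enzyme from a metabolite.

    Distance 1 means the metabolite participates in one of the enzyme's own
    reactions. Returns ``UNREACHABLE`` (-1) if no path exists.
    """
    if enzyme not in graph.gene_reactions:
        raise KeyError(f"unknown enzyme {enzyme!r}")
    mets = graph.metabolites
    if metabolite not in mets:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    D = _distance_matrix(mets, graph.reactions, graph.edge_list(), graph.gene_reactions[enzyme])
    d = D[:, mets.index(metabolite)].min()
    return UNREACHABLE if np.isinf(d) else int(d)


def tr_metabolite_distance(graph: MetabolicGraph, enzyme_targets: list[str], metabolite: str) -> int:
    """Minimum enzyme-metabolite distance over a TR's enzyme targets."""
    if not enzyme_targets:
        raise ValueError("empty enzyme-target set")
    known = [e for e in enzyme_targets if e in graph.gene_reactions]
    if not known:
        raise KeyError("no enzyme target maps to a reaction")
    dists = [enzyme_metabolite_distance(graph, e, metabolite) for e in known]
    reachable = [d for d in dists if d != UNREACHABLE]
    return min(reachable) if reachable else UNREACHABLE


def tr_distance_matrix(
    graph: MetabolicGraph,
    tr_targets: dict[str, list[str]],
    metabolites: list[str] | None = None,
    max_degree: int | None = None,
) -> pd.DataFrame:
    """TR x metabolite reaction-count distances (min over enzyme targets).

    ``max_degree`` optionally drops metabolites of higher degree (currency
    hubs) from the path search. TRs without mapped enzymes get all-inf rows.
    """
    mets_all = graph.metabolites
    edges = graph.edge_list()
    if max_degree is not None:
        deg = dict(graph.graph.degree())
        hubs = {m for m in mets_all if deg[m] > max_degree}
        edges = [(m, r) for m, r in edges if m not in hubs]
    rxns = graph.reactions
    want = metabolites if metabolites is not None else mets_all
    col_idx = [mets_all.index(m) for m in want if m in mets_all]

    out = np.full((len(tr_targets), len(col_idx)), np.inf)
    for i, (tr, enzymes) in enumerate(tr_targets.items()):
        src = sorted({r for e in enzymes for r in graph.gene_reactions.get(e, [])})
        if not src:
            continue
        D = _distance_matrix(mets_all, rxns, edges, src)
        out[i] = D.min(axis=0)[col_idx]
    cols = [m for m in want if m in mets_all]
    return pd.DataFrame(out, index=list(tr_targets), columns=cols)


def randomize_bipartite(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_swaps: int | None = None
) -> list[tuple[str, str]]:
    """Degree-preserving randomization by bipartite double-edge swaps.

    Two (metabolite, reaction) edges exchange their reaction endpoints;
    swaps creating duplicate edges are rejected. Preserves the degree
    sequence of both node classes exactly.
    """
    edges = list(edges)
    n = len(edges)
    if n < 2:
        return edges
    present = set(edges)
    target = n_swaps if n_swaps is not None else 2 * n
    done = attempts = 0
    while done < target and attempts < 20 * target:
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        (m1, r1), (m2, r2) = edges[i], edges[j]
        if r1 == r2 or m1 == m2:
            continue
        e1, e2 = (m1, r2), (m2, r1)
        if e1 in present or e2 in present:
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        edges[i], edges[j] = e1, e2
        present.add(e1)
        present.add(e2)
        done += 1
    return edges


def _randomize_int_edges(
    e_m: np.ndarray, e_r: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-array double-edge swaps (same scheme as randomize_bipartite)."""
    em, er = e_m.copy(), e_r.copy()
    n = len(em)
    width = int(er.max()) + 1 if n else 1
    present = set((em * width + er).tolist())
    target = 2 * n
    done = 0
    pairs = rng.integers(0, n, size=(20 * target, 2))
    for i, j in pairs:
        if done >= target:
            break
        if i == j or er[i] == er[j] or em[i] == em[j]:
            continue
        k1, k2 = em[i] * width + er[j], em[j] * width + er[i]
        if k1 in present or k2 in present:
            continue
        present.discard(int(em[i] * width + er[i]))
        present.discard(int(em[j] * width + er[j]))
        er[i], er[j] = er[j], er[i]
        present.add(int(k1))
        present.add(int(k2))
        done += 1
    return em, er


def distance_correlation_curve(
    assoc_R: pd.DataFrame,
    graph: MetabolicGraph,
    tr_targets: dict[str, list[str]],
    thresholds: np.ndarray | list[float] | None = None,
    n_random: int = 10_000,
    seed: int = 0,
    mode: str = "cumulative",
) -> pd.DataFrame:
    """Mean TR-metabolite distance versus association-strength threshold.

    For each |R| threshold t, the observed mean network distance over pairs
    with |R| >= t (cumulative sweep; ``mode="binned"`` uses |R| bins instead)
    is compared to the same quantity on ``n_random`` degree-preserving
    randomized graphs. The permutation p per threshold is the fraction of
    null means <= the observed one (proximity = small distance); Storey
    q-values are appended.
    """
    from .enrich import storey_q

    if thresholds is None:
        thresholds = np.arange(0.0, 0.85, 0.05)
    thresholds = np.asarray(list(thresholds), dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")

    mets_all = graph.metabolites
    rxns = graph.reactions
    met_pos = {m: i for i, m in enumerate(mets_all)}
    rxn_pos = {r: i for i, r in enumerate(rxns)}
    mets = [m for m in assoc_R.columns if m in met_pos]
    trs = [t for t in assoc_R.index if t in tr_targets]
    absR = assoc_R.loc[trs, mets].abs().to_numpy()
    met_cols = np.array([met_pos[m] for m in mets])

    # integer edge arrays; one multi-source BFS per graph over the union of
    # all TRs' reactions, then per-TR minima over its own source rows
    base = graph.edge_list()
    e_m = np.array([met_pos[m] for m, _ in base])
    e_r = np.array([rxn_pos[r] for _, r in base])
    tr_sources = {
        t: sorted({rxn_pos[r] for e in tr_targets[t] for r in graph.gene_reactions.get(e, [])})
        for t in trs
    }
    all_sources = sorted({r for s in tr_sources.values() for r in s})
    src_row = {r: i for i, r in enumerate(all_sources)}
    tr_rows = [np.array([src_row[r] for r in tr_sources[t]], dtype=int) for t in trs]
    n_m, n_r = len(mets_all), len(rxns)
    n_nodes = n_m + n_r

    def tr_distances(em: np.ndarray, er: np.ndarray) -> np.ndarray:
        rows = np.concatenate([em, er + n_m])
        cols = np.concatenate([er + n_m, em])
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes))
        d = dijkstra(adj, directed=False, unweighted=True,
                     indices=[s + n_m for s in all_sources])
        Dsrc = (d[:, met_cols] + 1.0) / 2.0
        D = np.full((len(trs), len(met_cols)), np.inf)
        for i, rows_i in enumerate(tr_rows):
            if len(rows_i):
                D[i] = Dsrc[rows_i].min(axis=0)
        return D

    # prefix sums along pairs sorted by |R| give every cumulative-threshold
    # mean in one pass; binned mode uses the per-bin differences
    flatR = absR.ravel()
    order = np.argsort(-flatR, kind="mergesort")
    counts_ge = np.searchsorted(-flatR[order], -thresholds, side="right")

    def masked_means(D: np.ndarray) -> np.ndarray:
        d_ord = D.ravel()[order]
        finite = np.isfinite(d_ord)
        csum = np.concatenate([[0.0], np.cumsum(np.where(finite, d_ord, 0.0))])
        cnum = np.concatenate([[0], np.cumsum(finite)])
        means = np.full(len(thresholds), np.nan)
        for k in range(len(thresholds)):
            if mode == "cumulative":
                lo, hi = 0, counts_ge[k]
            else:
                hi = counts_ge[k]
                lo = counts_ge[k + 1] if k + 1 < len(thresholds) else 0
                lo, hi = min(lo, hi), max(lo, hi)
            n_fin = cnum[hi] - cnum[lo]
            if n_fin:
                means[k] = (csum[hi] - csum[lo]) / n_fin
        return means

    observed = masked_means(tr_distances(e_m, e_r))

    rng = np.random.default_rng(seed)
    null = np.empty((n_random, len(thresholds)))
    for b in range(n_random):
        em, er = _randomize_int_edges(e_m, e_r, rng)
        null[b] = masked_means(tr_distances(em, er))

    with np.errstate(invalid="ignore"):
        pvals = np.array([
            np.mean(null[:, k][np.isfinite(null[:, k])] <= observed[k]) if np.isfinite(observed[k]) else np.nan
            for k in range(len(thresholds))
        ])
    mask = np.isfinite(pvals)
    q = np.full(len(thresholds), np.nan)
    if mask.sum():
        q[mask] = storey_q(pvals[mask])
    return pd.DataFrame({
        "threshold": thresholds,
        "mean_distance": observed,
        "null_mean": np.nanmean(null, axis=0),
        "p": pvals,
        "q": q,
    })
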