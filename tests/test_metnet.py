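"""Bipartite metabolic-network distances and randomization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trmet import metnet


def chain_graph() -> metnet.MetabolicGraph:
    """m1 - R1 - m2 - R2 - m3 with enzymes e1 -> R1, e2 -> R2."""
    table = pd.DataFrame({
        "reaction_id": ["R1", "R2"],
        "gene_ids": ["e1", "e2"],
        "substrates": ["m1", "m2"],
        "products": ["m2", "m3"],
    })
    return metnet.MetabolicGraph.from_reaction_table(table)


def random_graph(seed: int, n_m=12, n_r=14) -> metnet.MetabolicGraph:
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_r):
        mets = rng.choice(n_m, size=rng.integers(2, 4), replace=False)
        rows.append({
            "reaction_id": f"R{r}",
            "gene_ids": f"e{r}",
            "substrates": ";".join(f"m{i}" for i in mets[:-1]),
            "products": f"m{mets[-1]}",
        })
    return metnet.MetabolicGraph.from_reaction_table(rows_df(rows))


def rows_df(rows):
    return pd.DataFrame(rows)


class TestDistances:
    def test_chain_convention(self):
        g = chain_graph()
        assert metnet.enzyme_metabolite_distance(g, "e1", "m1") == 1
        assert metnet.enzyme_metabolite_distance(g, "e1", "m2") == 1
        assert metnet.enzyme_metabolite_distance(g, "e1", "m3") == 2
        assert metnet.enzyme_metabolite_distance(g, "e2", "m1") == 2

    def test_disconnected_metabolite_unreachable(self):
        table = pd.DataFrame({
            "reaction_id": ["R1", "R2"],
            "gene_ids": ["e1", "e2"],
            "substrates": ["m1", "m9"],
            "products": ["m2", "m10"],
        })
        g = metnet.MetabolicGraph.from_reaction_table(table)
        assert metnet.enzyme_metabolite_distance(g, "e1", "m9") == metnet.UNREACHABLE

    def test_unknown_entities_rejected(self):
        g = chain_graph()
        with pytest.raises(KeyError):
            metnet.enzyme_metabolite_distance(g, "nope", "m1")
        with pytest.raises(KeyError):
            metnet.enzyme_metabolite_distance(g, "e1", "nope")

    def test_matches_all_pairs_oracle(self):
        """BFS reaction counts agree with networkx path lengths on random graphs."""
        for seed in range(8):
            g = random_graph(seed)
            lengths = dict(nx.all_pairs_shortest_path_length(g.graph))
            for enzyme, rxns in list(g.gene_reactions.items())[:5]:
                for met in g.metabolites[:6]:
                    expected = min(
                        (lengths[r].get(met, np.inf) for r in rxns), default=np.inf
                    )
                    got = metnet.enzyme_metabolite_distance(g, enzyme, met)
                    if np.isinf(expected):
                        assert got == metnet.UNREACHABLE
                    else:
                        # reaction count = (edge count + 1) / 2 on alternating paths
                        assert got == int((expected + 1) // 2)

    def test_tr_distance_is_min_over_targets(self):
        g = chain_graph()
        assert metnet.tr_metabolite_distance(g, ["e1"], "m3") == 2
        assert metnet.tr_metabolite_distance(g, ["e1", "e2"], "m3") == 1
        with pytest.raises(ValueError):
            metnet.tr_metabolite_distance(g, [], "m3")

    def test_adding_target_never_increases_distance(self):
        g = random_graph(3)
        enzymes = list(g.gene_reactions)
        for met in g.metabolites[:4]:
            d1 = metnet.tr_metabolite_distance(g, enzymes[:1], met)
            d2 = metnet.tr_metabolite_distance(g, enzymes[:3], met)
            if d1 != metnet.UNREACHABLE and d2 != metnet.UNREACHABLE:
                assert d2 <= d1


class TestRandomization:
    def test_degree_sequences_preserved(self):
        g = random_graph(1)
        edges = g.edge_list()
        rng = np.random.default_rng(0)
        shuffled = metnet.randomize_bipartite(edges, rng)
        assert shuffled != edges  # swaps actually happened

        def degs(es):
            m, r = {}, {}
            for a, b in es:
                m[a] = m.get(a, 0) + 1
                r[b] = r.get(b, 0) + 1
            return m, r

        assert degs(edges) == degs(shuffled)
        assert len(set(shuffled)) == len(shuffled)  # stays a simple graph

    def test_integer_variant_matches_contract(self):
        g = random_graph(2)
        mets, rxns = g.metabolites, g.reactions
        mp = {m: i for i, m in enumerate(mets)}
        rp = {r: i for i, r in enumerate(rxns)}
        e_m = np.array([mp[m] for m, _ in g.edge_list()])
        e_r = np.array([rp[r] for _, r in g.edge_list()])
        em, er = metnet._randomize_int_edges(e_m, e_r, np.random.default_rng(1))
        assert np.array_equal(np.sort(np.bincount(em)), np.sort(np.bincount(e_m)))
        assert np.array_equal(np.sort(np.bincount(er)), np.sort(np.bincount(e_r)))
        assert len({(a, b) for a, b in zip(em, er)}) == len(em)


class TestDistanceCurve:
    def test_planted_proximity_decreases_distance(self, small_study):
        """Metabolites coupled to a TR sit near its enzyme targets, so the
        curve falls as the |R| threshold rises."""
        truth = small_study.truth
        graph = metnet.MetabolicGraph.from_reaction_table(truth.reaction_table)
        # synthetic association signal: strong R exactly for coupled pairs
        rng = np.random.default_rng(0)
        trs = list(truth.coupled_metabolites)
        mets = graph.metabolites
        R = pd.DataFrame(rng.uniform(-0.2, 0.2, (len(trs), len(mets))), index=trs, columns=mets)
        for tr, cm in truth.coupled_metabolites.items():
            for m in cm:
                R.loc[tr, m] = 0.9
        tr_targets = {}
        for tr, gene, mode in truth.regulatory_edges:
            if tr in trs and gene in graph.gene_reactions:
                tr_targets.setdefault(tr, []).append(gene)
        curve = metnet.distance_correlation_curve(
            R, graph, tr_targets, thresholds=[0.0, 0.5], n_random=50, seed=0
        )
        assert curve["mean_distance"].iloc[1] < curve["mean_distance"].iloc[0]
        assert curve["p"].iloc[1] < 0.05

    def test_threshold_zero_self_consistent_with_null(self, small_study):
        """At threshold 0 every pair counts; the observed mean sits inside
        the null distribution (p not extreme)."""
        truth = small_study.truth
        graph = metnet.MetabolicGraph.from_reaction_table(truth.reaction_table)
        rng = np.random.default_rng(1)
        trs = [f"TR{i + 1:03d}" for i in range(5)]
        tr_targets = {}
        for tr, gene, mode in truth.regulatory_edges:
            if tr in trs and gene in graph.gene_reactions:
                tr_targets.setdefault(tr, []).append(gene)
        mets = graph.metabolites
        R = pd.DataFrame(rng.uniform(-0.9, 0.9, (len(tr_targets), len(mets))),
                         index=list(tr_targets), columns=mets)
        curve = metnet.distance_correlation_curve(
            R, graph, tr_targets, thresholds=[0.0], n_random=100, seed=0
        )
        assert 0.05 < curve["p"].iloc[0]

    def test_ascending_thresholds_required(self, small_study):
        truth = small_study.truth
        graph = metnet.MetabolicGraph.from_reaction_table(truth.reaction_table)
        with pytest.raises(ValueError, match="ascending"):
            metnet.distance_correlation_curve(
                pd.DataFrame(), graph, {}, thresholds=[0.5, 0.1], n_random=2
            )


def test_bipartite_invariant_enforced():
    g = nx.Graph()
    g.add_node("m1", bipartite=0)
    g.add_node("m2", bipartite=0)
    g.add_edge("m1", "m2")
    with pytest.raises(ValueError, match="one node class"):
        metnet.MetabolicGraph(graph=g, gene_reactions={})
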