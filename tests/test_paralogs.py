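"""Percent identity, duplication detection, clustering and NJ phylograms.

The neighbour-joining check uses an independent oracle: exhaustive
enumeration of all unrooted binary topologies with ordinary-least-squares
branch lengths, picking the minimum-evolution (shortest total length) tree.
For additive distance matrices NJ must recover that topology.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from avipurge import (
    ParalogParams,
    SimulationConfig,
    build_phylogram,
    detect_duplications,
    identity_matrix,
    nj_tree,
    pairwise_identity,
    simulate_panel,
    single_linkage_clusters,
)
from avipurge.catalog import hits_to_frame, SpeciesHit

AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# brute-force minimum-evolution oracle
# ---------------------------------------------------------------------------

def enumerate_topologies(taxa):
    """All unrooted binary topologies as edge lists (taxa + internal ints)."""
    if len(taxa) == 3:
        yield [("X0", t) for t in taxa], 1
        return
    *rest, last = taxa
    for edges, n_internal in enumerate_topologies(rest):
        for i, (u, v) in enumerate(edges):
            new = f"X{n_internal}"
            out = edges[:i] + edges[i + 1:]
            out += [(u, new), (new, v), (new, last)]
            yield out, n_internal + 1


def ols_total_length(edges, taxa, dist):
    """OLS branch lengths for a fixed topology; returns total tree length."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(a, b):
        stack, seen = [(a, [])], {a}
        while stack:
            node, path = stack.pop()
            if node == b:
                return path
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, path + [frozenset((node, nxt))]))
        raise AssertionError("disconnected topology")

    edge_ids = [frozenset(e) for e in edges]
    pairs = list(itertools.combinations(taxa, 2))
    design = np.zeros((len(pairs), len(edge_ids)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for e in path_edges(a, b):
            design[r, edge_ids.index(e)] = 1.0
        y[r] = dist.loc[a, b]
    lengths, residuals, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((design @ lengths - y) ** 2).sum())
    return float(lengths.sum()), rss


def splits(newick: str, taxa) -> set:
    """Nontrivial bipartitions of an unrooted tree, as frozensets."""
    tree = TreeNode.read([newick])
    full = frozenset(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(full) - 1:
            out.add(min(side, full - side, key=sorted))
    return out


def edges_to_splits(edges, taxa) -> set:
    """Canonical nontrivial bipartitions induced by a topology's edges."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    leaves = set(taxa)
    out = set()
    for u, v in edges:
        if u in leaves or v in leaves:
            continue
        side, stack, seen = set(), [u], {u, v}
        while stack:
            node = stack.pop()
            if node in leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(frozenset(side), frozenset(leaves - side), key=sorted))
    return out


def random_additive_matrix(taxa, rng):
    """Distances induced by a random binary tree with positive lengths."""
    topo = list(enumerate_topologies(list(taxa)))
    edges, _ = topo[rng.integers(len(topo))]
    lengths = {frozenset(e): rng.uniform(1.0, 10.0) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    dist = pd.DataFrame(0.0, index=list(taxa), columns=list(taxa))
    for a, b in itertools.combinations(taxa, 2):
        stack, seen = [(a, 0.0)], {a}
        while stack:
            node, d = stack.pop()
            if node == b:
                dist.loc[a, b] = dist.loc[b, a] = d
                break
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, d + lengths[frozenset((node, nxt))]))
    return dist, edges_to_splits(edges, taxa)


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_single_substitution_over_ten_sites(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(90.0)

    def test_gap_columns_count_in_denominator(self):
        # one match over two alignment columns whichever end gaps
        assert pairwise_identity("A", "AA") == pytest.approx(50.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pairwise_identity("", "ACD")

    @given(
        a=st.text(AA, min_size=1, max_size=12),
        b=st.text(AA, min_size=1, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        ab = pairwise_identity(a, b)
        assert ab == pytest.approx(pairwise_identity(b, a))
        assert 0.0 <= ab <= 100.0

    def test_identity_matrix_shape(self):
        idm = identity_matrix({"a": "ACDE", "b": "ACDF", "c": "WWWW"})
        assert np.allclose(np.diag(idm.values), 100.0)
        assert np.allclose(idm.values, idm.values.T)


# ---------------------------------------------------------------------------
# duplication detection
# ---------------------------------------------------------------------------

class TestDetectDuplications:
    def test_two_paralogs_everywhere_flags_duplicated(self):
        hits = hits_to_frame(
            [SpeciesHit(f"sp{i}", "neoaves", "SLC7A11", 100, None, p)
             for i in range(4) for p in (1, 2)]
        )
        out = detect_duplications(hits).set_index("gene")
        assert out.loc["SLC7A11", "median_neoave_paralogs"] == 2
        assert bool(out.loc["SLC7A11", "duplicated_in_neoaves"])

    def test_single_copies_not_flagged(self):
        hits = hits_to_frame(
            [SpeciesHit(f"sp{i}", "neoaves", "G1", 100) for i in range(4)]
        )
        assert not detect_duplications(hits)["duplicated_in_neoaves"].any()

    def test_outgroup_rows_ignored(self):
        hits = hits_to_frame(
            [SpeciesHit("o1", "galloanserae", "G1", 100, None, p) for p in (1, 2)]
        )
        assert detect_duplications(hits).empty

    def test_simulated_truth_count_recovered(self):
        cfg = SimulationConfig(n_neoaves=6, n_outgroup=2, n_genes=5, p_dup=1.0,
                               dup_paralogs=(3, 3), rng_seed=6)
        panel = simulate_panel(cfg)
        out = detect_duplications(panel.hits)
        assert (out["median_neoave_paralogs"] == 3).all()
        assert out["duplicated_in_neoaves"].all()


# ---------------------------------------------------------------------------
# clustering and phylograms
# ---------------------------------------------------------------------------

class TestClustering:
    def test_two_identical_one_divergent(self):
        seqs = {"id1": "ACDEFGHIKL", "id2": "ACDEFGHIKL", "id3": "WWWWWWWWWW"}
        clusters = single_linkage_clusters(identity_matrix(seqs), cutoff=80.0)
        assert clusters == [frozenset({"id1", "id2"}), frozenset({"id3"})]

    def test_cutoff_is_inclusive(self):
        idm = pd.DataFrame(
            [[100.0, 80.0], [80.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        assert single_linkage_clusters(idm, cutoff=80.0) == [frozenset({"a", "b"})]
        assert len(single_linkage_clusters(idm, cutoff=81.0)) == 2


class TestPhylogram:
    def test_three_taxa_branch_lengths(self):
        # identities 98 (A,B), 92 (A,C) and (B,C): distances 2, 8, 8 force
        # the cherry (A,B) with branch lengths 1, 1, 7
        base = "A" * 50
        seqs = {
            "A": base,
            "B": "C" + base[1:],
            "C": "DDDD" + base[4:],
        }
        result = build_phylogram(seqs)
        tree = TreeNode.read([result.newick])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(7.0)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError, match="pairwise"):
            build_phylogram({"a": "ACD", "b": "ACD"})

    def test_alphabetical_truncation_rule(self):
        from avipurge.paralogs import select_sequences

        seqs = {f"sp_{c}": "ACDE" for c in "edcba"}
        chosen = select_sequences(seqs, max_sequences=3)
        assert list(chosen) == ["sp_a", "sp_b", "sp_c"]

    def test_leaf_set_and_nonnegative_branches(self):
        rng = np.random.default_rng(5)
        taxa = ["a", "b", "c", "d", "e"]
        dist, _ = random_additive_matrix(taxa, rng)
        tree = TreeNode.read([nj_tree(dist)])
        assert {t.name for t in tree.tips()} == set(taxa)
        for node in tree.traverse(include_self=False):
            assert node.length is not None and node.length >= -1e-12

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_nj_matches_minimum_evolution_enumeration(self, n_taxa):
        taxa = [f"t{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            dist, true_splits = random_additive_matrix(taxa, rng)
            # oracle: exhaustive minimum evolution over all topologies with
            # OLS branch lengths (shortest total length wins)
            scored = [
                (*ols_total_length(edges, taxa, dist), edges)
                for edges, _ in enumerate_topologies(taxa)
            ]
            best_len, best_rss, best_edges = min(scored, key=lambda t: t[0])
            assert best_rss < 1e-12  # additive matrix fits its topology exactly
            oracle_splits = edges_to_splits(best_edges, taxa)
            nj_splits = splits(nj_tree(dist), taxa)
            assert nj_splits == oracle_splits == true_splits

    def test_relabeling_preserves_topology(self):
        taxa = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(11)
        dist, _ = random_additive_matrix(taxa, rng)
        mapping = {"a": "w1", "b": "w2", "c": "w3", "d": "w4", "e": "w5"}
        relabeled = dist.rename(index=mapping, columns=mapping)
        s1 = splits(nj_tree(dist), taxa)
        s2 = splits(nj_tree(relabeled), list(mapping.values()))
        renamed = {frozenset(min((frozenset(mapping[x] for x in s)),
                                  frozenset(mapping.values()) - frozenset(mapping[x] for x in s),
                                  key=sorted)) for s in s1}
        assert {frozenset(s) for s in s2} == renamed

    def test_simulated_paralog_clusters_recovered(self):
        cfg = SimulationConfig(
            n_neoaves=4, n_outgroup=2, n_genes=1, p_dup=1.0, dup_paralogs=(2, 2),
            paralog_identity=0.70, species_identity=0.95, with_sequences=True,
            ref_length_range=(300, 400), rng_seed=21,
        )
        panel = simulate_panel(cfg)
        neo = panel.hits[panel.hits["clade"] == "neoaves"]
        seqs = {
            f"{r.species}|{r.paralog_index}": r.sequence
            for r in neo.itertuples(index=False)
        }
        result = build_phylogram(seqs, ParalogParams(cluster_cutoff=80.0))
        assert len(result.clusters) == 2
        by_paralog = {
            p: {k for k in seqs if k.endswith(f"|{p}")} for p in (1, 2)
        }
        assert {frozenset(c) for c in result.clusters} == {
            frozenset(by_paralog[1]), frozenset(by_paralog[2])
        }
        within = [
            result.identity.loc[a, b]
            for grp in by_paralog.values()
            for a, b in itertools.combinations(sorted(grp), 2)
        ]
        assert abs(np.mean(within) - 95.0) < 3.0
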