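import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptax import barcode as bc
from cryptax.datagen import Scenario, gen_sequences
from cryptax.errors import (
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
    ValidationError,
)

from conftest import make_species

seq_strategy = st.text(alphabet="ACGT", min_size=1, max_size=120)
seq_with_gaps = st.text(alphabet="ACGTN-", min_size=1, max_size=120)


# ---------------------------------------------------------------------------
# pairwise distances

class TestPDistance:
    def test_identical(self):
        assert bc.p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_one_of_four(self):
        assert bc.p_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        assert bc.p_distance("AC-T", "ACGT") == 0.0  # 3 comparable sites, 0 diffs

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            bc.p_distance("NN--", "ACGT")

    def test_unequal_lengths(self):
        with pytest.raises(ValidationError):
            bc.p_distance("ACGT", "ACG")


class TestK2PDistance:
    def test_zero(self):
        assert bc.k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_one_transition_in_100(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert bc.k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.98), abs=1e-15)
        assert bc.k2p_distance(a, b) == pytest.approx(0.01010, abs=5e-6)

    def test_pure_transversion_formula(self):
        # 2 transversions in 10 sites: P=0, Q=0.2
        a = "AAAAAAAAAA"
        b = "CCAAAAAAAA"
        expected = -0.5 * math.log(1 - 0.2) - 0.25 * math.log(1 - 0.4)
        assert bc.k2p_distance(a, b) == pytest.approx(expected, abs=1e-15)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            bc.k2p_distance("AAAA", "GGGG")  # P=1

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_metric_sanity(self, data):
        a = data.draw(seq_with_gaps)
        b = data.draw(st.text(alphabet="ACGTN-", min_size=len(a), max_size=len(a)))
        try:
            p = bc.p_distance(a, b)
            k = bc.k2p_distance(a, b)
        except (UndefinedDistanceError, SaturationError):
            return
        assert bc.p_distance(b, a) == p  # symmetry
        assert 0.0 <= p <= 1.0
        assert k >= p - 1e-12  # correction only stretches


def test_matrix_matches_scalar(sequences):
    aln, _ = sequences
    sub = bc.AlignedSequences(aln.ids[:8], aln.seqs[:8])
    dm = bc.distance_matrix(sub, "k2p")
    for i, j in itertools.combinations(range(8), 2):
        assert dm.values[i, j] == pytest.approx(
            bc.k2p_distance(sub.seqs[i], sub.seqs[j]), abs=1e-12
        )


# ---------------------------------------------------------------------------
# haplotypes and summaries

class TestCollapse:
    def test_identical_sequences_collapse(self):
        aln = bc.AlignedSequences(["x1", "x2", "x3"], ["ACGT"] * 3)
        part = {"x1": "a", "x2": "a", "x3": "a"}
        collapsed, mult, new_part = bc.collapse_haplotypes(aln, part)
        assert collapsed.ids == ["x1"]
        assert mult == {"x1": 3}
        assert new_part == {"x1": "a"}

    def test_species_boundary_respected(self):
        aln = bc.AlignedSequences(["x1", "y1"], ["ACGT", "ACGT"])
        collapsed, mult, _ = bc.collapse_haplotypes(aln, {"x1": "a", "y1": "b"})
        assert len(collapsed) == 2

    def test_ambiguity_tolerant(self):
        aln = bc.AlignedSequences(["x1", "x2"], ["ACGT", "ACNT"])
        collapsed, mult, _ = bc.collapse_haplotypes(aln, {"x1": "a", "x2": "a"})
        assert collapsed.ids == ["x1"]

    def test_zero_polymorphism_one_haplotype_per_species(self):
        scen = Scenario(
            species=[make_species("a", diag={2: "T"}), make_species("b", diag={7: "C"})],
            n_per_species=[5, 4],
            ancestor_seq="ACGA" * 25,
            seed=3,
        )
        aln, part = gen_sequences(scen)
        collapsed, mult, _ = bc.collapse_haplotypes(aln, part)
        assert len(collapsed) == 2
        assert sorted(mult.values()) == [4, 5]

    def test_collapsing_preserves_distinct_intra_distances(self, sequences):
        aln, part = sequences
        collapsed, _, new_part = bc.collapse_haplotypes(aln, part)

        def intra_values(a, p):
            vals = set()
            for i, j in itertools.combinations(range(len(a)), 2):
                if p[a.ids[i]] == p[a.ids[j]]:
                    vals.add(round(bc.p_distance(a.seqs[i], a.seqs[j]), 12))
            return vals

        before = intra_values(aln, part) - {0.0}
        after = intra_values(collapsed, new_part) - {0.0}
        assert after == before


class TestDistanceSummary:
    def test_identical_pairs_zero_intra(self):
        aln = bc.AlignedSequences(["a1", "a2", "b1", "b2"],
                                  ["ACGT", "ACGT", "TGCA", "TGCA"])
        part = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        out = bc.distance_summary(aln, part, "p")
        assert (out.intra["mean"] == 0.0).all()

    def test_worked_two_plus_two_example(self):
        # hand-enumerated p distances over 4 sites
        aln = bc.AlignedSequences(
            ["a1", "a2", "b1", "b2"],
            ["AAAA", "AAAT", "GGAA", "GGAT"],
        )
        part = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        out = bc.distance_summary(aln, part, "p")
        intra = out.intra.set_index("species")
        assert intra.loc["a", "mean"] == pytest.approx(0.25)  # 1 diff / 4
        assert intra.loc["b", "mean"] == pytest.approx(0.25)
        inter = out.inter.iloc[0]
        # pairs: a1-b1 2/4, a1-b2 3/4, a2-b1 3/4, a2-b2 2/4
        assert inter["n_pairs"] == 4
        assert inter["mean"] == pytest.approx((0.5 + 0.75 + 0.75 + 0.5) / 4)
        assert inter["min"] == pytest.approx(0.5)
        assert inter["max"] == pytest.approx(0.75)
        expected_se = np.std([0.5, 0.75, 0.75, 0.5], ddof=1) / 2.0
        assert inter["se"] == pytest.approx(expected_se)

    def test_relabeling_symmetry(self, sequences):
        aln, part = sequences
        swapped = {k: {"sp_A": "sp_B", "sp_B": "sp_A"}.get(v, v) for k, v in part.items()}
        a = bc.distance_summary(aln, part, "k2p")
        b = bc.distance_summary(aln, swapped, "k2p")
        assert sorted(a.intra["mean"].round(12)) == sorted(b.intra["mean"].round(12))
        assert sorted(a.inter["mean"].round(12)) == sorted(b.inter["mean"].round(12))


class TestBarcodeGap:
    def test_planted_gap(self, sequences):
        aln, part = sequences
        result = bc.barcode_gap(aln, part, "k2p")
        assert result.gap
        assert result.max_intra < result.min_inter

    def test_duplicated_species_no_gap(self):
        seqs = ["ACGTACGT", "ACGAACGT", "ACGTACGT", "ACGAACGT"]
        aln = bc.AlignedSequences(["x1", "x2", "y1", "y2"], seqs)
        part = {"x1": "a", "x2": "a", "y1": "b", "y2": "b"}
        result = bc.barcode_gap(aln, part, "p")
        assert result.min_inter == 0.0
        assert not result.gap

    def test_extremes_attained_by_reported_pairs(self, sequences):
        aln, part = sequences
        result = bc.barcode_gap(aln, part, "p")
        lookup = dict(zip(aln.ids, aln.seqs))
        i, j = result.max_intra_pair
        assert part[i] == part[j]
        assert bc.p_distance(lookup[i], lookup[j]) == pytest.approx(result.max_intra)
        i, j = result.min_inter_pair
        assert part[i] != part[j]
        assert bc.p_distance(lookup[i], lookup[j]) == pytest.approx(result.min_inter)
        # brute-force scan confirms the extremes
        best_intra, best_inter = -1.0, np.inf
        for x, y in itertools.combinations(aln.ids, 2):
            d = bc.p_distance(lookup[x], lookup[y])
            if part[x] == part[y]:
                best_intra = max(best_intra, d)
            else:
                best_inter = min(best_inter, d)
        assert best_intra == pytest.approx(result.max_intra)
        assert best_inter == pytest.approx(result.min_inter)


# ---------------------------------------------------------------------------
# neighbour joining

def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with uniform branch lengths in [0.1, 1].

    Returns (distance matrix dict, set of canonical bipartitions,
    dict bipartition -> internal branch length, dict leaf -> pendant length).
    Built by sequential leaf attachment; distances via path lengths.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> {neighbor: length}; leaves are labels, internals ints
    adj: dict = {}
    nxt = [0]

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def new_internal():
        nxt[0] += 1
        return -nxt[0]

    connect(labels[0], labels[1], rng.uniform(0.2, 2.0))
    for leaf in labels[2:]:
        # pick a random existing edge, split it with a new internal node
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = new_internal()
        alpha = rng.uniform(0.3, 0.7)
        connect(u, mid, w * alpha)
        connect(mid, v, w * (1 - alpha))
        connect(mid, leaf, rng.uniform(0.1, 1.0))

    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    dm = {l: paths_from(l) for l in labels}
    all_leaves = frozenset(labels)

    splits = {}
    pendants = {}
    for u in adj:
        for v in adj[u]:
            if isinstance(u, str) and u in labels:
                pendants[u] = adj[u][v]
        if not isinstance(u, str):
            for v in adj[u]:
                if isinstance(v, str) or str(u) >= str(v):
                    continue
            # collect leaves on each side of edge (u, v) for internal-internal edges
    for u in adj:
        for v in adj[u]:
            if isinstance(u, str) or isinstance(v, str):
                continue
            if u >= v:
                continue
            side = set()
            stack = [(v, u)]
            while stack:
                node, parent = stack.pop()
                for nb in adj[node]:
                    if nb == parent:
                        continue
                    if isinstance(nb, str):
                        side.add(nb)
                    else:
                        stack.append((nb, node))
            side = frozenset(side)
            if 1 < len(side) < n_taxa - 1:
                canon = side if "t0" not in side else all_leaves - side
                splits[canon] = adj[u][v]
    return labels, dm, splits, pendants


def tree_pendant_lengths(tree: bc.Tree) -> dict[str, float]:
    out = {}

    def walk(node):
        for child, length in node.children:
            if child.is_leaf():
                out[child.name] = length
            else:
                walk(child)

    walk(tree.root)
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = bc.nj_tree(bc.DistanceMatrix(["a", "b", "c"], d))
        lengths = tree_pendant_lengths(tree)
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)): d(a,b)=3, d(a,c)=5, d(a,d)=6, ...
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = bc.nj_tree(bc.DistanceMatrix(["a", "b", "c", "d"], d))
        splits = tree.bipartitions()
        assert len(splits) == 1
        (split, length), = splits.items()
        assert split == frozenset({"c", "d"})
        assert length == pytest.approx(1.0, abs=1e-12)
        lengths = tree_pendant_lengths(tree)
        for leaf, expected in zip("abcd", [1, 2, 3, 4]):
            assert lengths[leaf] == pytest.approx(expected, abs=1e-12)

    def test_input_order_invariance(self, rng):
        labels, dmap, splits, _ = random_additive_tree(rng, 7)
        mat = np.array([[dmap[i][j] for j in labels] for i in labels])
        t1 = bc.nj_tree(bc.DistanceMatrix(labels, mat))
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        mat2 = np.array([[dmap[i][j] for j in labels2] for i in labels2])
        t2 = bc.nj_tree(bc.DistanceMatrix(labels2, mat2))
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_validation(self):
        with pytest.raises(ValidationError):
            bc.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            bc.DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(InsufficientDataError):
            bc.nj_tree(bc.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_round_trips_via_dendropy(self, sequences):
        aln, _ = sequences
        sub = bc.AlignedSequences(aln.ids[:10], aln.seqs[:10])
        tree = bc.nj_from_alignment(sub, "k2p")
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True)
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(sub.ids)
        parsed.encode_bipartitions()
        internal = {
            frozenset(b.leafset_taxa(parsed.taxon_namespace))
            for b in parsed.bipartition_encoding
        }
        # every bipartition of ours appears in the parsed tree
        for split in tree.bipartitions():
            names = {t.label for t in parsed.taxon_namespace}
            assert any(
                {t.label for t in side} in (set(split), names - set(split))
                for side in internal
            )


class TestBootstrap:
    def test_supports_bounded(self, sequences):
        aln, part = sequences
        sub_ids = aln.ids[::3]
        sub = bc.AlignedSequences(sub_ids, [aln.seqs[aln.ids.index(i)] for i in sub_ids])
        result = bc.bootstrap_support(sub, n_reps=20, seed=0)
        assert all(0.0 <= v <= 100.0 for v in result.supports.values())

    def test_single_replicate_degenerate_supports(self, sequences):
        aln, part = sequences
        sub = bc.AlignedSequences(aln.ids[:6], aln.seqs[:6])
        result = bc.bootstrap_support(sub, n_reps=1, seed=1)
        assert set(result.supports.values()) <= {0.0, 100.0}

    def test_planted_species_clades_recovered(self, sequences):
        aln, part = sequences
        result = bc.bootstrap_support(aln, n_reps=50, seed=2,
                                      partition=part, collapse=True)
        hap_part = {i: part[i] for i in result.tree.leaf_names()}
        leaves = frozenset(result.tree.leaf_names())
        for sp in ("sp_A", "sp_B", "sp_C"):
            members = frozenset(i for i in leaves if hap_part[i] == sp)
            if 1 < len(members) < len(leaves) - 1:
                split = bc._canonical_split(members, leaves)
                assert result.supports[split] >= 95.0


# ---------------------------------------------------------------------------
# diagnostics

def brute_force_diagnostics(aln, partition):
    species = sorted(set(partition.values()))
    out = {s: {} for s in species}
    for pos in range(aln.length):
        column = {sid: seq[pos] for sid, seq in zip(aln.ids, aln.seqs)}
        for s in species:
            own = {column[i] for i in aln.ids if partition[i] == s} & set("ACGT")
            other = {column[i] for i in aln.ids if partition[i] != s} & set("ACGT")
            if len(own) == 1 and not own & other:
                out[s][pos + 1] = next(iter(own))
    return out


class TestDiagnostics:
    def test_planted_map_recovered_exactly(self):
        # three species: a diagnostic site of one species leaves the other
        # two sharing the ancestral state, so recovered == planted exactly
        ancestor = "ACGG" * 25
        diag_a = {2: "T", 40: "C", 90: "C"}   # ancestor G, A, G there
        diag_b = {11: "A", 63: "T"}           # ancestor G, G
        scen = Scenario(
            species=[
                make_species("a", diag=diag_a),
                make_species("b", diag=diag_b),
                make_species("c"),
            ],
            n_per_species=[4, 4, 4],
            ancestor_seq=ancestor,
            seed=5,
        )
        for model in scen.species:
            for pos, state in model.diag_positions.items():
                assert ancestor[pos] != state
        aln, part = gen_sequences(scen)
        table = bc.pure_diagnostic_characters(aln, part)
        assert table.pure["a"] == {p + 1: s for p, s in diag_a.items()}
        assert table.pure["b"] == {p + 1: s for p, s in diag_b.items()}
        assert table.pure["c"] == {}

    def test_polymorphic_position_not_pure(self):
        aln = bc.AlignedSequences(
            ["a1", "a2", "b1"],
            ["AAAA", "AAAT", "GCCC"],
        )
        part = {"a1": "a", "a2": "a", "b1": "b"}
        table = bc.pure_diagnostic_characters(aln, part)
        assert 4 not in table.pure["a"]  # species a has T/A at position 4
        # with two species, every fixed difference is pure for both sides
        assert table.pure["a"] == {1: "A", 2: "A", 3: "A"}

    def test_shared_state_pure_for_neither(self):
        aln = bc.AlignedSequences(["a1", "b1", "c1"], ["A", "A", "G"])
        part = {"a1": "a", "b1": "b", "c1": "c"}
        table = bc.pure_diagnostic_characters(aln, part)
        assert 1 not in table.pure["a"]
        assert 1 not in table.pure["b"]
        assert table.pure["c"] == {1: "G"}

    def test_matches_brute_force_scan(self, sequences):
        aln, part = sequences
        assert bc.pure_diagnostic_characters(aln, part).pure == \
            brute_force_diagnostics(aln, part)

    def test_context_reports_polymorphic_states(self):
        aln = bc.AlignedSequences(["a1", "a2", "b1"], ["T", "G", "C"])
        part = {"a1": "a", "a2": "a", "b1": "b"}
        table = bc.pure_diagnostic_characters(aln, part)
        row = table.table[(table.table["position"] == 1) & (table.table["species"] == "a")]
        assert row.iloc[0]["states"] == "G/T"
        assert not row.iloc[0]["is_pure"]
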