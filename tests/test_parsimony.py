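"""Parsimony engine: exact lengths against brute-force enumeration and
DendroPy's Fitch pass, CI/RI, search, constraints, consensus, pruning."""

import itertools

import numpy as np
import pytest

from sutura.charmatrix import MISSING, CharacterMatrix
from sutura.parsimony import (
    char_length,
    char_min_length,
    char_star_length,
    exhaustive_search,
    heuristic_search,
    prune_taxa,
    satisfies_constraint,
    strict_consensus,
    tree_length,
)
from sutura.simulate import random_tree, simulate_characters
from sutura.trees import Tree


def brute_force_length(tree, column, ordered):
    """Enumerate all internal-node assignments (and leaf choices for
    polymorphic/missing cells); the certain minimum."""
    labels = tree.labels
    internal = [u for u in tree.adj if u not in tree.leaf_label]
    observed = sorted(
        set().union(*[column[l] for l in labels if isinstance(column[l], frozenset)])
    )
    leaf_options = [
        sorted(column[l]) if isinstance(column[l], frozenset) else observed
        for l in labels
    ]
    best = None
    for assign in itertools.product(observed, repeat=len(internal)):
        amap = dict(zip(internal, assign))
        for choice in itertools.product(*leaf_options):
            lmap = dict(zip(labels, choice))
            total = 0
            for u, v in tree.edges():
                su = amap[u] if u in amap else lmap[tree.leaf_label[u]]
                sv = amap[v] if v in amap else lmap[tree.leaf_label[v]]
                total += abs(su - sv) if ordered else int(su != sv)
            best = total if best is None else min(best, total)
    return best


class TestCharLength:
    def test_single_change_on_matching_split(self):
        t = Tree.from_newick("((A,B),(C,D));")
        col = {"A": frozenset({0}), "B": frozenset({0}),
               "C": frozenset({1}), "D": frozenset({1})}
        assert char_length(t, col, ordered=False) == 1

    def test_two_leaf_ordered_distance(self):
        t = Tree()
        a, b = t.new_node("A"), t.new_node("B")
        t.add_edge(a, b)
        assert char_length(t, {"A": frozenset({0}), "B": frozenset({2})},
                           ordered=True) == 2

    def test_missing_leaf_entry_raises(self):
        t = Tree.from_newick("((A,B),(C,D));")
        with pytest.raises(KeyError):
            char_length(t, {"A": frozenset({0})}, ordered=False)

    def test_matches_exhaustive_assignment_oracle(self):
        """100 random instances, up to 6 leaves, 3-4 states, with missing
        and polymorphic cells, unordered and ordered."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 7))
            n_states = int(rng.integers(3, 5))
            tree = random_tree(n, int(rng.integers(1 << 30)))
            col = {}
            for lab in tree.labels:
                r = rng.random()
                if r < 0.15:
                    col[lab] = MISSING
                elif r < 0.30:
                    col[lab] = frozenset(
                        int(s) for s in rng.choice(n_states, size=2, replace=False)
                    )
                else:
                    col[lab] = frozenset({int(rng.integers(n_states))})
            if not any(isinstance(c, frozenset) for c in col.values()):
                continue
            for ordered in (False, True):
                assert char_length(tree, col, ordered) == brute_force_length(
                    tree, col, ordered
                )

    def test_rooting_and_leaf_order_invariance(self):
        rng = np.random.default_rng(3)
        tree = random_tree(6, 17)
        col = {lab: frozenset({int(rng.integers(3))}) for lab in tree.labels}
        want = char_length(tree, col, ordered=False)
        # re-read the newick (different node numbering / rooting)
        reread = Tree.from_newick(tree.newick())
        assert char_length(reread, col, ordered=False) == want

    def test_cross_check_against_dendropy_fitch(self):
        """Unordered lengths agree with DendroPy's Fitch down-pass."""
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(9)
        for rep in range(10):
            tree = random_tree(6, 50 + rep)
            matrix = simulate_characters(tree, n_chars=10, n_states=3,
                                         rate=0.8, seed=60 + rep)
            scored = random_tree(6, 70 + rep)  # score on a different topology
            mine = tree_length(scored, matrix).total

            ns = dendropy.TaxonNamespace(sorted(scored.labels))
            dtree = scored.to_dendropy(ns)
            dtree.is_rooted = False
            chars = dendropy.StandardCharacterMatrix.get(
                data=_to_nexus(matrix), schema="nexus", taxon_namespace=ns
            )
            tsm = chars.taxon_state_sets_map(gaps_as_missing=True)
            length = fitch_down_pass(dtree.postorder_node_iter(),
                                     taxon_state_sets_map=tsm)
            assert mine == length

    def test_adding_missing_only_taxon_keeps_optimal_length(self):
        tree = random_tree(6, 21)
        matrix = simulate_characters(tree, n_chars=12, n_states=3, rate=0.6,
                                     seed=22)
        best, _ = exhaustive_search(matrix)
        extended = CharacterMatrix(
            taxa=matrix.taxa + ["blank"],
            characters=list(matrix.characters),
            rows={**{t: list(r) for t, r in matrix.rows.items()},
                  "blank": [MISSING] * matrix.n_characters},
            ordered=list(matrix.ordered),
        )
        best2, _ = exhaustive_search(extended)
        assert best2 == best


def _to_nexus(matrix) -> str:
    lines = ["#NEXUS", "BEGIN DATA;",
             f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
             'FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
             "MATRIX"]
    for t in matrix.taxa:
        row = "".join(
            "?" if c == MISSING else "-" if c == "-" else
            ("".join(str(s) for s in sorted(c)) if len(c) == 1
             else "{" + "".join(str(s) for s in sorted(c)) + "}")
            for c in matrix.rows[t]
        )
        lines.append(f"{t}  {row}")
    lines += [";", "END;"]
    return "\n".join(lines)


class TestLengthReport:
    def test_all_constant_matrix(self):
        tree = random_tree(4, 2)
        m = CharacterMatrix(
            taxa=tree.labels, characters=["1", "2"],
            rows={t: [frozenset({0}), frozenset({1})] for t in tree.labels},
        )
        rep = tree_length(tree, m)
        assert rep.total == 0 and rep.ci is None and rep.ri is None

    def test_ci_one_on_perfect_fit(self):
        tree = random_tree(8, 30)
        matrix = simulate_characters(tree, n_chars=15, n_states=2, rate=0.15,
                                     seed=31)
        best, trees = heuristic_search(matrix, n_replicates=3, seed=32)
        rep = tree_length(trees[0], matrix)
        assert rep.total == best
        total_min = sum(rep.per_char_min)
        if best == total_min:  # zero homoplasy
            assert rep.ci == 1.0

    def test_hand_computed_homoplasy_case(self):
        # five taxa; char 1 fits the tree (m=1, s=1, g=2);
        # char 2 is homoplastic on this tree (m=1, s=2, g=2)
        tree = Tree.from_newick("((A,B),(C,(D,E)));")
        rows = {
            "A": [frozenset({0}), frozenset({0})],
            "B": [frozenset({0}), frozenset({1})],
            "C": [frozenset({1}), frozenset({0})],
            "D": [frozenset({1}), frozenset({1})],
            "E": [frozenset({1}), frozenset({0})],
        }
        m = CharacterMatrix(taxa=list("ABCDE"), characters=["1", "2"], rows=rows)
        rep = tree_length(tree, m)
        assert rep.per_char_steps == [1, 2]
        assert rep.per_char_min == [1, 1]
        assert rep.per_char_max == [2, 2]
        assert rep.total == 3
        assert rep.ci == pytest.approx(2 / 3)
        assert rep.ri == pytest.approx((4 - 3) / (4 - 2))

    def test_bounds_min_length_star(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            cells = []
            for _ in range(6):
                r = rng.random()
                if r < 0.2:
                    cells.append(MISSING)
                elif r < 0.35:
                    cells.append(frozenset(
                        int(s) for s in rng.choice(4, size=2, replace=False)))
                else:
                    cells.append(frozenset({int(rng.integers(4))}))
            tree = random_tree(6, int(rng.integers(1 << 30)))
            col = dict(zip(tree.labels, cells))
            for ordered in (False, True):
                m = char_min_length(cells, ordered)
                g = char_star_length(cells, ordered)
                s = char_length(tree, col, ordered)
                assert m <= s <= g


class TestSearch:
    def test_exhaustive_four_taxa_groups_the_zeros(self):
        m = CharacterMatrix(
            taxa=list("ABCD"), characters=["1"],
            rows={"A": [frozenset({0})], "B": [frozenset({0})],
                  "C": [frozenset({1})], "D": [frozenset({1})]},
        )
        best, trees = exhaustive_search(m)
        assert best == 1 and len(trees) == 1
        assert frozenset({"C", "D"}) in trees[0].bipartitions()

    def test_exhaustive_three_taxa_single_topology(self):
        m = CharacterMatrix(
            taxa=list("ABC"), characters=["1"],
            rows={"A": [frozenset({0})], "B": [frozenset({1})],
                  "C": [frozenset({1})]},
        )
        _, trees = exhaustive_search(m)
        assert len(trees) == 1

    def test_exhaustive_refuses_large_problems(self):
        tree = random_tree(10, 1)
        m = simulate_characters(tree, n_chars=5, seed=1)
        with pytest.raises(ValueError):
            exhaustive_search(m)

    def test_heuristic_matches_exhaustive(self):
        """On simulated 7-taxon matrices the heuristic finds the global
        optimum in (nearly) every case."""
        hits = 0
        n = 15
        for rep in range(n):
            tree = random_tree(7, 500 + rep)
            matrix = simulate_characters(tree, n_chars=20, n_states=3,
                                         rate=0.5, p_ordered=0.3,
                                         seed=600 + rep)
            best_ex, _ = exhaustive_search(matrix)
            best_h, trees = heuristic_search(matrix, n_replicates=5,
                                             seed=700 + rep)
            assert best_h >= best_ex
            hits += best_h == best_ex
            assert all(tree_length(t, matrix).total == best_h for t in trees[:2])
        assert hits >= 0.95 * n

    def test_clean_signal_recovers_generating_tree(self):
        """A matrix built from a tree's own bipartitions (one binary
        character per internal edge) is homoplasy-free; the search must
        recover that tree at length = number of informative characters."""
        tree = random_tree(8, 900)
        splits = sorted(tree.bipartitions(), key=sorted)
        rows = {
            lab: [frozenset({1 if lab in bp else 0}) for bp in splits]
            for lab in tree.labels
        }
        matrix = CharacterMatrix(
            taxa=tree.labels,
            characters=[str(j + 1) for j in range(len(splits))],
            rows=rows,
        )
        best, trees = heuristic_search(matrix, n_replicates=4, seed=902)
        assert best == len(splits) == sum(
            char_min_length([matrix.cell(t, j + 1) for t in matrix.taxa], False)
            for j in range(matrix.n_characters)
        )
        assert tree in trees

    def test_same_seed_same_tree_set(self):
        tree = random_tree(8, 910)
        matrix = simulate_characters(tree, n_chars=15, n_states=3, rate=0.6,
                                     seed=911)
        r1 = heuristic_search(matrix, n_replicates=4, seed=5)
        r2 = heuristic_search(matrix, n_replicates=4, seed=5)
        assert r1[0] == r2[0]
        assert {frozenset(t.bipartitions()) for t in r1[1]} == {
            frozenset(t.bipartitions()) for t in r2[1]
        }


class TestConstraint:
    def test_same_tree_satisfies_itself(self):
        t = Tree.from_newick("((A,B),(C,D));")
        assert satisfies_constraint(t, t)

    def test_contradicted_bipartition(self):
        constraint = Tree.from_newick("((A,B),(C,D));")
        tree = Tree.from_newick("((A,C),(B,D));")
        assert not satisfies_constraint(tree, constraint)

    def test_star_constraint_always_satisfied(self):
        star = Tree()
        hub = star.new_node()
        for lab in "ABCD":
            star.add_edge(hub, star.new_node(lab))
        tree = Tree.from_newick("((A,C),(B,D));")
        assert satisfies_constraint(tree, star)

    def test_backbone_floaters_attach_anywhere(self):
        constraint = Tree.from_newick("((A,B),(C,D));")
        tree = Tree.from_newick("(((A,X),B),((C,Y),D));")
        assert satisfies_constraint(tree, constraint)

    def test_search_output_honours_constraint(self):
        gen = random_tree(7, 40)
        matrix = simulate_characters(gen, n_chars=15, n_states=3, rate=0.6,
                                     seed=41)
        # constrain against the data: force t1+t2 together
        constraint = Tree.from_newick("((t1,t2),(t3,t4));")
        best, trees = heuristic_search(matrix, n_replicates=4, seed=42,
                                       constraint=constraint)
        assert trees
        for t in trees:
            assert satisfies_constraint(t, constraint)
        best_free, _ = heuristic_search(matrix, n_replicates=4, seed=42)
        assert best >= best_free


class TestConsensusAndPruning:
    def test_identical_trees_consensus_is_that_tree(self):
        t = Tree.from_newick("((A,B),(C,(D,E)));")
        assert strict_consensus([t, t.copy()]) == t

    def test_no_shared_bipartition_gives_star(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        t3 = Tree.from_newick("((A,D),(B,C));")
        cons = strict_consensus([t1, t2, t3])
        assert cons.bipartitions() == set()

    def test_single_collapsed_node(self):
        # trees differ only in how (C,D,E) is resolved; the consensus must
        # keep {CDE}, {FG} and the AB|CDEFG split (canonical: non-A side)
        # and collapse exactly the conflicting node
        base = "((A,B),((C,D),E),(F,G));"
        alt = "((A,B),(C,(D,E)),(F,G));"
        cons = strict_consensus([Tree.from_newick(base), Tree.from_newick(alt)])
        want = {frozenset("CDE"), frozenset("FG"), frozenset("CDEFG")}
        assert cons.bipartitions() == want

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError):
            strict_consensus([Tree.from_newick("((A,B),(C,D));"),
                              Tree.from_newick("((A,B),(C,E));")])

    def test_prune_one_leaf(self):
        t = Tree.from_newick("((A,B),(C,(D,E)));")
        pruned = prune_taxa(t, ["E"])
        assert sorted(pruned.labels) == ["A", "B", "C", "D"]
        assert pruned.is_binary()

    def test_prune_none_identity(self):
        t = Tree.from_newick("((A,B),(C,D));")
        assert prune_taxa(t, []) == t

    def test_prune_agrees_with_restriction(self):
        t = random_tree(8, 77)
        keep = t.labels[:5]
        drop = t.labels[5:]
        assert prune_taxa(t, drop).bipartitions() == t.restricted(keep).bipartitions()
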