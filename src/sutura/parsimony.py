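"""Maximum-parsimony scoring and search for discrete morphological data.

Tree length is the minimum number of character-state changes a topology
requires.  Unordered characters cost one step per change (Fitch sets);
ordered (morphocline) characters cost ``|i - j|`` steps for a change from
state *i* to *j* (a Sankoff pass with linear costs).  Missing and gap
cells never force changes; polymorphic cells are ambiguity sets whose
members are free to the leaf.

On top of the length function sit the consistency index CI = Σm/L and the
retention index RI = (Σg − L)/(Σg − Σm), where m is the smallest length
any tree allows a character and g its length on a star tree; an exhaustive
enumerator over all unrooted binary topologies (small problems only); a
random-addition + tree-bisection-reconnection (TBR) heuristic that can
honour a backbone constraint; strict consensus; and taxon pruning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .charmatrix import GAP, MISSING, CharacterMatrix
from .trees import Tree

__all__ = [
    "LengthReport",
    "char_length",
    "char_min_length",
    "char_star_length",
    "tree_length",
    "exhaustive_search",
    "heuristic_search",
    "satisfies_constraint",
    "strict_consensus",
    "prune_taxa",
    "ConstraintInfeasibleError",
]

_MAX_STATES = 10


class ConstraintInfeasibleError(RuntimeError):
    """No tree compatible with the backbone constraint could be built."""


# ---------------------------------------------------------------------------
# column preparation

def _cell_states(cell) -> Optional[frozenset]:
    """States a leaf may take for free; None = unconstrained (missing/gap)."""
    if isinstance(cell, frozenset):
        return cell
    if cell is None or cell == MISSING or cell == GAP:
        return None
    return frozenset(cell)


def _column_cells(column: Dict[str, object], labels: Sequence[str]) -> list:
    cells = []
    for label in labels:
        if label not in column:
            raise KeyError(f"leaf {label!r} has no entry in the character column")
        cells.append(_cell_states(column[label]))
    return cells


def _observed_states(cells: Iterable[Optional[frozenset]]) -> frozenset:
    out = set()
    for cell in cells:
        if cell is not None:
            out |= cell
    return frozenset(out)


# ---------------------------------------------------------------------------
# single-column length

def char_length(tree: Tree, column: Dict[str, object], ordered: bool = False) -> int:
    """Minimum number of state changes ``column`` requires on ``tree``.

    ``column`` maps each leaf label to a cell: a set of states (singleton
    or polymorphic), or MISSING/GAP.  The result is independent of where
    the tree is rooted for the traversal.
    """
    labels = tree.labels
    cells = dict(zip(labels, _column_cells(column, labels)))
    observed = _observed_states(cells.values())
    if len(observed) <= 1:
        return 0
    label_of = tree.leaf_label
    root = next((u for u in tree.adj if u not in label_of), tree.leaves[0])
    order = tree.postorder_edges(root)

    if not ordered:
        full = observed
        steps = 0
        # bottom-up Fitch: combine children into each internal node
        children: Dict[int, list] = {}
        for child, parent in order:
            children.setdefault(parent, []).append(child)
        resolved: Dict[int, frozenset] = {}

        def fitch_state(node: int) -> frozenset:
            nonlocal steps
            if node in label_of:
                cell = cells[label_of[node]]
                return cell if cell is not None else full
            state = None
            for ch in children.get(node, ()):
                s = resolved[ch]
                if state is None:
                    state = s
                else:
                    inter = state & s
                    if inter:
                        state = inter
                    else:
                        state = state | s
                        steps += 1
            return state if state is not None else full

        for child, parent in order:
            resolved[child] = fitch_state(child)
        fitch_state(root)
        return steps

    # ordered: Sankoff with linear costs over the observed state range
    lo, hi = min(observed), max(observed)
    states = list(range(lo, hi + 1))
    k = len(states)
    dist = np.abs(np.subtract.outer(states, states))
    INF = 10 ** 9
    cost: Dict[int, np.ndarray] = {}

    def leaf_cost(node: int) -> np.ndarray:
        cell = cells[label_of[node]]
        if cell is None:
            return np.zeros(k, dtype=np.int64)
        c = np.full(k, INF, dtype=np.int64)
        for s in cell:
            c[s - lo] = 0
        return c

    children: Dict[int, list] = {}
    for child, parent in order:
        children.setdefault(parent, []).append(child)

    for child, parent in order:
        if child in label_of:
            cost[child] = leaf_cost(child)
        else:
            total = np.zeros(k, dtype=np.int64)
            for ch in children.get(child, ()):
                total = total + (cost[ch][None, :] + dist).min(axis=1)
            cost[child] = total
    if root in label_of:
        root_cost = leaf_cost(root)
    else:
        root_cost = np.zeros(k, dtype=np.int64)
    for ch in children.get(root, ()):
        root_cost = root_cost + (cost[ch][None, :] + dist).min(axis=1)
    return int(root_cost.min())


def char_min_length(column_cells: Iterable, ordered: bool = False) -> int:
    """Smallest length the character can have on any tree.

    Unordered: one less than the fewest states that intersect every scored
    cell; ordered: the narrowest state window meeting every scored cell.
    """
    cells = [c for c in (_cell_states(x) for x in column_cells) if c is not None]
    observed = _observed_states(cells)
    if len(observed) <= 1 or not cells:
        return 0
    if ordered:
        best = max(observed) - min(observed)
        states = sorted(observed)
        for lo, hi in itertools.combinations_with_replacement(states, 2):
            if hi - lo < best and all(any(lo <= s <= hi for s in c) for c in cells):
                best = hi - lo
        return best
    # minimum hitting set over <= 10 states
    pool = sorted(observed)
    for k in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, k):
            chosen = set(combo)
            if all(chosen & c for c in cells):
                return k - 1
    return len(pool) - 1


def char_star_length(column_cells: Iterable, ordered: bool = False) -> int:
    """Length on a star tree: best single ancestral state against all leaves."""
    cells = [c for c in (_cell_states(x) for x in column_cells) if c is not None]
    observed = _observed_states(cells)
    if len(observed) <= 1 or not cells:
        return 0
    best = None
    for anc in observed:
        total = 0
        for cell in cells:
            if ordered:
                total += min(abs(anc - s) for s in cell)
            else:
                total += 0 if anc in cell else 1
        best = total if best is None else min(best, total)
    return int(best)


# ---------------------------------------------------------------------------
# vectorized whole-matrix scoring (used by the searches)

class _MatrixScorer:
    """Precompiled column data for fast repeated scoring of one matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.labels = [t for t in matrix.taxa if matrix.active[t]]
        self.index = {t: i for i, t in enumerate(self.labels)}
        unordered_cols: List[np.ndarray] = []
        self.ordered_cols: List[Tuple[np.ndarray, int, int]] = []
        for j in range(matrix.n_characters):
            cells = [matrix.cell(t, j + 1) for t in self.labels]
            sets = [_cell_states(c) for c in cells]
            observed = _observed_states(sets)
            if len(observed) <= 1:
                continue
            if matrix.ordered[j]:
                lo, hi = min(observed), max(observed)
                k = hi - lo + 1
                allowed = np.zeros((len(self.labels), k), dtype=bool)
                for i, s in enumerate(sets):
                    if s is None:
                        allowed[i, :] = True
                    else:
                        for st in s:
                            allowed[i, st - lo] = True
                self.ordered_cols.append((allowed, lo, hi))
            else:
                masks = np.zeros(len(self.labels), dtype=np.uint16)
                full = 0
                for st in observed:
                    full |= 1 << st
                for i, s in enumerate(sets):
                    if s is None:
                        masks[i] = full
                    else:
                        m = 0
                        for st in s:
                            m |= 1 << st
                        masks[i] = m
                unordered_cols.append(masks)
        self.unordered = (
            np.stack(unordered_cols, axis=1)
            if unordered_cols
            else np.zeros((len(self.labels), 0), dtype=np.uint16)
        )

    def length(self, tree: Tree) -> int:
        label_of = tree.leaf_label
        root = next((u for u in tree.adj if u not in label_of), tree.leaves[0])
        order = tree.postorder_edges(root)
        children: Dict[int, list] = {}
        for child, parent in order:
            children.setdefault(parent, []).append(child)

        total = 0
        ncols = self.unordered.shape[1]
        if ncols:
            steps = np.zeros(ncols, dtype=np.int64)
            state: Dict[int, np.ndarray] = {}
            for child, parent in order + [(root, None)]:
                if child in label_of:
                    state[child] = self.unordered[self.index[label_of[child]]]
                else:
                    acc = None
                    for ch in children.get(child, ()):
                        s = state[ch]
                        if acc is None:
                            acc = s
                        else:
                            inter = acc & s
                            zero = inter == 0
                            steps += zero
                            acc = np.where(zero, acc | s, inter)
                    state[child] = acc
            total += int(steps.sum())

        for allowed, lo, hi in self.ordered_cols:
            k = hi - lo + 1
            dist = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            INF = 10 ** 9
            cost: Dict[int, np.ndarray] = {}
            for child, parent in order + [(root, None)]:
                if child in label_of:
                    c = np.where(allowed[self.index[label_of[child]]], 0, INF)
                    cost[child] = c.astype(np.int64)
                else:
                    acc = np.zeros(k, dtype=np.int64)
                    for ch in children.get(child, ()):
                        acc = acc + (cost[ch][None, :] + dist).min(axis=1)
                    cost[child] = acc
            total += int(cost[root].min())
        return total


# ---------------------------------------------------------------------------
# length report

@dataclass
class LengthReport:
    """Tree length with per-character decomposition and homoplasy indices."""

    total: int
    per_char_steps: List[int]
    per_char_min: List[int]
    per_char_max: List[int]
    ci: Optional[float]
    ri: Optional[float]


def tree_length(tree: Tree, matrix: CharacterMatrix,
                exclude_uninformative: bool = False) -> LengthReport:
    """Score every character of ``matrix`` on ``tree`` and report CI/RI.

    ``exclude_uninformative`` drops parsimony-uninformative characters
    (m == g) from the index sums; the plain formulas are the default.
    """
    active = [t for t in matrix.taxa if matrix.active[t]]
    if set(active) != set(tree.labels):
        raise ValueError("tree leaves do not match the active taxa")
    steps, minima, maxima = [], [], []
    for j in range(matrix.n_characters):
        column = {t: matrix.cell(t, j + 1) for t in active}
        cells = list(column.values())
        ordered = matrix.ordered[j]
        steps.append(char_length(tree, column, ordered))
        minima.append(char_min_length(cells, ordered))
        maxima.append(char_star_length(cells, ordered))
    total = int(sum(steps))
    idx = range(len(steps))
    if exclude_uninformative:
        idx = [j for j in idx if maxima[j] > minima[j]]
    sum_m = sum(minima[j] for j in idx)
    sum_g = sum(maxima[j] for j in idx)
    length_idx = sum(steps[j] for j in idx)
    ci = sum_m / length_idx if length_idx > 0 else None
    ri = (
        (sum_g - length_idx) / (sum_g - sum_m)
        if sum_g > sum_m
        else None
    )
    return LengthReport(total, steps, minima, maxima, ci, ri)


# ---------------------------------------------------------------------------
# topology enumeration and search

def _three_leaf_tree(labels: Sequence[str]) -> Tree:
    t = Tree()
    hub = t.new_node()
    for lab in labels[:3]:
        leaf = t.new_node(lab)
        t.add_edge(hub, leaf)
    return t


def _insert_leaf(tree: Tree, label: str, edge: Tuple[int, int]) -> Tuple[int, int]:
    """Attach a new leaf in the middle of ``edge``; returns (leaf, junction)."""
    u, v = edge
    mid = tree.new_node()
    leaf = tree.new_node(label)
    tree.remove_edge(u, v)
    tree.add_edge(u, mid)
    tree.add_edge(mid, v)
    tree.add_edge(mid, leaf)
    return leaf, mid


def all_topologies(labels: Sequence[str]):
    """Yield every unrooted binary topology over ``labels`` (n <= 9)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least three taxa")

    def build(tree: Tree, remaining: List[str]):
        if not remaining:
            yield tree.copy()
            return
        label = remaining[0]
        for edge in tree.edges():
            t2 = tree.copy()
            _insert_leaf(t2, label, edge)
            yield from build(t2, remaining[1:])

    yield from build(_three_leaf_tree(labels), labels[3:])


def exhaustive_search(matrix: CharacterMatrix):
    """Global optimum by enumeration of all unrooted binary topologies."""
    active = [t for t in matrix.taxa if matrix.active[t]]
    if len(active) > 9:
        raise ValueError("exhaustive search is limited to nine active taxa")
    if len(active) < 3:
        raise ValueError("need at least three active taxa")
    scorer = _MatrixScorer(matrix)
    best_len: Optional[int] = None
    best: List[Tree] = []
    for tree in all_topologies(active):
        length = scorer.length(tree)
        if best_len is None or length < best_len:
            best_len = length
            best = [tree]
        elif length == best_len:
            best.append(tree)
    return best_len, best


def satisfies_constraint(tree: Tree, constraint: Optional[Tree]) -> bool:
    """Backbone semantics: the tree restricted to the constraint's taxa must
    display every bipartition of the constraint; other taxa float freely."""
    if constraint is None:
        return True
    wanted = constraint.bipartitions()
    if not wanted:
        return True
    shared = set(constraint.labels) & set(tree.labels)
    relevant = {
        bp & frozenset(shared)
        for bp in wanted
        if len(bp & frozenset(shared)) >= 2 and len(shared - bp) >= 2
    }
    relevant = {bp for bp in relevant if bp}
    if not relevant:
        return True
    if len(shared) < 4:
        return True
    restricted = tree.restricted(shared)
    have = restricted.bipartitions()
    # re-canonicalize the wanted splits against the restricted leaf set
    ref = min(restricted.labels)
    canon = set()
    for bp in relevant:
        canon.add(frozenset(shared) - bp if ref in bp else bp)
    return canon <= have


def _tbr_neighbors(tree: Tree):
    """Yield TBR rearrangements (deduplicated by topology)."""
    seen = set()
    for u, v in tree.edges():
        work = tree.copy()
        work.remove_edge(u, v)
        side_u = work.component(u)
        work_u = work
        for node in (u, v):
            work_u.suppress_degree_two(node)
        part_u = {n for n in side_u if n in work_u.adj}
        part_v = set(work_u.adj) - part_u
        edges_u = [e for e in work_u.edges() if e[0] in part_u and e[1] in part_u]
        edges_v = [e for e in work_u.edges() if e[0] in part_v and e[1] in part_v]
        att_u = edges_u or [None]
        att_v = edges_v or [None]
        for ea in att_u:
            for eb in att_v:
                cand = work_u.copy()
                if ea is None:
                    # single node on the u side
                    (node_a,) = [n for n in part_u]
                    pa = node_a
                else:
                    a1, a2 = ea
                    pa = cand.new_node()
                    cand.remove_edge(a1, a2)
                    cand.add_edge(a1, pa)
                    cand.add_edge(pa, a2)
                if eb is None:
                    (node_b,) = [n for n in part_v]
                    pb = node_b
                else:
                    b1, b2 = eb
                    pb = cand.new_node()
                    cand.remove_edge(b1, b2)
                    cand.add_edge(b1, pb)
                    cand.add_edge(pb, b2)
                cand.add_edge(pa, pb)
                if not cand.is_binary():
                    continue
                key = frozenset(cand.bipartitions())
                if key in seen:
                    continue
                seen.add(key)
                yield cand


def _random_addition_tree(
    scorer: _MatrixScorer,
    labels: Sequence[str],
    rng: np.random.Generator,
    constraint: Optional[Tree],
) -> Tree:
    order = list(labels)
    rng.shuffle(order)
    tree = _three_leaf_tree(order[:3])
    for label in order[3:]:
        candidates = []
        for edge in tree.edges():
            t2 = tree.copy()
            _insert_leaf(t2, label, edge)
            if constraint is not None and not satisfies_constraint(t2, constraint):
                continue
            candidates.append((scorer.length(t2), t2))
        if not candidates:
            raise ConstraintInfeasibleError(
                f"no constraint-compatible placement for {label!r}"
            )
        best = min(c[0] for c in candidates)
        pool = [t for score, t in candidates if score == best]
        tree = pool[rng.integers(len(pool))]
    if constraint is not None and not satisfies_constraint(tree, constraint):
        raise ConstraintInfeasibleError("addition produced a violating tree")
    return tree


def heuristic_search(
    matrix: CharacterMatrix,
    n_replicates: int = 10,
    seed: int = 0,
    constraint: Optional[Tree] = None,
):
    """Random-addition-sequence starts refined by TBR branch swapping.

    Each replicate builds a starting tree by greedy random addition, then
    applies TBR moves, taking any strictly shorter rearrangement until a
    local optimum is reached; trees violating the backbone constraint are
    never accepted.  Equal-length optima encountered at the final plateau
    are pooled across replicates and deduplicated by topology.
    """
    active = [t for t in matrix.taxa if matrix.active[t]]
    if len(active) < 4:
        raise ValueError("heuristic search needs at least four active taxa")
    if constraint is not None:
        extra = set(constraint.labels) - set(active)
        if extra:
            raise ValueError(f"constraint taxa not in matrix: {sorted(extra)}")
    scorer = _MatrixScorer(matrix)
    rng = np.random.default_rng(seed)
    best_len: Optional[int] = None
    pool: Dict[frozenset, Tree] = {}
    for _ in range(n_replicates):
        tree = _random_addition_tree(scorer, active, rng, constraint)
        length = scorer.length(tree)
        improved = True
        while improved:
            improved = False
            for cand in _tbr_neighbors(tree):
                if constraint is not None and not satisfies_constraint(cand, constraint):
                    continue
                cand_len = scorer.length(cand)
                if cand_len < length:
                    tree, length = cand, cand_len
                    improved = True
                    break
        # pool the local optimum and its equal-length neighbors
        plateau = [tree] + [
            cand
            for cand in _tbr_neighbors(tree)
            if (constraint is None or satisfies_constraint(cand, constraint))
            and scorer.length(cand) == length
        ]
        if best_len is None or length < best_len:
            best_len = length
            pool = {}
        if length == best_len:
            for t in plateau:
                pool.setdefault(frozenset(t.bipartitions()), t)
    return best_len, list(pool.values())


# ---------------------------------------------------------------------------
# consensus and pruning

def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the bipartitions common to all inputs."""
    if not trees:
        raise ValueError("need at least one tree")
    labels = set(trees[0].labels)
    for t in trees[1:]:
        if set(t.labels) != labels:
            raise ValueError("trees have different leaf sets")
    common = set.intersection(*(set(t.bipartitions()) for t in trees))
    ordered_labels = sorted(labels)
    ref = ordered_labels[0]
    # every common split is a clade on the non-ref side; nest by containment
    clades = sorted(common, key=len)
    out = Tree()
    root = out.new_node()
    leaf_nodes = {lab: out.new_node(lab) for lab in ordered_labels}
    parent_clade: Dict[frozenset, Optional[frozenset]] = {}
    for i, clade in enumerate(clades):
        parent = None
        for other in clades[i + 1:]:
            if clade < other:
                parent = other
                break
        parent_clade[clade] = parent
    clade_nodes = {clade: out.new_node() for clade in clades}
    for clade, node in clade_nodes.items():
        parent = parent_clade[clade]
        out.add_edge(node, clade_nodes[parent] if parent else root)
    for lab in ordered_labels:
        containing = [c for c in clades if lab in c]
        if containing and lab != ref:
            smallest = min(containing, key=len)
            out.add_edge(leaf_nodes[lab], clade_nodes[smallest])
        else:
            out.add_edge(leaf_nodes[lab], root)
    out.suppress_degree_two(root)
    return out


def prune_taxa(tree: Tree, labels: Iterable[str]) -> Tree:
    """Remove the named leaves and suppress the resulting degree-2 nodes."""
    labels = list(labels)
    if not labels:
        return tree.copy()
    return tree.prune_leaves(labels)
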