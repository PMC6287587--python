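"""Synthetic data: contact tables evolved on trees, and discrete
character matrices for parsimony benchmarks.

The contact simulator emulates the categorical structure of the coding
scheme: each bone-pair contact carries a nominal spatial relation and an
ordered four-level suture depth, and evolves along a tree by three kinds
of events — presence toggles (gain/loss), spatial-relation switches, and
single-step depth moves.  Event counts per branch are Poisson with
branch-length-proportional means, the minimal model under which phenetic
similarity should decay with path length.  Depth moves are +/-1 on the
ordinal scale (clipped to [0, 3]), so two-category jumps — the threshold
at which the similarity statistic reacts — require multiple events.

The packaged study fixture is a transcription of the four-skull contact
observations; see :func:`study_fixture`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np

from .contacts import (
    BONE_VOCABULARY,
    ContactRecord,
    ContactSegment,
    ContactTable,
    SutureDepth,
    read_contact_table,
)
from .trees import Tree

__all__ = [
    "ContactEvolutionModel",
    "random_tree",
    "simulate_tables",
    "study_fixture",
    "simulate_characters",
]

_SPATIAL = ("p", "o", "u", "c", "cb", "t")


@dataclass(frozen=True)
class ContactEvolutionModel:
    """Rates (events per contact per unit branch length) and shape of the
    simulated ancestral contact table."""

    rate_spatial_switch: float = 0.3
    rate_depth_step: float = 0.3
    rate_gain_loss: float = 0.1
    n_pairs: int = 50
    p_multi_segment: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_spatial_switch", "rate_depth_step", "rate_gain_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_multi_segment <= 1:
            raise ValueError("p_multi_segment must be in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def random_tree(n_taxa: int, seed: int) -> Tree:
    """Random binary unrooted tree by sequential attachment.

    Branch lengths are Gamma(shape 2, scale 0.5) draws (mean 1), giving
    "unit-ish" branches with moderate spread.  Identical seeds give
    identical trees.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def bl() -> float:
        return float(rng.gamma(2.0, 0.5))

    tree = Tree()
    if n_taxa == 2:
        a = tree.new_node(labels[0])
        b = tree.new_node(labels[1])
        tree.add_edge(a, b, bl())
        return tree
    hub = tree.new_node()
    for lab in labels[:3]:
        tree.add_edge(hub, tree.new_node(lab), bl())
    for lab in labels[3:]:
        edges = tree.edges()
        u, v = edges[rng.integers(len(edges))]
        length = tree.edge_length(u, v)
        tree.remove_edge(u, v)
        mid = tree.new_node()
        leaf = tree.new_node(lab)
        half = length / 2.0
        tree.add_edge(u, mid, half)
        tree.add_edge(mid, v, half)
        tree.add_edge(mid, leaf, bl())
    return tree


def _random_segments(rng: np.random.Generator, p_multi: float) -> tuple:
    n_seg = 2 if rng.random() < p_multi else 1
    return tuple(
        ContactSegment(_SPATIAL[rng.integers(6)], SutureDepth(int(rng.integers(4))))
        for _ in range(n_seg)
    )


def _random_state(rng: np.random.Generator, p_multi: float) -> dict:
    if rng.random() < 0.5:
        return {"status": "present", "segments": _random_segments(rng, p_multi)}
    return {"status": "absent", "segments": ()}


def _evolve_state(state: dict, length: float, model: ContactEvolutionModel,
                  rng: np.random.Generator) -> dict:
    status = state["status"]
    segments = list(state["segments"])
    n_toggle = rng.poisson(model.rate_gain_loss * length)
    for _ in range(n_toggle):
        if status == "present":
            status, segments = "absent", []
        else:
            status = "present"
            segments = list(_random_segments(rng, model.p_multi_segment))
    if status == "present":
        n_switch = rng.poisson(model.rate_spatial_switch * length)
        for _ in range(n_switch):
            i = int(rng.integers(len(segments)))
            segments[i] = ContactSegment(
                _SPATIAL[rng.integers(6)], segments[i].depth
            )
        n_depth = rng.poisson(model.rate_depth_step * length)
        for _ in range(n_depth):
            i = int(rng.integers(len(segments)))
            level = segments[i].depth.level
            step = 1 if rng.random() < 0.5 else -1
            level = min(3, max(0, level + step))
            segments[i] = ContactSegment(segments[i].spatial, SutureDepth(level))
    else:
        segments = []
    return {"status": status, "segments": tuple(segments)}


def simulate_tables(
    tree: Tree, model: ContactEvolutionModel
) -> Tuple[ContactTable, ContactTable]:
    """Evolve a contact table along ``tree``; returns (tips, ancestor).

    The ancestral table draws each pair's status uniformly (present with a
    random segment list, or absent); states then change along each branch
    by Poisson-count events as described in the module docstring.
    """
    rng = np.random.default_rng(model.seed)
    bones = sorted(b for b in BONE_VOCABULARY if b not in ("nasal", "columella"))
    all_pairs = [
        (a, b) for i, a in enumerate(bones) for b in bones[i + 1:]
    ]
    if model.n_pairs > len(all_pairs):
        raise ValueError(f"n_pairs exceeds available bone pairs ({len(all_pairs)})")
    chosen = [all_pairs[i] for i in sorted(rng.choice(len(all_pairs),
                                                      size=model.n_pairs,
                                                      replace=False))]
    ancestor_states = {
        pair: _random_state(rng, model.p_multi_segment) for pair in chosen
    }

    root = next((u for u in tree.adj if u not in tree.leaf_label), tree.leaves[0])
    node_states: Dict[int, dict] = {root: ancestor_states}
    stack = [(root, None)]
    order = []
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nbr in sorted(tree.adj[node]):
            if nbr != parent:
                stack.append((nbr, node))
    for node, parent in order:
        if parent is None:
            continue
        length = tree.edge_length(parent, node)
        parent_states = node_states[parent]
        node_states[node] = {
            pair: _evolve_state(parent_states[pair], length, model, rng)
            for pair in chosen
        }

    def to_table(states_by_taxon: Dict[str, dict]) -> ContactTable:
        table = ContactTable()
        for taxon in sorted(states_by_taxon):
            states = states_by_taxon[taxon]
            for pair in chosen:
                st = states[pair]
                table.add(taxon, ContactRecord(
                    pair[0], pair[1], st["status"], st["segments"]
                ))
        return table

    tips = to_table({
        tree.leaf_label[n]: node_states[n] for n in tree.leaves
    })
    ancestor = to_table({"ancestor": ancestor_states})
    return tips, ancestor


def study_fixture() -> ContactTable:
    """The packaged four-skull contact table.

    A transcription of the per-bone contact statements for *Desmatochelys
    lowii* (fossil; many suture depths undeterminable, coded ``?``),
    *Eretmochelys imbricata*, *Dermochelys coriacea* and *Chelydra
    serpentina*.  Shipped as a versioned TSV data file so the
    transcription can be audited and corrected row by row.
    """
    ref = resources.files("sutura.data").joinpath("study_contacts.tsv")
    with resources.as_file(ref) as path:
        return read_contact_table(path)


def simulate_characters(
    tree: Tree,
    n_chars: int = 20,
    n_states: int = 3,
    rate: float = 0.5,
    p_ordered: float = 0.0,
    p_missing: float = 0.0,
    seed: int = 0,
):
    """Evolve discrete characters on ``tree`` (Mk-like jump process).

    Per branch, each character experiences Poisson(rate x length) change
    events; unordered characters resample uniformly among the other
    states, ordered characters step +/-1 (clipped).  Returns a
    :class:`~sutura.charmatrix.CharacterMatrix` over the tree's leaves.
    """
    from .charmatrix import MISSING, CharacterMatrix

    rng = np.random.default_rng(seed)
    ordered_flags = [bool(rng.random() < p_ordered) for _ in range(n_chars)]
    root = next((u for u in tree.adj if u not in tree.leaf_label), tree.leaves[0])
    states: Dict[int, np.ndarray] = {
        root: rng.integers(n_states, size=n_chars)
    }
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if parent is not None:
            length = tree.edge_length(parent, node)
            current = states[parent].copy()
            n_events = rng.poisson(rate * length, size=n_chars)
            for j in range(n_chars):
                for _ in range(n_events[j]):
                    if ordered_flags[j]:
                        step = 1 if rng.random() < 0.5 else -1
                        current[j] = min(n_states - 1, max(0, current[j] + step))
                    else:
                        others = [s for s in range(n_states) if s != current[j]]
                        current[j] = others[rng.integers(len(others))]
            states[node] = current
        for nbr in sorted(tree.adj[node]):
            if nbr != parent:
                stack.append((nbr, node))

    taxa = [tree.leaf_label[n] for n in tree.leaves]
    rows = {}
    for leaf in tree.leaves:
        label = tree.leaf_label[leaf]
        cells = []
        for j in range(n_chars):
            if p_missing and rng.random() < p_missing:
                cells.append(MISSING)
            else:
                cells.append(frozenset({int(states[leaf][j])}))
        rows[label] = cells
    return CharacterMatrix(
        taxa=taxa,
        characters=[str(j + 1) for j in range(n_chars)],
        rows=rows,
        ordered=ordered_flags,
    )
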