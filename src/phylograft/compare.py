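"""Tree agreement: Robinson-Foulds metrics (unweighted and branch-score) and
per-node conflict classification against a reference tree.

All comparisons are made on the shared (intersection) leaf set: updated trees
typically carry many more tips than the originals they were grown from.
Rooted inputs are treated as unrooted for split extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .datamodel import leaf_labels
from .errors import PhylograftError, UndefinedMetricError

Split = frozenset  # frozenset({frozenset(side1), frozenset(side2)})


def _edge_splits(tree: dendropy.Tree, leafset: frozenset):
    """Yield (node, split, edge_length) for every edge, with the split induced
    on ``leafset``. Trivial and empty splits are yielded too; callers filter."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter()) & leafset
        other = leafset - below
        yield node, frozenset({below, other}), node.edge.length


def make_split(side1, side2) -> Split:
    a, b = frozenset(side1), frozenset(side2)
    if not a or not b or (a & b):
        raise PhylograftError("bipartition sides must be nonempty and disjoint")
    return frozenset({a, b})


def _nontrivial(split: Split, leafset: frozenset) -> bool:
    sides = list(split)
    if len(sides) != 2:
        return False
    return all(len(s) >= 2 for s in sides)


def induced_bipartitions(tree: dendropy.Tree, leafset) -> set:
    """Nontrivial splits of ``tree`` restricted to ``leafset`` (degree-2 nodes
    suppressed implicitly: identical induced splits collapse)."""
    leafset = frozenset(leafset)
    missing = leafset - leaf_labels(tree)
    if missing:
        raise PhylograftError(f"leafset not in tree: {sorted(missing)}")
    return {
        s for _, s, _ in _edge_splits(tree, leafset) if _nontrivial(s, leafset)
    }


def split_set(tree: dendropy.Tree, leafset) -> set:
    return induced_bipartitions(tree, leafset)


def _shared_leafset(t1, t2, minimum: int = 4) -> frozenset:
    shared = frozenset(leaf_labels(t1) & leaf_labels(t2))
    if len(shared) < minimum:
        raise UndefinedMetricError(
            f"only {len(shared)} shared leaves; need at least {minimum}"
        )
    return shared


def rf_unweighted(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric difference of the induced nontrivial bipartition sets on the
    shared leaf set."""
    shared = _shared_leafset(t1, t2)
    return len(induced_bipartitions(t1, shared) ^ induced_bipartitions(t2, shared))


def _split_lengths(tree, leafset) -> dict:
    lengths: dict = {}
    for node, split, length in _edge_splits(tree, leafset):
        if not _nontrivial(split, leafset):
            continue
        if length is None:
            raise PhylograftError(
                f"missing branch length on edge above node {node.taxon.label if node.taxon else node.label or id(node)}"
            )
        lengths[split] = lengths.get(split, 0.0) + length
    return lengths


def rf_weighted(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Branch-score variant: sum over the union of nontrivial induced
    bipartitions of |len1 - len2|, absent bipartitions contributing 0."""
    shared = _shared_leafset(t1, t2)
    l1 = _split_lengths(t1, shared)
    l2 = _split_lengths(t2, shared)
    return sum(abs(l1.get(s, 0.0) - l2.get(s, 0.0)) for s in set(l1) | set(l2))


@dataclass(frozen=True)
class ConflictLabel:
    node_id: str
    label: str  # supported_by | conflicts_with | resolves | uninformative
    witness: str | None = None


def _splits_incompatible(s1: Split, s2: Split) -> bool:
    (a, b), (x, y) = list(s1), list(s2)
    return all((p & q) for p in (a, b) for q in (x, y))


def conflict_classify(
    tree: dendropy.Tree, reference: dendropy.Tree
) -> list[ConflictLabel]:
    """Label every internal node of ``tree`` against ``reference`` on the
    shared leaf set: supported_by (identical split exists), conflicts_with
    (incompatible with some reference split; first such reference node in
    preorder is the witness), resolves (compatible with all, equal to none),
    or uninformative (fewer than 2 shared leaves on a side)."""
    shared = _shared_leafset(tree, reference)

    ref_nodes = []  # (node_id, split) in preorder
    for idx, (node, split, _len) in enumerate(_edge_splits(reference, shared)):
        if _nontrivial(split, shared):
            ref_nodes.append((f"r{idx}", split))

    labels = []
    for idx, (node, split, _len) in enumerate(_edge_splits(tree, shared)):
        if node.is_leaf():
            continue
        node_id = f"n{idx}"
        if not _nontrivial(split, shared):
            labels.append(ConflictLabel(node_id, "uninformative"))
            continue
        supported = next((rid for rid, rs in ref_nodes if rs == split), None)
        if supported is not None:
            labels.append(ConflictLabel(node_id, "supported_by", supported))
            continue
        conflicting = next(
            (rid for rid, rs in ref_nodes if _splits_incompatible(split, rs)), None
        )
        if conflicting is not None:
            labels.append(ConflictLabel(node_id, "conflicts_with", conflicting))
        else:
            labels.append(ConflictLabel(node_id, "resolves"))
    return labels


def comparison_summary(t1: dendropy.Tree, t2: dendropy.Tree) -> dict:
    """JSON-ready summary used by the CLI: RF metrics plus conflict counts of
    ``t1`` classified against ``t2``."""
    labels = conflict_classify(t1, t2)
    counts = {l.label: 0 for l in labels}
    for l in labels:
        counts[l.label] = counts.get(l.label, 0) + 1
    try:
        rfw = rf_weighted(t1, t2)
    except PhylograftError:
        rfw = None
    return {
        "rf_unweighted": rf_unweighted(t1, t2),
        "rf_weighted": rfw,
        "n_supported": counts.get("supported_by", 0),
        "n_conflicting": counts.get("conflicts_with", 0),
        "n_resolving": counts.get("resolves", 0),
    }
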