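"""Newick trees, stable edge references, and branch annotations.

Trees are dendropy :class:`~dendropy.Tree` objects throughout; this module
adds the conventions the placement pipeline relies on:

* tip labels are normalized like matrix labels (quotes stripped,
  underscores mapped to spaces) so matrix and tree taxa match;
* an edge of the *unrooted* topology is addressed by an :data:`EdgeRef` — the
  canonical bipartition of tip labels it induces.  Bipartitions survive
  pruning, re-rooting and re-parsing, which internal node ids do not;
* per-branch annotations (here: placement scores) are written either as
  node labels or as ``[&score=...]`` comment tags and can be read back.

Branch lengths are parsed but never used: scoring is topology-only.
"""

from __future__ import annotations

from io import StringIO
from typing import Iterable, Mapping

import dendropy

from .matrix import normalize_label

__all__ = [
    "EdgeRef",
    "TreeParseError",
    "DuplicateTipError",
    "UnknownEdgeError",
    "parse_tree",
    "write_tree",
    "tip_labels",
    "edge_refs",
    "canonical_bipartition",
    "node_for_edge",
    "write_annotated_tree",
    "read_edge_annotations",
    "topologies_equal",
]

#: Canonical bipartition of an unrooted edge: the frozenset of tip labels on
#: the side NOT containing the lexicographically smallest tip.
EdgeRef = frozenset


class TreeParseError(ValueError):
    """Malformed Newick input."""


class DuplicateTipError(TreeParseError):
    """Two tips share a label."""


class UnknownEdgeError(KeyError):
    """An EdgeRef that does not address any edge of the tree."""


def parse_tree(text: str) -> dendropy.Tree:
    """Parse one Newick tree; tip labels normalized; polytomies preserved."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:
        if "duplicate" in str(exc).lower():
            raise DuplicateTipError(str(exc)) from exc
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        label = normalize_label(leaf.taxon.label if leaf.taxon else (leaf.label or ""))
        if not label:
            raise TreeParseError("tip without a label")
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.require_taxon(label)
        leaf.taxon.label = label
        labels.append(label)
    if len(set(labels)) != len(labels):
        raise DuplicateTipError("duplicate tip labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, *, lengths: bool = False) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=not lengths,
        unquoted_underscores=True,
    ).strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def canonical_bipartition(side: Iterable[str], all_tips: frozenset[str]) -> EdgeRef:
    """Root-independent form of an edge bipartition.

    Of the two sides of the split, keep the one not containing the smallest
    tip label, so the same unrooted edge maps to the same key however the
    tree happens to be rooted.
    """
    side = frozenset(side)
    ref = min(all_tips)
    return all_tips - side if ref in side else side


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[nd] = frozenset((nd.taxon.label,))
        else:
            out[nd] = frozenset().union(*(out[c] for c in nd.child_nodes()))
    return out


def edge_refs(tree: dendropy.Tree) -> dict[EdgeRef, dendropy.Node]:
    """Map every unrooted edge to a representative (child-side) node.

    The two child edges of a binary root describe the same unrooted edge and
    are collapsed onto one entry, so a rooted binary input with *n* tips
    yields 2n−3 edges, matching the unrooted edge count.
    """
    tips = tip_labels(tree)
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    leafsets = _leafsets(tree)
    out: dict[EdgeRef, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ref = canonical_bipartition(leafsets[nd], tips)
        if ref and ref != tips and ref not in out:
            out[ref] = nd
    return out


def node_for_edge(tree: dendropy.Tree, edge: EdgeRef) -> dendropy.Node:
    refs = edge_refs(tree)
    try:
        return refs[frozenset(edge)]
    except KeyError:
        raise UnknownEdgeError(f"no edge with bipartition {sorted(edge)!r}") from None


def write_annotated_tree(
    tree: dendropy.Tree,
    annotations: Mapping[EdgeRef, str],
    *,
    mode: str = "label",
) -> str:
    """Newick with per-branch annotation strings.

    ``mode="label"`` places annotations in the Newick branch-label slot
    (internal node labels); terminal branches, whose label slot is the taxon
    name, carry a ``[&score=...]`` comment instead.  ``mode="comment"`` uses
    comment tags on every annotated branch.  Unannotated edges are left bare.
    """
    if mode not in ("label", "comment"):
        raise ValueError("mode must be 'label' or 'comment'")
    work = tree.clone(depth=1)
    refs = edge_refs(work)
    for edge, text in annotations.items():
        try:
            nd = refs[frozenset(edge)]
        except KeyError:
            raise UnknownEdgeError(f"no edge with bipartition {sorted(edge)!r}") from None
        if mode == "comment" or nd.is_leaf():
            nd.comments.append(f"&score={text}")
        else:
            nd.label = str(text)
    return work.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=True,
        suppress_item_comments=False,
        unquoted_underscores=True,
    ).strip() + "\n"


def read_edge_annotations(text: str) -> dict[EdgeRef, str]:
    """Recover the per-branch annotations of :func:`write_annotated_tree`."""
    tree = parse_tree(text)
    tips = tip_labels(tree)
    leafsets = _leafsets(tree)
    out: dict[EdgeRef, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        value = None
        ann = nd.annotations.get_value("score")
        if ann is not None:
            value = str(ann)
        elif not nd.is_leaf() and nd.label:
            value = str(nd.label)
        if value is not None:
            out[canonical_bipartition(leafsets[nd], tips)] = value
    return out


def topologies_equal(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Unrooted topology identity: same tips and same set of bipartitions."""
    ta, tb = tip_labels(a), tip_labels(b)
    if ta != tb:
        return False
    return set(edge_refs(a)) == set(edge_refs(b))
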