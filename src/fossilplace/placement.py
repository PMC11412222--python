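"""Backbone-constrained placement of a fossil taxon.

The relationships among extant taxa are fixed (the backbone, typically from
molecular work) and only the fossil moves: it is grafted in turn onto every
branch of the unrooted backbone, each augmented topology is scored under
implied-weights parsimony against the morphological matrix, and the scores
are mapped back onto the branches.  Reporting keeps the whole ranking, not
just the winner, so suboptimal placements can be inspected — with a mostly
incomplete fossil the signal is often spread over several branches.

Lower score = better throughout ("fit" is a homoplasy penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .matrix import CharacterMatrix, UnknownTaxonError
from .parsimony import ImpliedWeightConfig, TreeScore, _min_steps_per_char, tree_score
from .trees import (
    DuplicateTipError,
    EdgeRef,
    edge_refs,
    node_for_edge,
    tip_labels,
    write_annotated_tree,
)

__all__ = [
    "PlacementResult",
    "enumerate_attachments",
    "attach",
    "place_fossil",
    "report_placements",
]

DEFAULT_TIE_TOL = 1e-9


def _edge_sort_key(edge: EdgeRef):
    return (len(edge), tuple(sorted(edge)))


def enumerate_attachments(backbone: dendropy.Tree) -> list[EdgeRef]:
    """Every branch of the unrooted backbone, in a deterministic order.

    A binary unrooted backbone with *n* tips has 2n−3 branches; polytomies
    simply contribute fewer.  Each EdgeRef is one candidate attachment point.
    """
    if len(tip_labels(backbone)) < 2:
        raise ValueError("backbone must have at least 2 tips")
    return sorted(edge_refs(backbone), key=_edge_sort_key)


def attach(backbone: dendropy.Tree, edge: EdgeRef, fossil: str) -> dendropy.Tree:
    """Graft ``fossil`` onto ``edge``: the branch is bisected by a new
    degree-3 node bearing the fossil tip; extant relationships are untouched."""
    if fossil in tip_labels(backbone):
        raise DuplicateTipError(f"{fossil!r} is already a tip of the backbone")
    tree = backbone.clone(depth=1)
    nd = node_for_edge(tree, edge)
    parent = nd.parent_node
    index = parent.child_nodes().index(nd)
    parent.remove_child(nd)
    joint = dendropy.Node()
    parent.insert_child(index, joint)
    joint.add_child(nd)
    tip = joint.new_child()
    tip.taxon = tree.taxon_namespace.require_taxon(fossil)
    return tree


@dataclass
class PlacementResult:
    """Scores for every candidate attachment of one fossil.

    ``ranking`` lists edges by ascending score (ties broken by edge key for
    determinism); ``ranks`` uses competition ranking, so all members of a tie
    share the rank; ``argmax_set`` holds every edge tied — within
    ``tie_tol`` relative tolerance — for the best (lowest) score.
    """

    fossil: str
    k_used: float
    score_kind: str
    tie_tol: float
    backbone_score: TreeScore
    per_edge: dict[EdgeRef, TreeScore] = field(repr=False)
    ranking: list[EdgeRef] = field(repr=False)
    ranks: dict[EdgeRef, int] = field(repr=False)
    argmax_set: frozenset[EdgeRef] = frozenset()

    def edge_score(self, edge: EdgeRef) -> float:
        cfg = ImpliedWeightConfig(self.k_used, self.score_kind)
        return self.per_edge[edge].score(cfg)

    @property
    def best_score(self) -> float:
        return self.edge_score(self.ranking[0])


def _ties(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


def place_fossil(
    backbone: dendropy.Tree,
    m: CharacterMatrix,
    fossil: str,
    cfg: ImpliedWeightConfig = ImpliedWeightConfig(),
    *,
    tie_tol: float = DEFAULT_TIE_TOL,
    restrict_to: Iterable[str] | None = None,
) -> PlacementResult:
    """Score every attachment branch for ``fossil`` on ``backbone``.

    ``restrict_to`` optionally names a clade by its tip labels; the ranking
    is then filtered to branches lying within (or subtending) that clade,
    which excludes e.g. inter-familial backbone branches from consideration.
    """
    tips = tip_labels(backbone)
    if fossil not in m.taxa:
        raise UnknownTaxonError(f"fossil {fossil!r} absent from matrix")
    if fossil in tips:
        raise DuplicateTipError(f"fossil {fossil!r} already in backbone")
    missing = tips - set(m.taxa)
    if missing:
        raise UnknownTaxonError(f"backbone tips absent from matrix: {sorted(missing)}")

    edges = enumerate_attachments(backbone)
    if restrict_to is not None:
        clade = frozenset(restrict_to)
        unknown = clade - tips
        if unknown:
            raise UnknownTaxonError(f"restriction tips not in backbone: {sorted(unknown)}")
        edges = [e for e in edges if e <= clade or (tips - e) <= clade]
        if not edges:
            raise ValueError("clade restriction excludes every branch")

    aug_taxa = frozenset(tips | {fossil})
    mins_aug = _min_steps_per_char(m, aug_taxa)
    backbone_score = tree_score(backbone, m, cfg)

    per_edge: dict[EdgeRef, TreeScore] = {}
    for edge in edges:
        per_edge[edge] = tree_score(attach(backbone, edge, fossil), m, cfg, _min_steps=mins_aug)

    scores = {e: per_edge[e].score(cfg) for e in edges}
    ranking = sorted(edges, key=lambda e: (scores[e], _edge_sort_key(e)))
    ranks = {
        e: 1 + sum(1 for o in edges if scores[o] < scores[e] and not _ties(scores[o], scores[e], tie_tol))
        for e in edges
    }
    best = scores[ranking[0]]
    argmax = frozenset(e for e in edges if _ties(scores[e], best, tie_tol))
    return PlacementResult(
        fossil=fossil,
        k_used=cfg.k,
        score_kind=cfg.score_kind,
        tie_tol=tie_tol,
        backbone_score=backbone_score,
        per_edge=per_edge,
        ranking=ranking,
        ranks=ranks,
        argmax_set=argmax,
    )


def _edge_description(edge: EdgeRef, tips: frozenset[str]) -> str:
    """Human-readable side of the split: the smaller side's sorted tips."""
    other = tips - edge
    side = edge if len(edge) <= len(other) else other
    return ",".join(sorted(side))


def report_placements(
    result: PlacementResult,
    backbone: dendropy.Tree,
    *,
    precision: int = 2,
    annotation_mode: str = "label",
) -> tuple[str, str]:
    """Tabular and tree-shaped views of a placement result.

    Returns ``(tsv, newick)``: one TSV row per candidate branch (stable edge
    id, adjacent clade, scores at full precision, competition rank, tie
    flag), and the backbone with each branch labelled by its score rounded
    to ``precision`` decimals — the figure-style per-branch score map.
    """
    tips = tip_labels(backbone)
    edges = sorted(result.per_edge, key=_edge_sort_key)
    ids = {e: f"E{i + 1:03d}" for i, e in enumerate(edges)}
    shared = {r for r in result.ranks.values() if sum(1 for v in result.ranks.values() if v == r) > 1}

    lines = [
        f"# fossil={result.fossil}\tk={format(result.k_used, '.10g')}\tscore_kind={result.score_kind}",
        f"# backbone_total_fit={format(result.backbone_score.total_fit, '.10g')}"
        f"\tbackbone_total_length={result.backbone_score.total_length}",
        "edge_id\tclade\ttotal_fit\ttotal_length\trank\ttie",
    ]
    for e in sorted(edges, key=lambda e: (result.ranks[e], _edge_sort_key(e))):
        ts = result.per_edge[e]
        lines.append(
            "\t".join(
                (
                    ids[e],
                    _edge_description(e, tips),
                    format(ts.total_fit, ".10g"),
                    str(ts.total_length),
                    str(result.ranks[e]),
                    "1" if result.ranks[e] in shared else "0",
                )
            )
        )
    tsv = "\n".join(lines) + "\n"

    ann = {e: f"{result.edge_score(e):.{precision}f}" for e in edges}
    newick = write_annotated_tree(backbone, ann, mode=annotation_mode)
    return tsv, newick
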