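"""Fitch parsimony lengths and the Goloboff implied-weights score.

For each character the observed parsimony length ``s`` is the minimum number
of state changes needed to explain the tip states on the given topology
(unordered states, equal costs).  The minimum conceivable length ``m`` is the
fewest changes any tree could need, so ``e = s − m`` counts *extra* steps —
homoplasy.  Implied weighting turns homoplasy into a concave penalty per
character,

    f = e / (e + k),

with concavity constant ``k > 0`` (``k = 12`` here by default, the setting
used for fossil-placement work on morphological matrices); the tree score is
``Σ f`` over characters and is minimized.  Small ``k`` punishes homoplastic
characters harshly; as ``k → ∞`` the ranking converges to equal-weights
parsimony (``Σ s``), available via ``score_kind="raw_length"``.

The length computation is a uniform-cost dynamic program over states (the
Fitch–Hartigan–Sankoff generalization), which is exact for polytomies and
for set-valued tips: polymorphic cells contribute their state set, missing
and inapplicable cells contribute full ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .matrix import CellState, CharacterMatrix, UnknownTaxonError
from .trees import tip_labels

__all__ = [
    "ImpliedWeightConfig",
    "CharacterScore",
    "TreeScore",
    "fitch_length",
    "min_steps",
    "implied_fit",
    "tree_score",
    "scores_tsv",
]

_INF = 1 << 30


@dataclass(frozen=True)
class ImpliedWeightConfig:
    """Scoring options: concavity constant and which total ranks trees."""

    k: float = 12.0
    score_kind: str = "implied_fit_total"  # or "raw_length"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("concavity constant k must be > 0")
        if self.score_kind not in ("implied_fit_total", "raw_length"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")


@dataclass(frozen=True)
class CharacterScore:
    s: int  # observed steps on this tree
    m: int  # minimum steps on any tree
    e: int  # extra steps (homoplasy)
    f: float  # implied-weight fit penalty e/(e+k)


@dataclass
class TreeScore:
    total_fit: float
    total_length: int
    per_character: list[CharacterScore] = field(repr=False)

    def score(self, cfg: ImpliedWeightConfig) -> float:
        return float(self.total_length) if cfg.score_kind == "raw_length" else self.total_fit


def implied_fit(e: float, k: float) -> float:
    """Concave homoplasy penalty ``e/(e+k)``; 0 iff no extra steps."""
    if not k > 0:
        raise ValueError("concavity constant k must be > 0")
    if e < 0:
        raise ValueError("extra steps must be >= 0")
    return e / (e + k)


# ---------------------------------------------------------------------------
# lengths


def _allowed_mask(cell: CellState, n_states: int) -> np.ndarray:
    if cell.is_observed:
        mask = np.zeros(n_states, dtype=bool)
        mask[sorted(cell.states)] = True
        return mask
    return np.ones(n_states, dtype=bool)  # '?' and '-' scored as full ambiguity


def _fitch_lengths(
    tree: dendropy.Tree, cells: Mapping[str, Sequence[CellState]], n_chars: int
) -> np.ndarray:
    """Parsimony length of every character at once, shape ``(n_chars,)``.

    Dynamic program over states: ``cost[v, s]`` is the cheapest explanation
    of the subtree at ``v`` given state ``s`` at ``v``; a child in state
    ``s'`` adds 1 if ``s' != s``.  Exact for multifurcations and ambiguity.
    """
    n_states = 0
    for row in cells.values():
        for c in row:
            if c.is_observed:
                n_states = max(n_states, max(c.states) + 1)
    if n_states == 0:
        return np.zeros(n_chars, dtype=np.int64)

    cost: dict[int, np.ndarray] = {}
    root = None
    for nd in tree.postorder_node_iter():
        root = nd
        if nd.is_leaf():
            row = cells[nd.taxon.label]
            mask = np.stack([_allowed_mask(c, n_states) for c in row], axis=1)
            cost[id(nd)] = np.where(mask, 0, _INF).astype(np.int64)
        else:
            acc = np.zeros((n_states, n_chars), dtype=np.int64)
            for child in nd.child_nodes():
                cc = cost.pop(id(child))
                acc += np.minimum(cc, cc.min(axis=0) + 1)
            cost[id(nd)] = acc
    if root is None:
        raise ValueError("empty tree")
    return cost[id(root)].min(axis=0)


def fitch_length(tree: dendropy.Tree, column: Mapping[str, CellState]) -> int:
    """Minimum number of state changes for one character on ``tree``.

    Every tip must have a cell in ``column``; missing/inapplicable tips are
    free to take any state.
    """
    tips = tip_labels(tree)
    if not tips:
        raise ValueError("empty tree")
    absent = tips - set(column)
    if absent:
        raise UnknownTaxonError(f"tips without cells: {sorted(absent)}")
    cells = {t: [column[t]] for t in tips}
    return int(_fitch_lengths(tree, cells, 1)[0])


def min_steps(column: Mapping[str, CellState]) -> int:
    """Fewest changes this character needs on *any* tree.

    Equals (size of a minimum hitting set of the observed state sets) − 1,
    floored at 0: a tree can realize a character with ``h`` unavoidable
    states in ``h − 1`` changes by grouping taxa by state, and no fewer,
    while polymorphic cells satisfied by an already-needed state demand
    nothing extra.
    """
    sets = [c.states for c in column.values() if c.is_observed]
    if not sets:
        return 0
    universe = sorted(frozenset().union(*sets))
    for size in range(1, len(universe) + 1):
        for combo in combinations(universe, size):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                return size - 1
    raise AssertionError("unreachable: universe itself hits every set")


def _min_steps_per_char(m: CharacterMatrix, taxa: frozenset[str]) -> np.ndarray:
    out = np.empty(m.n_chars, dtype=np.int64)
    for j in range(m.n_chars):
        out[j] = min_steps({t: m.rows[t][j] for t in taxa})
    return out


def tree_score(
    tree: dendropy.Tree,
    m: CharacterMatrix,
    cfg: ImpliedWeightConfig = ImpliedWeightConfig(),
    *,
    _min_steps: np.ndarray | None = None,
) -> TreeScore:
    """Score one topology against the whole matrix.

    Characters with fewer than two observed taxa on this tree carry no
    signal and score ``s = m = e = 0`` (routine in fossil-heavy matrices).
    """
    tips = tip_labels(tree)
    absent = tips - set(m.taxa)
    if absent:
        raise UnknownTaxonError(f"tips absent from matrix: {sorted(absent)}")
    cells = {t: m.rows[t] for t in tips}
    s = _fitch_lengths(tree, cells, m.n_chars)
    mins = _min_steps_per_char(m, tips) if _min_steps is None else _min_steps
    e = s - mins
    if (e < 0).any():
        raise AssertionError("observed length below the theoretical minimum")
    fits = e / (e + cfg.k)
    per_char = [
        CharacterScore(int(s[j]), int(mins[j]), int(e[j]), float(fits[j]))
        for j in range(m.n_chars)
    ]
    return TreeScore(float(fits.sum()), int(s.sum()), per_char)


def scores_tsv(ts: TreeScore) -> str:
    """Per-character score table (1-based character index; columns s, m, e, f)."""
    lines = ["char\ts\tm\te\tf"]
    for j, c in enumerate(ts.per_character, start=1):
        lines.append(f"{j}\t{c.s}\t{c.m}\t{c.e}\t{format(c.f, '.10g')}")
    return "\n".join(lines) + "\n"
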