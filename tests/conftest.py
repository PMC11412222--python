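from __future__ import annotations

import random

import pytest

from fossilplace import CellState, CharacterMatrix, parse_tree


@pytest.fixture
def quartet_tree():
    return parse_tree("((A,B),(C,D));")


@pytest.fixture
def quartet_column():
    return {
        "A": CellState.observed(0),
        "B": CellState.observed(0),
        "C": CellState.observed(1),
        "D": CellState.observed(1),
    }


def random_cell(rng: random.Random, n_states: int) -> CellState:
    """A random cell: mostly single observed states, some missing,
    inapplicable, and polymorphic entries."""
    u = rng.random()
    if u < 0.10:
        return CellState.missing()
    if u < 0.15:
        return CellState.inapplicable()
    if u < 0.25 and n_states > 1:
        size = rng.randint(2, n_states)
        return CellState.observed(rng.sample(range(n_states), size))
    return CellState.observed(rng.randrange(n_states))


def random_matrix(rng: random.Random, n_taxa: int, n_chars: int, n_states: int) -> CharacterMatrix:
    taxa = [f"T{i}" for i in range(1, n_taxa + 1)]
    rows = {t: [random_cell(rng, n_states) for _ in range(n_chars)] for t in taxa}
    return CharacterMatrix(taxa, rows)


def random_tuple_tree(rng: random.Random, labels: list[str]):
    """Random binary tuple-tree by sequential random edge insertion."""
    from oracles import _insert_everywhere

    labels = list(labels)
    rng.shuffle(labels)
    t = (labels[0], labels[1], labels[2]) if len(labels) >= 3 else tuple(labels)
    for label in labels[3:]:
        options = _insert_everywhere(t, label)
        t = options[rng.randrange(len(options))]
    return t


def tuple_to_newick(t) -> str:
    def rec(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(rec(c) for c in node) + ")"

    return rec(t) + ";"
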