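"""Fitch lengths, minimum steps, and the implied-weights fit."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_cell, random_matrix, random_tuple_tree, tuple_to_newick
from oracles import brute_force_fitch, brute_min_steps, all_unrooted_topologies
from fossilplace import (
    CellState,
    CharacterMatrix,
    ImpliedWeightConfig,
    UnknownTaxonError,
    attach,
    canonical_bipartition,
    enumerate_attachments,
    fitch_length,
    implied_fit,
    min_steps,
    parse_tree,
    scores_tsv,
    tip_labels,
    tree_score,
)


def _cell_to_allowed(cell: CellState, n_states: int) -> set[int]:
    return set(cell.states) if cell.is_observed else set(range(n_states))


def test_constant_column_needs_no_changes():
    t = parse_tree("((A,(B,E)),(C,D));")
    col = {lbl: CellState.observed(0) for lbl in "ABCDE"}
    assert fitch_length(t, col) == 0


def test_single_origin_separating_two_clades(quartet_tree, quartet_column):
    assert fitch_length(quartet_tree, quartet_column) == 1


def test_polytomy_scored_exactly():
    # star tree with three states among five tips: two changes, not more
    t = parse_tree("(A,B,C,D,E);")
    col = {
        "A": CellState.observed(0), "B": CellState.observed(0),
        "C": CellState.observed(1), "D": CellState.observed(2),
        "E": CellState.observed(0),
    }
    assert fitch_length(t, col) == 2


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10**6), n_tips=st.integers(4, 7), n_states=st.integers(2, 4))
def test_fitch_equals_brute_force_enumeration(seed, n_tips, n_states):
    rng = random.Random(seed)
    labels = [f"T{i}" for i in range(n_tips)]
    tup = random_tuple_tree(rng, labels)
    cells = {lbl: random_cell(rng, n_states) for lbl in labels}
    allowed = {lbl: _cell_to_allowed(c, n_states) for lbl, c in cells.items()}
    tree = parse_tree(tuple_to_newick(tup))
    assert fitch_length(tree, cells) == brute_force_fitch(tup, allowed, n_states)


def test_min_steps_nothing_observed():
    assert min_steps({"A": CellState.missing(), "B": CellState.inapplicable()}) == 0


def test_min_steps_three_singleton_states():
    col = {t: CellState.observed(i) for i, t in enumerate("ABC")}
    assert min_steps(col) == 2


def test_min_steps_polymorphism_never_inflates():
    col = {
        "A": CellState.observed({0, 1}),
        "B": CellState.observed({1, 2}),
        "C": CellState.observed(1),
    }
    assert min_steps(col) == 0  # state 1 satisfies everyone


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10**6), n_taxa=st.integers(3, 6))
def test_min_steps_equals_minimum_over_all_trees(seed, n_taxa):
    """min_steps is the best Fitch length achievable on any topology."""
    rng = random.Random(seed)
    n_states = 3
    labels = [f"T{i}" for i in range(n_taxa)]
    cells = {lbl: random_cell(rng, n_states) for lbl in labels}
    observed = {
        lbl: (set(c.states) if c.is_observed else None) for lbl, c in cells.items()
    }
    best = min(
        fitch_length(parse_tree(tuple_to_newick(tup)), cells)
        for tup in all_unrooted_topologies(labels)
    )
    assert min_steps(cells) == best
    assert min_steps(cells) == brute_min_steps(observed)


@pytest.mark.parametrize(
    "e,k,expected", [(0, 12, 0.0), (1, 12, 1 / 13), (13, 12, 0.52), (5, 3, 0.625)]
)
def test_implied_fit_values(e, k, expected):
    assert implied_fit(e, k) == expected


def test_implied_fit_rejects_bad_arguments():
    with pytest.raises(ValueError):
        implied_fit(1, 0)
    with pytest.raises(ValueError):
        implied_fit(-1, 12)


def test_all_constant_matrix_scores_zero(quartet_tree):
    m = CharacterMatrix(
        list("ABCD"), {t: [CellState.observed(1)] * 6 for t in "ABCD"}
    )
    ts = tree_score(quartet_tree, m)
    assert ts.total_fit == 0.0
    assert ts.total_length == 0


def test_tree_score_composes_fitch_and_fit(quartet_tree, quartet_column):
    m = CharacterMatrix(list("ABCD"), {t: [quartet_column[t]] for t in "ABCD"})
    cfg = ImpliedWeightConfig(k=12)
    ts = tree_score(quartet_tree, m, cfg)
    s = fitch_length(quartet_tree, quartet_column)
    assert ts.total_length == s
    assert ts.per_character[0].m == min_steps(quartet_column)
    assert ts.total_fit == implied_fit(s - ts.per_character[0].m, 12)


def test_underobserved_characters_score_zero(quartet_tree):
    rows = {
        "A": [CellState.observed(1), CellState.missing()],
        "B": [CellState.missing(), CellState.missing()],
        "C": [CellState.missing(), CellState.inapplicable()],
        "D": [CellState.inapplicable(), CellState.missing()],
    }
    ts = tree_score(quartet_tree, CharacterMatrix(list("ABCD"), rows))
    assert ts.total_length == 0
    assert ts.total_fit == 0.0


def test_tip_absent_from_matrix_raises(quartet_tree):
    m = CharacterMatrix(list("ABC"), {t: [CellState.observed(0)] for t in "ABC"})
    with pytest.raises(UnknownTaxonError):
        tree_score(quartet_tree, m)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10**6))
def test_score_invariant_under_rerooting_and_taxon_order(seed):
    rng = random.Random(seed)
    m = random_matrix(rng, 6, 10, 3)
    tup = random_tuple_tree(rng, list(m.taxa))
    tree = parse_tree(tuple_to_newick(tup))
    cfg = ImpliedWeightConfig()
    base = tree_score(tree, m, cfg)

    rerooted = tree.clone(depth=1)
    node = rerooted.find_node_with_taxon_label("T3")
    rerooted.reroot_at_edge(node.edge, update_bipartitions=False)
    assert tree_score(rerooted, m, cfg).total_length == base.total_length
    assert tree_score(rerooted, m, cfg).total_fit == pytest.approx(base.total_fit)

    shuffled_taxa = list(m.taxa)
    rng.shuffle(shuffled_taxa)
    m2 = CharacterMatrix(shuffled_taxa, {t: m.rows[t] for t in shuffled_taxa})
    assert tree_score(tree, m2, cfg).total_fit == pytest.approx(base.total_fit)


@settings(deadline=None, derandomize=True, max_examples=15)
@given(seed=st.integers(0, 10**6))
def test_adding_a_tip_changes_each_character_by_zero_or_one(seed):
    rng = random.Random(seed)
    m = random_matrix(rng, 7, 8, 3)
    backbone = parse_tree(tuple_to_newick(random_tuple_tree(rng, m.taxa[:6])))
    base = tree_score(backbone, m)
    edges = enumerate_attachments(backbone)
    edge = edges[rng.randrange(len(edges))]
    aug = tree_score(attach(backbone, edge, m.taxa[6]), m)
    for before, after in zip(base.per_character, aug.per_character):
        assert after.s - before.s in (0, 1)


@settings(deadline=None, derandomize=True, max_examples=15)
@given(seed=st.integers(0, 10**6))
def test_fit_bounds_and_raw_length_limit(seed):
    rng = random.Random(seed)
    m = random_matrix(rng, 6, 10, 3)
    tree = parse_tree(tuple_to_newick(random_tuple_tree(rng, m.taxa)))
    ts = tree_score(tree, m)
    assert all(0 <= c.f < 1 for c in ts.per_character)
    assert 0 <= ts.total_fit < m.n_chars
    assert ts.total_length == sum(c.s for c in ts.per_character)
    raw = tree_score(tree, m, ImpliedWeightConfig(score_kind="raw_length"))
    assert raw.score(ImpliedWeightConfig(score_kind="raw_length")) == ts.total_length


def test_scores_tsv_layout(quartet_tree, quartet_column):
    m = CharacterMatrix(list("ABCD"), {t: [quartet_column[t]] * 2 for t in "ABCD"})
    text = scores_tsv(tree_score(quartet_tree, m))
    lines = text.strip().splitlines()
    assert lines[0] == "char\ts\tm\te\tf"
    assert len(lines) == 3
    assert lines[1].startswith("1\t")
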