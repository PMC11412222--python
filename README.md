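# fossilplace

Backbone-constrained placement of a fossil taxon under implied-weights
parsimony.

## The problem

Where does a newly described fossil belong on the tree of its living
relatives?  Molecular phylogenies give a well-supported backbone for the
extant taxa, but a fossil offers only morphology — and usually only a
fraction of it (amber inclusions, compressions).  The standard constrained
approach fixes the relationships among extant taxa to the molecular backbone
and lets *only* the fossil move: the fossil is grafted in turn onto every
branch of the unrooted backbone, each augmented topology is scored against a
discrete morphological character matrix, and the per-branch scores are mapped
back onto the tree.  Reading the whole score map, not just the optimum,
shows how decisively the data favour the best placement over the
alternatives.

## The score

For character *i* on topology *T*, let `s_i` be its Fitch parsimony length
(minimum number of unordered state changes), `m_i` the minimum length it
needs on *any* topology, and `e_i = s_i − m_i` its extra steps (homoplasy).
Implied weighting scores the tree as

```
score(T) = Σ_i  e_i / (e_i + k)
```

minimized over placements, with concavity constant `k > 0` (default 12).
Homoplastic characters are progressively down-weighted; `k → ∞` recovers
equal-weights parsimony (available as `score_kind="raw_length"`).  Lower
score = better placement.  Missing (`?`) and inapplicable (`−`) cells are
scored as full ambiguity; polymorphic cells (`{01}`) as their state set; the
three kinds are kept distinct in the data model and in all round-trips.

The Fitch lengths come from a uniform-cost dynamic program over states
(exact for polytomies and ambiguous tips), vectorized across characters.

## Worked example

Simulate a small study — 8 taxa, 150 binary characters evolved on a Yule
tree, one tip degraded into a fossil codable for about half the matrix, the
backbone equal to the true tree minus that fossil — then place the fossil:

```
$ fossilplace simulate --n-tips 8 --n-chars 150 --rate 0.2 --seed 11 \
      --missing-fraction 0.5 --out-prefix demo
INFO fossil tip: t08 (codable for 72 of 150 characters)
INFO wrote demo.nex, demo.backbone.nwk, demo.true_tree.nwk

$ fossilplace place --matrix demo.nex --tree demo.backbone.nwk \
      --fossil t08 --out-prefix demo_run
INFO fossil t08 codable for 72 of 150 characters
INFO backbone score: total_fit=2.956044 total_length=158
INFO scored 11 attachment branches; best score 3.329670 on 1 tied branch(es)
INFO   best placement side: t02,t03,t04,t05,t06,t07
```

`demo_run.placements.tsv` holds the full ranking (edge id, the smaller side
of the split the branch induces, implied-weights fit, raw length, rank, tie
flag):

```
edge_id  clade            total_fit    total_length  rank  tie
E011     t01              3.32967033   168           1     0
E004     t05              3.483516484  170           2     0
E008     t06,t07          3.626373626  172           3     1
E009     t05,t06,t07      3.626373626  172           3     1
E010     t01,t02,t03      3.626373626  172           3     1
...
```

and `demo_run.annotated.nwk` is the backbone with each branch labelled by
its score — the tree-figure view of the same numbers:

```
(t01[&score=3.33],((t02[&score=4.30],t03[&score=4.29])3.70,
 (t04[&score=3.77],(t05[&score=3.48],(t06[&score=4.02],t07[&score=4.02])3.63)3.63)3.63));
```

Reading it: the optimal attachment (fit 3.33, i.e. 10 extra steps spread over
the matrix beyond the backbone's 158) is the terminal branch of `t01`, while
the *true* branch (the split `t01,t02,t03 | t04..t07`, edge E010) ties at
rank 3, 0.30 fit units behind.  With half the fossil's cells missing the
optimum and its runners-up are close — which is exactly why the suboptimal
placements are reported alongside the winner rather than discarded.

The library surface mirrors the CLI: `parse_matrix`, `parse_tree`,
`place_fossil`, `report_placements`, `recovery_experiment`, … — see the
docstrings and `docs/methods.md`.

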