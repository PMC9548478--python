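# simprep

Compare mechanistic models encoded as **labelled abstract simplicial
complexes**. Each model component is a labelled vertex; higher simplices
encode the conceptual interconnections between components. The package

- detects **exchangeable vertex pairs** (swap automorphisms that fix all
  other vertices), the structural signature of conceptually equivalent
  components;
- reduces a representation to its **final orbit space** by iterated quotients
  under the group generated by the exchange transpositions, recording every
  stage in an auditable trace;
- decides **equivalence of two representations** by a label-constrained
  isomorphism search between their final orbit spaces (with degree and
  coface pruning, optional shared-component forcing, and a restricted mode
  that only permits identifications over a user-approved list of component
  pairs);
- provides the applicable **partial operations** — adjacent-vertex
  identification, nonadjacent-vertex identification, vertex substitution —
  with full precondition checking;
- offers an alternative **group encoding**: the subsets of a complex's
  simplices under symmetric difference form an elementary abelian 2-group,
  with singleton generators, element classification, identification /
  substitution homomorphisms, and a symmetric-difference distance;
- ships **fixtures and generators** (random graph-first complexes, planted
  exchangeable pairs) so every pipeline stage is testable without external
  data.

Note the software decides *structural* equivalence only. Whether a matched
pair of component sets is conceptually meaningful is a human decision; the
verdict carries the component pairings for that sign-off.

## File format

Complexes are JSON:

```json
{
  "components": {"1": "morphogen", "2": "diffusion"},
  "simplices": [[1], [2], [1, 2]],
  "maximal_only": false,
  "clique_complete": false
}
```

Vertices are positive integers (or nested lists for merged vertices, as
produced by quotients). With `"maximal_only": true` only maximal simplices
need be listed; with `"clique_complete": true` the file may carry just the
1-skeleton and the flag complex is built on read. The writer is canonical:
the same complex always serializes to identical bytes.

## CLI

```sh
simprep fixture triangle -o K.json     # example complexes (edge, triangle, square, path)
simprep gen --n 7 --density 0.4 --seed 1 --clique -o R.json
simprep validate K.json                # face closure / labelling report
simprep exchanges K.json               # exchangeable pairs, one per line
simprep quotient K.json --pair 1,2     # single quotient (default: all pairs)
simprep final K.json --trace trace.json  # full reduction + stage trace
simprep identify K.json 1 2            # vertex identification (checked)
simprep substitute K.json 1 9          # vertex relabelling
simprep compare K.json L.json          # equivalence verdict as JSON
simprep compare K.json L.json --allowed-pairs allowed.json
simprep classify A.json B.json C.json  # equivalence classes of a collection
simprep distance K.json L.json         # symmetric-difference distance
simprep plant K.json 1 --mode adjacent # plant an exchangeable duplicate
```

Vertices on the command line are addressed by their flattened component
labels, joined with `+` (e.g. `1+2` after a merge). Exit codes: `0` success,
`1` domain error with the violated clause on stderr, `2` usage error.

## Notes

- Clique completion is implemented as the flag complex of the 1-skeleton
  (cliques admitted incrementally by dimension); see the docstring of
  `simprep.core.clique_completion`.
- Reduction applies all exchangeable pairs of each stage simultaneously.
  Batched application is available separately
  (`simprep.quotient.batched_final_orbit_space`) and is checked empirically
  to reach an isomorphic final complex; uniqueness across batchings is a
  tested property, not an assumed theorem.
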