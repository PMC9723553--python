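# mixs-sa

Tools for working with the **MIxS symbiont-associated (MIxS-SA) environmental
package** — the minimum-information checklist for sequence data from microbes
of symbiotic organisms (parasites, mutualists, commensals) whose samples are
nested inside hosts that are themselves nested inside environments.

The package is aimed at researchers and data curators preparing
BioSample-attributes-style metadata tables for symbiont microbiome studies,
and at anyone who needs to check such tables for checklist compliance before
archive submission. It provides:

- **a term registry** — every SA checklist term with its 7-digit MIXS ID,
  requirement level (M mandatory / C conditional / O optional), category,
  definition and expected value syntax, plus the core checklist terms and the
  census of environmental packages (17 pre-existing + symbiont-associated);
- **a validator** — record- and table-level conformance checking of wide
  (one row per sample) or long (key–value) TSV tables, with severity-coded,
  machine-readable reports;
- **a relationship-graph engine** — the repeatable core term
  *relationship to other samples* links samples of one Bioproject with a
  closed vocabulary ('technical replicate of', 'after', 'before', 'next to',
  'within', 'contains'). Edges are canonicalized (`contains(a,b)` ≡
  `within(b,a)`, `after` ≡ inverted `before`), the 'within' subgraph is
  checked to be a containment DAG, and queries return transitive nesting
  (`nested_within`, `contains_closure`), direct co-location (`colocated`)
  and technical-replicate groups;
- **executable study designs** — two bundled demonstration designs (a
  trematode sampled across four life stages in snail/amphipod/fish hosts
  with sediment and water samples; a parasitic plant on ivy hosts with soil
  samples) and a seeded generator of randomized nested studies with optional
  single-defect injection for systematic validator testing.

## The relationship model

A relationship cell holds `;`-separated entries of the form
`predicate:target_sample_id`, e.g. a symbiont sample declaring

```
within:HA8974;next to:SA7890
```

Within/contains and after/before are inverse pairs; 'next to' and 'technical
replicate of' are symmetric. Canonical storage keeps one direction only
(contained → container, earlier → later; symmetric edges with the smaller
endpoint first), so containment queries are plain reachability over a DAG.
Cycles in 'within' or 'before' edges, references to samples outside the
table, unknown predicates and self-relations are all reported with stable
issue codes.

## Worked example

```
$ mixs-sa lookup "host dependence"
term:        host dependence
canonical:   host_dependence
mixs_id:     0001315
category:    symbiont_specific
packages:    symbiont-associated
requirement: symbiont-associated=M
syntax:      free_text
definition:  Type of host dependence for the symbiotic host organism to its host.

$ mixs-sa generate --design fig1a --out demo
$ mixs-sa validate demo/fig1a.tsv --with-graph
ERROR: 0
WARNING: 0
INFO: 16
valid

$ mixs-sa graph query demo/fig1a.tsv --sample S1 --relation nested-within
H1
E2
```

The demonstration design is valid (exit code 0): every mandatory SA term is
present and the relationship graph is a proper containment DAG. The 16 INFO
lines are absent *conditional* terms — advisory by default, promotable to
errors with `--strict-conditional` or per-study applicability rules in a YAML
config. The final query walks the containment chain: symbiont sample S1 sits
within host sample H1, which sits within water sample E2.

The same operations are available as a library:

```python
from mixs_sa import load_registry, fig1a_study, build_graph, nested_within

registry = load_registry()
graph = build_graph(fig1a_study())
nested_within(graph, "S1")   # ['H1', 'E2']
```

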