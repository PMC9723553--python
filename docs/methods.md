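# Methods

## The checklist model

The registry transcribes the symbiont-associated (SA) checklist: 21 published
rows covering 20 distinct terms, because *observed host symbionts* is printed
both as an SA package item and as the term shared with seven host-related
packages (host-associated, human-associated, plant-associated, human-vaginal,
human-skin, human-oral, human-gut); it is stored once, as a single
`TermDefinition` with eight package memberships. Each term carries:

- a **7-digit MIXS ID**, unique across the registry. *Relationship to other
  samples* has no assigned ID yet (`TBD` in the published checklist); it gets
  the internal provisional token `SA-REL-0001`, is flagged provisional, and is
  excluded from the ID↔term bijection invariant.
- a **requirement level per package**: M (mandatory), C (conditional —
  mandatory when applicable), O (optional). The SA package has exactly three
  mandatory terms: *host dependence*, *symbiotic host organism life cycle
  type* and *host life stage*.
- a **category**: symbiont-specific, symbiont–host relationship,
  host-of-symbiont, core, or shared. *Observed host symbionts* spans two
  published sections; since a term has one category here, it is classed
  `shared`, which also makes the "new in this release" set derivable as
  category ∈ {core, shared} — exactly the three terms introduced for use
  beyond the SA package (*observed host symbionts*, *biotic relationship*,
  *relationship to other samples*).
- a **value syntax** class. The published checklist does not print controlled
  vocabularies for the free-text terms (they live in supplementary material),
  so those terms are `free_text` by default; a study can pin them to an
  enumeration via validator config rather than the package inventing a
  vocabulary. Syntax checks are purely syntactic: taxon ids must be positive
  integers but are not resolved against a taxonomy; ontology terms must look
  like a `PREFIX:ID` CURIE or an OBO PURL but are not dereferenced.

The 17 pre-existing environmental package *names* are bundled so the package
census is self-contained; their term inventories (beyond *observed host
symbionts*) are out of scope and deliberately empty.

## Validation semantics

Severity mapping where the standard is silent, chosen to mirror archive
submission practice:

| finding | severity | rationale |
|---|---|---|
| mandatory term absent | ERROR | the term is what makes a record minimally informative |
| conditional term absent | INFO | "conditional" means mandatory-when-applicable and applicability is study-specific; promotable to ERROR globally (`strict_conditional`) or by rule ("term X required when term Y equals V") |
| attribute not in registry | WARNING | archives accept extra attributes; forward-compatible with registry growth |
| attribute from another package | WARNING | informative but probably misplaced |
| malformed value | ERROR | the value cannot mean what the term requires |

The two core terms (*biotic relationship*, *relationship to other samples*)
apply to records of every package: they are recognized and syntax-checked
wherever they appear, and their absence is never reported — only the record's
own package items generate missing-term issues. One advisory consistency
nudge is package-specific: reporting only one of the host-of-host
taxon-id/subject-id pair warns, since both identify the same organism.

Reports are deterministic: issues sort by severity, then sample, then term,
so identical inputs produce byte-identical reports.

## Graph semantics

- Canonical direction is `within` (contained → container) and `before`
  (earlier → later); `contains` and `after` are input sugar rewritten on
  ingestion. Symmetric predicates store the lexicographically smaller
  endpoint first. Canonicalization is idempotent and deduplicating.
- Containment is a **DAG, not a tree**: a sample may legitimately be within
  several containers. Cycles in `within` (and in `before`) are ERRORs.
- `next to` is **not transitive** and containment does **not** imply
  co-location; queries return only what declared edges state, because the
  standard defines only direct relationships.
- A pair related by both `within` and `next to` is contradictory but not
  forbidden by the standard → WARNING. Technical replicates reported under
  different packages → WARNING (replicates of one material are expected to
  share a package; an advisory check, not part of the standard).
- Relationship targets must be samples of the same table (same Bioproject);
  anything else is a DANGLING_REFERENCE error, collected while the rest of
  the graph is still built.
- `nested_within` returns containers in breadth-first order with each
  nesting level sorted, making the order total and deterministic when a
  sample has several containers at one depth.

## Table I/O

Both layouts are UTF-8 TSV with a mandatory header; LF written, LF/CRLF
accepted. An empty cell and a missing column are equivalent (attribute
absent). Relationship cells use the grammar
`predicate:target[;predicate:target...]` with straight apostrophes tolerated
around predicates and whitespace around `:` trimmed; sample ids may not
contain tab, newline, `;` or `:` so the grammar stays unambiguous. List
values split on commas with no escaping — values containing literal commas
are an accepted limitation. An optional `# bioproject=<token>` comment line
carries the Bioproject id through round trips. In the long layout, scalar
attributes may not repeat; relationship rows may (each adds one entry).

## Synthetic study generator

`generate_nested_study` emulates the nested environment → host → symbiont
sampling structure of real symbiont-microbiome studies: every host within
exactly one environment, every symbiont within exactly one host, co-location
edges drawn independently with probability `p_next_to` among environments and
among siblings, and technical-replicate pairs copying an existing sample's
attributes. Defaults (2 environments × 3 hosts × 2 symbionts, p = 0.25, one
replicate pair) give a small design of 21 samples. All randomness comes from
one seeded stream and ids follow a fixed `E*/H*/S*` scheme, so output is a
pure function of the parameters; the node total is capped at 10⁴.

What the generator does **not** emulate: real attribute content (values are
plausible free text, not drawn from any empirical distribution), sequence
data or community composition, multi-Bioproject structure, or malformed
input beyond the six injectable defect kinds. Passing tests therefore
demonstrate structural correctness of the registry/validator/graph machinery
on well-formed and singly-defective tables, not robustness to arbitrarily
messy real-world submissions.

`inject_error` plants exactly one seed-located defect per call (drop a
mandatory attribute, create a containment cycle, a dangling reference, an
unknown predicate, a duplicated sample id, or a malformed taxon id) and
returns a manifest of what was planted, enabling exhaustive
detection-soundness tests.

## Numerical and testing choices

There are no tolerances — every check is exact (counts, edge sets, orders).
Graph-algorithm correctness is established by dual routes: the engine uses
networkx (cycle detection, reachability, connected components) while the
test oracles enumerate simple paths and expand closures to fixpoint with no
shared code; the suites compare them on hundreds of random ≤ 8-node graphs.
Problem sizes in the test and acceptance runs (500 random graphs, 6 × 20
injections, 100 round-trip tables) keep the full suite under a few seconds
while exercising every code path; rates are expected at exactly 100%.

## Known limitations

- Conditional-term applicability rules are user-supplied; the package ships
  no opinion on which studies make which C terms mandatory.
- Ontology and taxonomy identifiers are checked for shape only.
- The provisional ID for *relationship to other samples* is internal and
  will not match whatever ID the standard eventually assigns.
- No temporal reasoning beyond before/after cycle detection, and no merging
  of graphs across Bioprojects.
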