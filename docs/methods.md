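# Methods

## The reconstruction procedure

`paxnet` assembles the upstream network of a gene list by iterated query
rewriting over a BioPAX Level 3 knowledge graph. The state is a
*frontier* of names to explain, an *explored* set of names already
queried, and an accumulating edge set. One level does:

1. **Pre-expansion.** The frontier names are widened with registered
   synonyms (from an NCBI gene_info table) and with decorated variants
   (`<prefix> name`, `name <suffix>`), when those options are on.
2. **Query.** The expanded batch is split into chunks (default 20 names)
   and matched with one of two patterns. Regulation:
   a `TemplateReactionRegulation` whose controlled `TemplateReaction`
   produces an entity whose `displayName` *or* any `name` literal is in
   the batch. Signaling: a `Control` or `Catalysis` whose controlled
   `BiochemicalReaction` has such an entity among its `right`
   participants. Both select the controller, its class, the matched
   product, the `controlType`, the interaction IRI and the `dataSource`
   provenance; both filter excluded sources inside the query (rows with
   no source survive the filter and are attributed to `unspecified`).
3. **Absorption.** Each hit becomes a signed edge controller → product
   (`controlType` containing `ACTIVATION`/`INHIBITION` collapses onto the
   two signs; anything else is UNKNOWN). A signaling reaction's left
   participants additionally contribute substrate → product edges with
   sign UNKNOWN, since participation carries no control sign. Decorations
   are stripped from names before node creation, so graph nodes carry
   canonical labels. A complex controller contributes oriented `PART_OF`
   edges member → complex — from explicit `component` links when present,
   else by splitting its label on the complex delimiters — and its
   members join the frontier.
4. **Advance.** Newly seen names not yet explored form the next frontier;
   the loop stops when the frontier empties or `max_depth` levels have run.

Termination is guaranteed by a **global visited set**: a name is queried
at most once ever, even if reachable along several paths, so the loop
runs at most `min(max_depth, #names in the KB)` levels and cycles
(including autoregulation) cannot re-enqueue their members. Whether the
original tool's visited set is global or per-level is not documented;
the global choice is taken here and should be kept in mind when comparing
node counts against other reconstructions.

Assembly is fully deterministic — there is no randomness, and iteration
orders are lexicographic — so two runs on the same local file produce
byte-identical outputs.

### Graph forms

Two views are maintained. The **influence graph** is a directed
multigraph of entities with signed edges; parallel edges that differ in
sign are kept (contradictory reports from different databases are
preserved as data; merging is left to exporters), while edges coinciding
on (source, target, sign, kind) merge with their provenance sets unioned.
The **hypergraph** keeps reaction nodes, as a strictly bipartite graph of
entities and reactions with typed participation roles (`controller-of`,
`left-of`, `product-of`, `right-of`, `member-of`). Complex membership is
modeled as a *complex-assembly pseudo-reaction* whose product is the
complex and whose members attach with `member-of`; this preserves
bipartiteness and compiles to `PART_OF` edges. Compilation to the
influence form fans each controller out to every product with the
controller's sign.

### Unification and exports

Unification is a post-processing on the finished graph: a node whose name
matches exactly one gene in the synonym table is renamed to that gene's
canonical symbol; names matching several genes are left untouched and
reported as ambiguous; a merge that would fuse a complex with a protein
is refused (class mismatch). Both the unified and the non-unified graph
are always written. Exports: SIF plus a TSV edge-attribute table
(kind, provenance), a 3-column signed table for sign-consistency tools
(ACTIVATION → `+`, INHIBITION → `-`, `PART_OF` → `+` by default, complex
formation being treated as a positive influence, or dropped on request;
UNKNOWN edges must be filtered first — the exporter refuses them
otherwise), and GraphML for the hypergraph.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| `max_depth` | 10 | matches the depth at which explorations typically plateau (growth stabilizes around level 4–5; deeper levels mostly rediscover known nodes) |
| `chunk_size` | 20 names/query | bounded query size avoids endpoint limits while keeping round-trips low |
| complex delimiters | `/`, `:` | `-` is deliberately excluded: hyphens occur inside gene symbols (`HLA-A`) |
| label prefixes | `expression of` | the decoration most commonly attached to expression-state entities |
| label suffixes | `mutant form`, `phosphorylated`, `protein`, `gene` | a configurable starting set (YAML-overridable); databases differ in the decorations they use |
| remote timeout / retries | 60 s / 3 | public pathway endpoints are slow and flaky; failures carry the endpoint and attempt count |
| name matching | exact, case-sensitive (case-insensitive opt-in) | reproducible; aggregated display names are case-normalized |

Synonym ambiguity (one name → several gene ids) expands over *all*
matches with a logged warning: the expansion stage is deliberately
recall-oriented, and precision is recovered later by unification, which
refuses exactly those ambiguous merges.

`drop_unknown` (the CLI's `-unk`) recovers only signed interactions: an
UNKNOWN-signed hit is discarded as it arrives and its controller does not
extend the frontier. A post-hoc `filter_unsigned` is also provided for
graphs assembled without the flag; the two differ on nodes reachable only
through unsigned edges.

## The synthetic knowledge bases

`synthetic_kb.generate_kb` plants a layered upstream network: each node
at level *l−1* receives `1 + Poisson(branching − 1)` regulators at level
*l* (optionally reusing existing nodes with probability
`reuse_probability`, which creates cross-edges and cycles), with per-edge
signs drawn as (1 − p_inhibition − p_unknown, p_inhibition, p_unknown)
and a data source drawn from `source_names`. A configurable number of
regulators are complexes — emitted with both explicit `component` links
and a `/`-joined label so both decomposition paths are exercised — and of
entities carry either an extra alias `name` literal (recorded in a
companion gene_info file) or a decorated display name
(`expression of X`). All randomness flows from `KbSpec.seed` through one
Mersenne Twister, and the emission avoids blank nodes, so serializations
are byte-stable per seed.

`ground_truth_upstream` is an independent oracle: a breadth-first upstream
closure over the planted edge *table* (never the RDF), expanding complex
members, resolving aliases/decorations to canonical names, and optionally
skipping unsigned edges. Assembler correctness is checked as exact
set equality of per-provenance edge tuples against this closure.

What the generator does **not** emulate: the degree distribution, scale
and redundancy of real aggregated pathway data; conflicting signs for the
same pair from different databases arising systematically; entities whose
display name differs from every registered symbol; BioPAX pathway/step
scaffolding beyond what the two query patterns touch. Passing the planted
tests therefore demonstrates the correctness of the query patterns,
recursion, expansion and bookkeeping — not retrieval quality on live
PathwayCommons, which depends on the database version and is out of scope
here. Test and acceptance runs use planted networks of up to roughly two
hundred nodes (2–6 input genes, 1–5 levels, branching ≤ 2), which keeps
the whole acceptance sweep under a minute while still covering every
code path (complexes, aliases, decorations, reuse cycles, all three
signs).

## Metrics

* **Coverage** S = |ON| / |IG| × 100, reported raw and integer-rounded;
  with a synonym table, an input gene counts as present if any of its
  registered names is a node (otherwise alias spelling deflates ON).
* **2-cycle fraction**: the share of non-membership *edges* (u,v) for
  which some edge (v,u) exists; self-loops excluded. The alternative
  convention (counting unordered pairs) gives different numbers; edges
  are counted here to match the phrasing "edges that belong to a cycle of
  size 2".
* **Clique census**: all complete subgraphs (not only maximal ones) of
  sizes 3..max on the undirected simple projection; K5 gives 10/5/1.
* **Topology summary**: components on the undirected projection; diameter
  and characteristic path length as the max and mean of *finite* directed
  shortest-path lengths over distinct ordered pairs (on a disconnected
  graph this effectively reports the largest component, which is what a
  single-number diameter means there); "percentage of shortest paths" is
  the fraction of ordered node pairs with a finite directed path;
  multi-edge node pairs are unordered pairs joined by more than one edge
  in any direction or sign.
* **Betweenness top-k**: shortest-path betweenness on the largest weakly
  connected component of the directed simple projection, ties broken
  lexicographically, each entry carrying the node's neighbor count.
* **Triad census**: a raw count of connected 3-node subgraph types on the
  directed simple projection — a descriptive census only, *not* a motif
  z-score analysis against randomized ensembles.

All metrics are deterministic and independent of node insertion order.

## Drug screening

The screen runs three steps: (1) match the input gene symbols against a
DrugBank-like RDF source through `drug --target--> entity --gene-name-->
symbol` paths, keeping drugs with an `approved` status when the filter is
on; (2) assemble a depth-1 regulation network with all expansions on and
take as *new targets* the sources of non-membership edges into the input
genes that are not input genes themselves; (3) re-run the drug query on
the new targets. Drugs are deduplicated by identifier; predicate IRIs are
a configurable mapping because linked-data DrugBank deployments drift.

## Known limitations

* BioPAX Level 3 only; no OWL reasoning — only asserted triples are seen.
* The signaling pattern does not traverse `Modulation` or `PathwayStep`
  links; reconstructions may miss interactions expressed only there.
* Upstream exploration only; no successor (downstream) search.
* Left-participant (substrate) edges appear in the assembled influence
  graph but hypergraph compilation emits controller→product edges only,
  so the two views differ on reactions with substrates.
* Unification cannot split a node matched by two different genes; it
  leaves such names untouched and reports them.
* Remote mode trusts the endpoint's SPARQL conformance; no paging beyond
  the chunked queries is attempted.
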