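# Methods

## Scope and model

`ppiscreen` screens several disease interactomes for shared critical
proteins.  Each interactome is a simple undirected graph: self-loops are
dropped at parse time, parallel rows collapse to one edge, and protein
symbols are case-sensitive and never remapped (no identifier translation).
Confidence scores in STRING-style exports are parsed and ignored; no score
threshold is applied, because screening here is purely topological.

The screen is a fixed-order funnel:
common proteins → top-50% ("hub-like") filter → action-map isolation
screen → intersection with the common hubs (top-10%).  All stages are set
operations given the per-network degree rankings, so the pipeline is fully
deterministic for fixed inputs.

## Centrality conventions

All four indices treat edges as unweighted hop counts and are computed by
single-source breadth-first accumulation (Brandes-style, O(n·m) overall);
an exponential path-enumeration oracle exists only in the test suite.

* **Degree** — count of distinct neighbours.
* **Betweenness** — pair-dependencies accumulated per source, halved
  (each unordered pair is seen from both endpoints), then normalised by
  2/((n−1)(n−2)) with *n* the **whole-graph** node count, not the
  component size.  On disconnected graphs this differs from tools that
  normalise per component; unreachable pairs contribute nothing.  For
  n < 3 all values are defined as 0.
* **Closeness** — reachable-set formulation: (number of nodes reachable
  from *v*) divided by the sum of distances to them.  This keeps the index
  defined on disconnected graphs and equals the classical reciprocal mean
  distance on connected ones; an isolated node scores 0.  The harmonic
  variant was deliberately not used.
* **Stress** — integer count of shortest paths containing the node as an
  interior vertex, counted **once per unordered** source–target pair.  Per
  source, the number of shortest paths through *v* equals σ(v)·T(v), where
  T(v) counts shortest-path continuations of *v* in the BFS DAG
  (T(v) = Σ over DAG successors x of (1 + T(x))); summing over sources
  double-counts each pair, hence the final halving.

## Percentile screens

The cut size for percentile *p* over *n* ranked nodes is
max(1, ⌊p/100·n + 0.5⌋) — half-up rounding, so cut sizes are deterministic
and monotone in *p*.  Ranking is by degree only (betweenness, closeness and
stress are reported but never filtered on), ordered degree-descending then
label-ascending; `strict` mode returns exactly the cut size (boundary ties
broken lexicographically for reproducibility), `include_ties` extends the
cut to all nodes tied with the last included degree.  Cross-disease hub
status requires percentile membership in **every** network
(`hub_scope="all"`); an `"any"` mode is exposed because prose descriptions
of such screens are often ambiguous between the two readings, but the
conjunctive reading is the default and the one under which common hubs are
a subset of each network's hub list.

## Action-map isolation screen

The action map holds three directed edge layers — activation, inhibition,
expression — restricted to the candidate set (edges with an endpoint
outside it are discarded and counted).  A candidate is *isolated* in a
layer when it has no incident edge in either direction; direction is
ignored because regulatory embeddedness, not regulatory polarity, is what
the screen tests.  The screen removes candidates isolated in **any**
selected layer (default: all three); the survivors are the core.  Removal
sets are retained per layer, so core ∪ removed always partitions the
candidates.

## Synthetic scenario generator

The generator emulates STRING-derived disease networks at desk scale:
three networks of 100 proteins with ~1500–2200 edges, a 42-label shared
subset, 36 of those hub-like in every network, 3 super-hubs, and an action
fixture whose isolation plan removes 18 of the 36 candidates (expression
isolates 6, activation 2 of those 6, inhibition 17 = 5 of the 6 plus 12
others including two of the three super-hubs), leaving exactly one
critical protein.  These defaults are the reference study conditions; every
planted fact is recorded in a YAML manifest.

Each network grows by preferential attachment (new node attaches to *m*
distinct existing nodes with probability proportional to degree), which
produces the heavy-tailed degree distribution expected of interactomes.
The planting mechanics, in growth order:

1. **Initial clique** (size *m*): the super-hubs plus disease-unique
   labels.  Unique clique members ensure each network's top degree ranks
   are dominated by non-shared proteins, so shared labels cannot drift into
   the top-10% of every network by accident.
2. **Hub-like labels**, inserted immediately after the clique in a
   per-network shuffled order — shuffling decorrelates their degree ranks
   across diseases.
3. **Remaining unique labels** (shuffled), then the **low-ranking shared
   labels** last with a reduced attachment count (m/4), keeping them out of
   every top-50% band.
4. **Uniform densification** up to the per-network edge target: extra
   edges between uniformly chosen non-adjacent pairs.  Uniform (not
   preferential) selection is used here on purpose — preferential
   densification re-amplifies tail variance among late-inserted nodes and
   erodes the planted margins, while a uniform increment preserves the
   ordering established by growth.  The heavy tail is already fixed by the
   growth phase.
5. **Extra attachment rounds** for planted sets, applied last so they are
   additive margins on the final degree scale: 42 uniformly chosen extra
   partners per super-hub, 22 per "decoy hub" (the unique clique labels
   that fill the top-10% slots beyond the super-hubs), 14 per hub-like
   label.  The three constants order the bands
   (super-hubs > decoys > hub-like > bulk > low-shared) with margins wide
   enough that band membership survives attachment noise; they are part of
   the generator's design, chosen so the planted contract (super-hubs in
   the top-10% and hub-like labels in the top-50% of every network) holds
   in well over 95% of seeds.

The attachment count *m* is solved per network so that clique + growth +
boost edges land nearest the edge target (shortfall closed by
densification), subject to a cap that prevents clique members from
crowding planted hub-like labels out of the top-50% band.

Planted-rank guarantees are **statistical**: ranks emerge from random
attachment, and forcing exact ranks would distort the degree distribution.
Recovery is therefore validated as a frequency over a 20-seed ensemble
(≥95% of seeds must recover the exact funnel and the exact super-hub set);
measured rates are 99–100% over wider sweeps.  Everything downstream of
the percentile cuts is exact set algebra and is tested deterministically.

What the generator does **not** emulate: real STRING score distributions
(scores written to the export are cosmetic), degree-exponent fitting to
real interactomes, biological edge semantics, or correlated noise between
the disease networks beyond the planted overlap.  Passing the funnel tests
therefore demonstrates that the screening machinery recovers known
structure; it says nothing about the biological validity of any particular
disease dataset.

## Determinism and numerical notes

* All randomness flows from `numpy.random.default_rng` seeded with the
  scenario seed plus a stream index (network index; fixed offsets for the
  action fixture and the cosmetic scores).  Generated files and reports
  are byte-identical across runs *and across processes* — no iteration
  over unordered sets ever feeds the RNG stream or an output file (set
  draws are sorted first), so Python hash randomisation cannot perturb
  results.
* Betweenness values are accumulated in floating point; the oracle
  equivalence tests bound the error at 1e−9 on the graph sizes tested.
  Degree and stress are exact integers.
* Display CSVs print reals with 3 decimals; machine-readable variants with
  full-precision columns are always written alongside.
* Degenerate inputs: empty networks yield empty record lists; isolated
  nodes score 0 on all four indices; a percentile cut over fewer nodes
  than the cut fraction returns at least one node.

## Known limitations

* The whole-graph betweenness normalisation and reachable-set closeness
  are stated conventions, not universal ones; users comparing against
  other network tools on disconnected graphs should expect systematic
  differences.
* The isolation screen is binary (isolated / not): edge multiplicity and
  confidence within action layers are ignored.
* The generator's planted guarantees were engineered for scenario shapes
  near the reference configuration; extreme configurations (e.g. hub-like
  sets approaching half the network) tighten the percentile bands and
  lower recovery rates.
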