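# Methods

## Adduct m/z computation

Theoretical ion masses are sums over a hard-coded monoisotopic atomic mass
table (C, H, N, O, P, S and the halogens, ≥ 6 decimals), after applying the
adduct's net atom delta, divided by |charge|. The composite negative-mode
species "formate adduct minus water", written `[M+HCOO]-[H2O]`, is modeled as
a single adduct with net delta {C:+1, H:−1, O:+1}: the two steps are always
applied jointly to one observed ion, and the stepwise and net forms are
verified equivalent in the tests.

**Electron mass.** By default no electron-mass term is applied: the common
"calcd" reporting convention for small-molecule assignments quotes the plain
atom-sum, and back-computation of the three reference ions (447.1080,
449.1236, 437.1600) confirms that convention — adding the electron
(~0.000549 Da per charge) shifts the 4th decimal. `electron_correction=True`
switches to the physically exact ion mass.

**Presentation rounding** uses Python's round-half-even at 4 decimals,
standard in MS reporting.

## QED scoring

Each descriptor value x is mapped through an asymmetric double sigmoid

    raw(x) = a + b/(1 + exp(−(x − c + d/2)/e)) · (1 − 1/(1 + exp(−(x − c − d/2)/f)))

normalized by its maximum (the published DMAX constants, shipped in
`netpharm/data/qed_coefficients.json`; for user-supplied coefficient sets the
maximum is located numerically by grid scan plus bounded refinement). QED is
the weighted geometric mean of the eight desirabilities. All three published
weighting schemes are available — `unweighted` (all 1), `mean` (the usual
default, also used here), `max` — selected by `mode` or overridden with an
explicit weight map. Zero weights drop a descriptor from the mean; the score
is invariant to rescaling all weights.

The EAC cutoffs are **inclusive**: QED ≥ 0.3, ROTB ≤ 10, TPSA ≤ 140 Å². The
weighting variant behind any given external descriptor table is often
unstated, which is why both modes are first-class; scores from this package
match the RDKit reference implementation to < 1e-6 on identical descriptor
vectors (verified in the test suite for all three schemes).

## Target sets

Gene identity is the uppercase HGNC-style symbol string; ingest uppercases
and strips whitespace but attempts **no alias resolution** — a documented
limitation, chosen for determinism. "False-positive" prediction removal is
operationalized as an optional score threshold on the compound→target pairs
(default 0 = keep all), since no principled rule is derivable from symbol
lists alone. An empty intersection is a warning, not an error.

## PPI centralities

Conventions follow NetworkAnalyzer/Cytoscape, the tooling the 0.01/0.5
cutoffs are calibrated against:

- degree = neighbor count;
- betweenness = Brandes' statistic normalized by (n−1)(n−2)/2, with n the
  **full** graph's node count, isolated nodes included;
- closeness = component-local, (|component|−1)/Σ distances to co-component
  nodes; isolated nodes score 0. `wf_closeness=True` switches to the
  Wasserman–Faust global rescaling by (|component|−1)/(n−1).

Induced subgraphs recompute centralities from scratch; betweenness and
closeness are not restriction-invariant. With all cutoffs at zero the filter
returns every node (isolated nodes pass only because closeness 0 ≥ 0).
networkx supplies the graph container and the centrality algorithms; the
brute-force shortest-path-enumeration oracle in the test suite pins the exact
normalization conventions on every connected graph of ≤ 7 nodes and a sample
of 8-node graphs.

## Over-representation

The hypergeometric upper tail is evaluated via the scipy survival function
(log-space internally); the EASE variant replaces k with max(k−1, 0), so a
single-gene overlap can never be significant — EASE is the default, matching
the annotation tool the pipeline emulates. The background universe defaults
to all genes in the annotation collection (annotation-based background) and
can be overridden. BH adjustment is computed across all overlapping terms
before truncation. Ranking is fully specified — ascending p, descending
overlap, term id — so outputs are byte-stable. Tails are verified against
exhaustive subset enumeration for every parameter tuple with N ≤ 12 at 1e-12.

## C-T-P network

Edges exist only between adjacent layers. Target→pathway edges use the
enrichment rows' **overlap genes** (not full term membership), keeping the
network consistent with the enrichment stage. Compound→target edges restrict
to key targets by default (`restrict_to_key=False` widens). Compounds and
pathways left edgeless are retained and flagged as isolated so the EAC roster
is preserved in reports. GraphML export inserts nodes and edges in sorted
order, making identical inputs byte-identical on disk.

## Synthetic-data generator

The generator emulates the statistical structure of the pipeline's inputs,
not their biochemical detail:

- **Compounds** (default n = 43, pass fraction 28/43): each compound's
  verdict is drawn Bernoulli(frac_druglike), then descriptors are sampled
  from the matching stratum — drug-like: MW 250–450 Da, ALOGP 1–3.5,
  HBA 2–7, HBD 0–3, TPSA 40–120 Å², ROTB ≤ 8, 1–3 aromatic rings, no alerts;
  non-drug-like: either a Veber violation (ROTB 11–20 or TPSA 141–250) or a
  QED-failing profile (MW 650–900, high lipophilicity/alerts) that still
  passes Veber, so both arms of the conjunction are exercised. The realized
  verdict is verified with the actual screen and resampled within the
  stratum (bounded at 50 draws), making the planted EAC list exact per seed.
- **Target layers** (pool 600 of a 3000-gene universe, 25 targets/compound,
  265 disease genes, 24 planted shared): compound targets come from the
  pool; each planted gene is additionally assigned to at least one EAC
  compound; non-planted disease genes are drawn strictly outside the pool,
  so the intersection equals the planted set by construction.
- **Interactome** (24 nodes, 9 hubs): hubs form a near-clique (pairwise
  p = 0.95), every satellite gets one spoke to a random hub, and background
  edges appear at p = 0.03 on non-core pairs. Because the centrality cutoffs
  are global properties no local rule guarantees, each draw is verified
  (filter recovers exactly the hubs) and resampled up to 50 times; exhausted
  retries raise with the achieved margins. A fully-hub configuration cannot
  satisfy the betweenness cutoff (a near-complete graph has ~0 betweenness
  everywhere), and the generator correctly reports failure there rather than
  returning an unverifiable instance.
- **Annotations** (66 terms, planted coverage 0.8): one planted term holds
  ⌈0.8·|key|⌉ key genes plus background filler; the rest sample members
  uniformly, touching key genes only at the background rate.

Randomness comes from one `SeedSequence` spawned into fixed-order child
streams (compounds, targets, interactome, annotations), so outputs are
deterministic per seed and extending the generator never perturbs earlier
streams.

**What passing tests show — and don't.** Exact planted-truth recovery
demonstrates the selection logic (cutoff semantics, set algebra, centrality
conventions, ranking) is correct. It does not validate the screen against
real chemistry: synthetic descriptors are independent uniform draws with no
inter-descriptor correlation, the interactome has no scale-free degree
structure beyond the planted module, and annotation terms lack the GO DAG's
nesting. Counts from live databases (predicted-target totals, term counts)
are snapshot-dependent and are emulated only at the order-of-magnitude level.

## Numerical and degenerate-input choices

- Desirability slope parameters e, f = 0 are rejected (degenerate sigmoid);
  non-positive desirabilities (impossible for valid coefficient tables) are
  guarded as errors rather than propagating NaNs.
- Hypergeometric count inconsistencies (k > min(n, K), K > N, n > N) are
  parameter errors, not clamped.
- The empty graph yields an empty centrality report; the empty compound list
  screens to an empty selection.
- Problem sizes in the test suite follow the defaults above (100 generator
  seeds for end-to-end recovery, 200 for the pass-count calibration, the
  ≤ 7-node graph catalogue plus forty 8-node samples for the centrality
  oracle, N ≤ 12 for the exhaustive tail enumeration) — small enough to run
  on one CPU in about a minute while covering every selection boundary.

## Known limitations

- No identifier mapping/orthology: symbol-level identity only.
- Closeness/betweenness conventions target NetworkAnalyzer; other tools
  (e.g. igraph defaults) normalize differently and will disagree on
  disconnected graphs.
- EASE here is the penalized hypergeometric tail only; the annotation tool
  it emulates also curates its own background and term catalogue, so term
  *counts* are not comparable across database snapshots.
- The m/z module covers singly- and multiply-charged adducts only through
  the |charge| division; no isotope patterns, no positive-mode registry
  beyond user-supplied specs.
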