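# Methods

This note documents the statistical procedures implemented in `herbnet`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where conventions diverge.

## ADME compound screen

Compounds are retained when OB ≥ `ob_min` (percent scale, default 30) and
DL ≥ `dl_min` (unitless, default 0.18) — both comparisons inclusive, so a
compound sitting exactly on a threshold is kept. OB values are stored on
the percent scale (42.36 means 42.36%) and never rescaled. A molecule
listed in two herb tables yields two records, one per herb; de-duplication
by molecule id happens only when targets are mapped. This per-herb
accounting is what makes per-table row counts additive.

## Gene-set operations

Symbols are normalized by trimming and uppercasing only; hyphens and dots
are preserved. Full-name→symbol conversion, normally a database lookup, is
replaced by an optional local alias→symbol table; conflicting aliases are a
configuration error. All emitted gene lists are sorted lexicographically so
artifacts are byte-reproducible. Venn region counts support 2–5 sets and
are computed by direct membership-pattern tallying; they always sum to the
union's cardinality.

## PPI topology and median screening

The network is built from a scored undirected edge list by keeping edges
with confidence ≥ `min_score` (default 0.9) and dropping any node left
without an edge. Integer scores on a 0–1000 scale are auto-detected (any
value > 1) and divided by 1000.

Centralities (formulas restated in `ppi_topology`'s module docstring):

- **DC** — degree.
- **BC** — unnormalized betweenness over unordered pairs,
  Σ_{s≠v≠t} σ_st(v)/σ_st.
- **CC** — Wasserman–Faust closeness (s−1)²/((n−1)·Σ_u d(v,u)) with s the
  component size; this equals the classical (n−1)/Σd on connected graphs
  and degrades gracefully on disconnected ones. The improved form was
  chosen because the screening comparisons are within one graph, where any
  closeness variant that is monotone in Σd gives the same median ordering
  on connected inputs.
- **EC** — principal eigenvector of the unweighted adjacency matrix,
  computed by shifted power iteration x ← (A + I)x from the uniform start
  vector (the +I shift keeps bipartite spectra convergent), tolerance
  1e−10 on successive iterates, at most 10,000 iterations, sign fixed
  nonnegative, normalized to unit maximum. The test suite checks agreement
  with a dense eigensolver to 1e−8 on graphs up to 50 nodes; the practical
  accuracy is ≈ tol/(1 − λ₂/λ₁).
- **LAC** — for node v with neighborhood N(v), the mean over u ∈ N(v) of
  u's degree in the induced subgraph G[N(v)] (v excluded). A node whose
  neighbors induce no edges has LAC 0.
- **NC** — Σ_{u∈N(v)} ECC(v,u) with ECC(v,u) = z(v,u)/min(deg v−1, deg u−1),
  z the number of triangles containing the edge. When an endpoint has
  degree 1 the denominator is 0 and ECC is defined as 0 — the "no
  clustering evidence" convention that keeps sums finite.

**Median screening**: per round, centralities are computed on the current
induced subgraph, each configured metric's median (midpoint rule for even
n) is recorded, and nodes **strictly greater** than the median on *every*
metric are retained; ties are excluded. The default is one round; an
`until-stable` mode iterates until the retained set stops shrinking. If a
round would retain the empty set — guaranteed on vertex-transitive graphs,
where every metric ties at its median — the round's input set is returned
flagged `terminal` rather than an empty result. The six-metric set
(DC, BC, CC, EC, LAC, NC) is the default; any nonempty subset can be
configured.

## Over-representation analysis

For a term with K members in an N-gene universe and a query of n genes
hitting k of them, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n), evaluated
by the scipy survival function (log-space internally; exact to 1e−12
against subset enumeration in the tests). Multiplicity is controlled with
Benjamini–Hochberg step-up q-values (capped at 1, monotone-enforced,
returned in input order). BH was chosen over the empirical-null "qvalue"
estimator because it is deterministic and exactly testable. The universe
defaults to all genes appearing in the annotation collection — the
standard ORA default — and query genes outside it are dropped with a
logged warning; results are filtered to p ≤ 0.05 and q ≤ 0.05, sorted by p
with ties broken by term id, and truncated to top-N (10 is conventional
for per-category GO displays, 30 for pathway collections).

## Prognostic survival screen

Each gene dichotomizes the cohort at its median expression, ties assigned
to the low group — the dominant convention for cohort KM screens; the rule
is stated in every output. A gene with constant expression (or a maximum
tied with the median, leaving the high group empty) is skipped and listed
in a skipped-genes report. The Kaplan–Meier estimator and the two-group
log-rank test are implemented directly from their O/E/V definitions
(χ² = (O_A−E_A)²/V with the hypergeometric variance per distinct event
time, 1 df); censored subjects leave the risk set after their time, and a
subject censored exactly at an event time is still at risk for that event.
Zero total events or zero variance returns (χ² = 0, p = 1) with a logged
warning. Both routines are cross-checked in the tests against the
`lifelines` implementations and against an exhaustive permutation
reference on tiny cohorts. Screening keeps p < α strictly (defaults 0.05,
refined at 0.01); the refinement reuses the same results table — no
re-test, so the stricter set is always nested.

## Synthetic data

One root seed drives independent substreams (fixed `spawn_key` per
generator), so outputs are pure functions of (config, seed) and adding a
generator never perturbs existing ones. Defaults were chosen once to mimic
study-scale inputs:

- **Compounds** (default n = 100): OB ~ Normal(50, 15) truncated to
  [0, 100], DL ~ Beta(2, 3) — location and spread near the packaged
  curated tables' empirical values, putting the ADME pass fraction
  deliberately away from 0 and 1.
- **Drug/disease pools**: 216 drug targets, 2,000 disease genes, 150
  planted shared symbols; each of 5 sources samples 60% of the disease
  pool, so the realized overlap can fall slightly below 150 (it is
  reported in the ground truth). Every target is assigned to ≥ 1 compound.
- **PPI**: 20-node Erdős–Rényi core at edge probability 0.7 with scores
  U(0.9, 1.0), plus an 80-node periphery attached preferentially
  (2 edges per node, probability ∝ degree + 1) with scores U(0.4, 0.95).
  A 0.9 score cut therefore keeps the core and ~9% of periphery edges.
- **Annotations**: 200 uniform decoy terms with sizes U{10..60}; each
  planted term absorbs 80% of the query padded with non-query genes.
- **Survival** (default n = 200): expression standard normal; a patient's
  hazard is the baseline (1/1500 per day, mean survival ≈ 4 years)
  multiplied by the configured hazard ratio (default 3) for every planted
  gene on which they sit above the median; event times exponential; an
  exact 30% of patients is censored at a uniform point before their event
  time (an exact-fraction reading of "uniform censoring over follow-up").

What the generators do **not** emulate: real ADME chemistry or OB/DL
correlations, STRING score calibration, expression covariance between
genes, non-proportional hazards, or informative censoring. Passing the
recovery tests therefore shows the pipeline's machinery is correct and
well-calibrated under its own assumptions — not that any specific
database-derived gene list is reproduced. The packaged curated tables are
parsing/reporting fixtures, not recomputation targets: the exact gene sets
they descend from depend on database snapshots.

## Pipeline

Stage order: ADME filter → target restriction to active compounds →
disease union and intersection → PPI (edges restricted to intersection
genes) → centralities and median screening → enrichment of the
intersection → survival screen of the intersection genes, intersected with
the PPI core and refined at p < 0.01 → docking triage → bipartite
compound–gene network export (node attributes: kind, herb membership with
`both` for shared ingredients, degree). Every intermediate table is
written; the JSON manifest records input SHA-256 digests, all parameters
(including defaulted ones, also logged), and per-stage counts. The
pipeline itself is deterministic — all randomness lives in the synthetic
module. Defaults equal the conventional screen parameters throughout, so a
bare run mirrors the standard study design.

## Problem sizes and test design

The test suite verifies each operation against an independent oracle:
brute-force filtering and sorting, exhaustive shortest-path enumeration and
dense eigendecomposition (200 random graphs, n ≤ 12, agreement to 1e−9),
subset-enumeration hypergeometrics (every parameter combination with
N ≤ 12, to 1e−12), a hand-worked log-rank O/E/V table (χ² = 49/17), and
`lifelines` for the survival routines. Stochastic behaviour is measured at
the generators' default scales: planted-term recovery over 100 seeded
replicates (≥ 95 expected), log-rank power at hazard ratio 3 and n = 200
over 100 replicates (≥ 80 expected), and type-I error over 2,000 null
tests (expected within [0.03, 0.07] at α = 0.05). These sizes keep the
whole suite to a few minutes on one CPU while leaving the binomial noise
of the rate estimates well inside the asserted bands.

## Known limitations

- Closeness uses the Wasserman–Faust form; tools reporting (n−1)/Σd differ
  on disconnected graphs (identical on connected ones).
- Eigenvector centrality on a disconnected graph concentrates on the
  component with the largest spectral radius; nodes elsewhere get ~0.
- The BH q-value is not the empirical-null estimator some enrichment tools
  print; q-values here are ≥ the corresponding BH-adjusted p by
  construction of that estimator, so thresholds are conservative.
- The log-rank p is asymptotic (χ², 1 df); at very small group sizes the
  permutation distribution is coarser and p is only rank-consistent.
- Median-split survival screening tests marginal association only — no
  covariate adjustment, no proportional-hazards regression.
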