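# Methods

## Model and assumptions

The package operates on three linked structures. The **SSN** is an
undirected graph whose nodes represent sequences — possibly representative
nodes (rep-nodes) standing for a list of accessions with aligned taxon
ids — and whose edges carry a non-negative pairwise similarity score. The
method assumes only that scores order pairs by similarity; their absolute
scale is irrelevant. **Sequence clusters** are the connected components of
the SSN after removing all edges below a threshold; no other clustering
algorithm is offered, because the threshold-induced components *are* the
object the downstream statistics describe. The **GNN** is bipartite:
cluster hubs against Pfam spokes, with an edge whenever enough member
sequences carry the Pfam in their ±nb gene neighborhood.

The neighborhood of a gene is taken irrespective of strand and of
transcriptional organization: ±nb genes, truncated at contig ends, wrapped
on circular replicons. The query gene itself is excluded, but the same
Pfam on a *neighboring* gene counts — only self-counting is suppressed,
not the family's domain. Multi-domain neighbors contribute all their
Pfams; set semantics per sequence ensure tandem repeats cannot inflate
support counts. A sequence present in several genomes contributes the
union of its neighborhoods but counts once in its cluster's denominator;
genomes holding two family members are supported (each target gets its
own record) with the caveat that their neighborhoods may blend adjacent
contexts.

## Threshold selection

Let `Nn(Th)` be the number of nodes incident to at least one edge of
score ≥ Th and `SE(Th)` the number of such edges. The grid runs from
⌊min score⌋ to ⌊max score⌋+1 in integer steps (configurable step width);
edge survival is `score ≥ Th`. Isolated nodes are excluded from `Nn` but
never deleted.

* **A-Th**: smallest grid value whose `Nsv = SE/Nn` strictly exceeds the
  previous grid value's (pairs with `Nn = 0` skipped; equality is not a
  rise).
* **S-Th**: smallest `Th_t` with
  `relNn(Th_t) − relNn(Th_{t+1}) > relSE(Th_t) − relSE(Th_{t+1})`,
  normalization at the grid start.

Both comparisons are evaluated by cross-multiplied integer counts, so the
selected thresholds are exact and independent of floating-point rounding.
On dense networks `Nsv` may decrease monotonically; A-Th is then reported
as absent rather than forced, and S-Th is the recommended selector. Both
recommendations are always printed; the applied threshold is the user's
choice (including a fixed numeric value).

Cluster numbering is deterministic: multi-node components first, ordered
by descending SeqCount with ties broken by the smallest member node id,
then singletons in the same order. Singletons are retained because the
total sequence count N of the uniqueness statistics must reflect the
displayed network. Cluster ids survive SeqCount filtering unchanged so
results remain comparable across filter settings.

## Uniqueness statistics

For a cluster c of n sequences and Pfam p linked to M of the N sequences
in the displayed GNN, with k of c's sequences supporting the edge, the
edge uniqueness is `−log10` of the hypergeometric point probability
`C(M,k)·C(N−M,n−k)/C(N,n)`. Cluster and Pfam uniqueness are the sums over
their incident edges, i.e. Pfam occurrences are treated as independent —
an approximation, since operonic Pfams co-occur by construction, so
cluster values should be read as descriptive scores, not p-values (no
multiple-testing machinery is attached, deliberately).

All probabilities are computed in log space via the log-gamma function:
realistic families produce uniqueness values in the thousands,
far beyond float underflow of the direct probability. The exact
big-integer rational value serves as the test oracle; over every valid
configuration with N ≤ 60 the log-gamma path agrees within ~4·10⁻¹²
relative error and the pmf normalizes to 1 within ~10⁻¹³.

Two choices the statistics depend on:

* **N counts the displayed network.** N is the total sequence count of
  the clusters present in the GNN after any filtering, not the pre-filter
  SSN total, so the reported surprise describes the network the user
  actually sees.
* **Rep-nodes are expanded.** All counts (N, M, n, k, PhylumStat, species
  dedup) run over represented accession lists; treating a rep-node as one
  sequence would make every statistic depend on the collapsing threshold
  used upstream.

## Refinement steps

Whitelist filtering removes Pfam spokes (never hubs); composite ids like
`PF04055-PF13394` pass if any component passes and are otherwise opaque —
they are never split into separate nodes. The built-in whitelist *rule*
selects Pfams whose description contains a four-field EC number pattern
(`d.d/-.d/-.d/-`, optional "EC" prefix) or the substrings "enzyme" /
"catalytic" case-insensitively; the description corpus is an input, not
shipped data.

Subspecies elimination and one-sequence-per-species-per-cluster
deduplication are two independent, idempotent operations (they compose in
either order). A taxid is a subspecies iff the taxonomy table anchors it
to a different species-level taxid. Dedup keeps the lexicographically
smallest accession per (cluster, species) pair — deterministic and
data-independent. Unknown taxids (0, or absent from the table) are never
deleted and never enter PhylumStat denominators; they are surfaced in a
skip report instead, because silently dropping unannotated sequences
could empty real families.

## Numerical and format choices

* XGMML writers sort graph attributes, nodes and edges, and print floats
  with full `repr` precision: identical documents serialize
  byte-identically and `read(write(x)) == x` exactly.
* Duplicate undirected SSN edges collapse to the maximum score
  (conservative: keeps pairs connected at their strongest evidence);
  self-edges are dropped on input.
* The edge-score attribute name is configurable (default
  `alignment_score`) because externally produced SSN files differ here.
* Edge emission uses the exact integer test `100·k ≥ limit·n` rather than
  a rounded coverage, so boundary cases (e.g. 40 of 200 at limit 20) are
  decided consistently.
* The pipeline writes no timestamps; its manifest (parameters, selected
  threshold, SHA-256 input checksums, version) makes a run reproducible
  from the manifest alone.

## Synthetic data: what it emulates, what it does not

The generator plants: complete intra-cluster edge sets with scores
uniform on a high interval (default 90–100) against sparse inter-cluster
edges on a disjoint low interval (20–40, 2% of pairs); one linear genome
of 21 genes per sequence with the target in the middle, the cluster's
operon Pfams on adjacent slots (default 3 Pfams, each included per
sequence with probability 0.6, within ±3 genes) and background Pfams from
a 100-id pool at rate 0.1 per gene; per-cluster phylum mixtures (75/25 of
two phyla by default); and optional subspecies duplicates that copy a
genome and its cluster membership verbatim — the worst case of
phylogenetic bias, chosen so the subspecies filter's effect is exactly
assertable. Default sizes (2 clusters × 200 sequences) keep every test
and the acceptance script in the seconds range while leaving binomial
coverage fluctuations (±3 SE ≈ ±0.104) well resolved.

Not emulated: realistic similarity-score distributions (uniform draws
suffice because thresholding uses only score order), sequence content,
horizontal transfer, assembly fragmentation, annotation errors, or
skewed family sizes. Passing tests therefore demonstrate the
correctness of the algorithms under clean planted structure, not
robustness to noisy real annotations.

A consequence of the planted design worth stating: when every node has
intra-cluster edges, removing inter-cluster edges can never isolate a
node, so `Nsv` strictly decreases and the first `relNn` violation occurs
*inside* the intra-score range, near its top. On such networks A-Th is
typically absent and S-Th lands at the top of the intra range (e.g. 99
for scores uniform on 90–100) — which still separates the planted blocks,
because a clique thinned to the edges above the 90th percentile remains
connected with overwhelming probability at the default sizes. The
recovery tests assert the separation property, which is the invariant
that holds mathematically.

## Known limitations

* Thresholds are evaluated on an integer grid; scores are not required to
  be integral, but sub-integer threshold structure is invisible.
* The co-occurrence/coverage denominator is the cluster's *sequence*
  count. With subspecies elimination and per-species dedup active this
  coincides with the genome count in the intended workflow; without them,
  multi-copy genomes make the two differ.
* GNN XGMML reading supports the dialect this package writes; foreign GNN
  files are out of scope (foreign *SSNs* are supported via the
  configurable score attribute).
* Uniqueness values are descriptive; no calibration under a realistic
  null (correlated neighborhoods, uneven cluster sizes) is attempted.
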