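# Methods

This note documents the models, conventions and numerical choices behind
`culturemap`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic-data tests do and do not
demonstrate about real data.

## Identity mapping

The comparison unit is the community ASV (the V4 query) against each
full-length isolate 16S sequence (the subject). Identity is the maximum,
over every ungapped placement of the whole query inside the subject and
over both strands, of the fraction of matching positions; the denominator
is the query length, which under the 100%-coverage contract equals the
alignment length. This is an *exact exhaustive scan*: at desk scale (a few
thousand ~250 nt queries × a few hundred ~1.5 kb subjects) it replaces a
megablast-style seeded heuristic with the quantity that heuristic
approximates, implemented as a one-hot/matrix-multiply kernel so the full
default problem runs in seconds. Consequences of the conventions:

* `N` matches nothing, including another `N` — conservative and
  deterministic.
* Ties are broken by smallest subject offset, forward strand before
  reverse complement, and lexicographically smallest subject id. The data
  do not determine these choices; fixing them makes runs reproducible.
* A query longer than every subject cannot satisfy full coverage and
  yields a no-hit record (the `unmatched` bin). Note that real pipelines
  using seeded search also report no-hits for *diverged* queries; an
  exhaustive scan instead reports their (low) identity, so diverged
  sequences land in `distant` rather than `unmatched`. Both routes lead to
  the same combined "no close cultured relative" interpretation.

Both strands are scanned because amplicon orientation is not guaranteed
across sequencing chemistries. An optimized scan must equal the naive
double loop; this is enforced by property tests and by the acceptance
script on 1000 random pairs.

## Fraction binning and statistics

Thresholds are strict: cultured means identity **> 99** (species level,
allowing for inter-platform variation), distant means **< 85.93** (the
upper 95% CI of median 16S identity at the class level); the boundary
value 85.93 itself falls in the close-uncultured tier. An optional ladder
of cutpoints can subdivide the close-uncultured interval; the default
keeps it as a single tier because only the two outer thresholds are
well-motivated constants.

Mean relative abundance of an ASV is the unweighted mean over samples of
its per-sample count proportion, zeros included — no depth weighting, so
every sample contributes equally regardless of library size. Bin shares
(ASV % and abundance %) each sum to 100 by construction; reported
percentages are rounded half-up to 2 decimals while full precision is kept
internally.

Rank coverage counts, per taxonomic rank, the fraction of *named* taxa
containing at least one cultured ASV. Genuinely empty taxonomy cells are
excluded from numerator and denominator (they are not countable taxa), but
placeholder names ("Subgroup_2"-style) are kept verbatim; an entirely
unclassified rank yields NaN rather than an error.

The Mann–Whitney U test is two-sided; exact by full enumeration when the
smaller sample has ≤ 8 observations and there are no ties, otherwise the
normal approximation with tie and continuity corrections (both routes via
scipy, cross-checked against an independent enumeration in the tests).

## Network topology

All path-based measures are unweighted hop counts computed within
connected components, matching the defaults of desktop network tools:

* closeness(v) = (number of reachable nodes) / (sum of hop distances);
  isolated nodes get 0.
* betweenness is normalized by (N−1)(N−2) over ordered pairs with N the
  *component* size.
* radiality(v) = Σ_w (Δ + 1 − d(v,w)) / (N−1) with Δ the component
  diameter; this follows the common desktop-tool convention, since no
  single canonical normalization exists — the formula is documented here
  and isolated in one function should a different convention be needed.
* neighborhood connectivity is the mean degree of a node's neighbors
  (NaN for isolated nodes); average shortest path length is the mean hop
  distance to reachable nodes (NaN for singletons).

Negative edges are traversed like positive edges in path computations (one
network, one topology); they retain their sign for degree and
edge-sharing. Hubs must *simultaneously and strictly* exceed degree > 7,
betweenness > 0.1 and closeness > 0.3. Nearest-hub distance is a
multi-source BFS; hubs sit at 0 and are excluded from the
cultured-vs-uncultured distance comparison by default, because including
them would mix the reference set into the compared groups (a flag restores
them). Unreachable nodes are excluded from group tests. The edge-sharing
classification labels a node by the majority culturability of its
partners (strictly > 50%; exact ties excluded) and tests the 2×2
node-fraction × majority-label table with Pearson χ² without continuity
correction (correction available as a flag); a table with a zero margin
returns NaN rather than raising. Group tests report raw two-sided
Mann–Whitney p-values without multiplicity adjustment. The centrality PCA
z-scores its features, eigendecomposes the correlation matrix, drops
zero-variance features with a warning, and signs each component so its
largest-magnitude loading is positive.

### Co-occurrence inference stand-in

`infer_network` is a deliberately simple, transparent baseline — CLR
transform (pseudocount 1), pairwise Spearman correlation, a per-pair
permutation null with independent sample shuffles, Benjamini–Hochberg
control — and **not** a reimplementation of conditional-independence
methods (FlashWeave etc.); externally inferred networks should be supplied
as edge lists for the downstream statistics. One practical consequence of
the permutation design: the smallest attainable p-value is 1/(n_perm+1),
so with m candidate pairs BH at level α can only ever reject if
n_perm ≳ m/α. With the default n_perm = 1000, panels above ~50 retained
ASVs need more permutations for even a perfect association to survive
correction. The null calibration (false-edge proportion within the
binomial envelope of α on independent data) holds by construction of the
permutation test and is verified in the tests.

## Synthetic-data generator

The generator emulates the structure such a culturability study measures;
its defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 2000 | community ASVs |
| `v4_length` | 250 nt | community amplicon length |
| `n_samples`, `depth_per_sample` | 40, 50 000 | samples × reads/sample |
| `n_isolates`, `isolate_flank_length` | 150, 600 nt | isolates; flanks around the embedded V4 (~1450 nt total) |
| `cultured_fraction_of_species` | 0.0632 | planted cultured ASV fraction |
| `cultured_abundance_share` | 0.892 | planted cultured abundance share |
| `lognormal_sigma` | 1.0 | dispersion of base abundances |
| `n_network_nodes`, `edge_density`, `n_hubs` | 103, 0.0288, 7 | latent network (~151 edges) |
| `laplacian_beta` | 0.5 | latent coupling strength |
| `unclassified_rate` | 0.10 | taxonomy truncation rate |

Identity bins are planted by substituting bases of a source isolate's V4 at
distinct positions (substitution-only, no indels — this keeps the ungapped
best-hit identity exact by construction and is why bin recovery can be
asserted *exactly*). The substitution count is round-half-up of
(1 − target/100) × length, so the achieved identity is within 1/length of
the target; the manifest records the achieved value. ASV counts per bin
follow largest-remainder apportionment for exact reproducibility. De-novo
ASVs (planted identity "none") are independent random sequences; random
250-mers sit far below every threshold (all-pairs checks show < 70%
identity), so they land in the distant bin deterministically.

Abundances: log-normal base abundances (σ = 1.0, a typical amplicon
rank-abundance dispersion; the choice is an assumption, not a measured
value); the cultured bin is multiplied either by a fixed enrichment factor
or — the default — by the factor that makes the cultured share of the
expected mean relative abundance *exactly* the configured 0.892 for the
realized draw. Per-sample variation comes from a latent-graph Gaussian
with precision I + β·Laplacian (positive definite for any graph),
exponentiated and then standardized to mean 1 per node across the drawn
samples. The standardization decouples the planted expectations from the
modulation, so the pipeline's recovered cultured abundance share differs
from the planted one only through per-sample renormalization and
multinomial sampling — empirically well within the ±2-percentage-point
recovery band at the default depth. Counts are multinomial per sample, so
column sums equal the depth exactly.

The latent network places a planted cultured-node quota (28%), connects
the hubs in a ring, gives each hub 8–12 spokes wired preferentially to
uncultured nodes (`hub_uncultured_bias`, default 0.8, mimicking the
greater hub-proximity of uncultured taxa), and tops up with random edges
to the target density. Planted hubs are wired densely enough to satisfy
the joint hub criteria; the random top-up can occasionally promote an
additional node past the thresholds, so the classified hub set is
guaranteed to *contain* the planted set rather than equal it at every
seed. Randomness uses one root seed with derived per-stage streams, so
every stage is independently reproducible and bundles are byte-identical
across reruns.

**What passing the synthetic tests does not show.** The generator has no
sequencing-error model, no chimeras, no primer bias, no indels, no
compositional zero-inflation beyond multinomial sampling, and its taxonomy
is an arithmetic hierarchy. Exact bin recovery on synthetic data therefore
validates the *algorithms* (scan, binning, accounting, topology), not the
biological robustness of the thresholds to real sequencing noise.

## Degenerate inputs and numerical conventions

Empty sequence sets, all-zero tables, zero-depth samples, non-binary
presence tables, empty graphs and single-group comparisons raise
`ValueError` with a descriptive message; cross-file id mismatches abort
before computation unless `allow_partial` is set, in which case offending
records are dropped with a logged count. Matches in the vectorized scan
are float32 dot products rounded to integers (exact for counts ≤ 2²⁴).
Fraction shares use exact rational counts; only *reported* percentages are
rounded (half-up, 2 decimals).

## Known limitations

* The exhaustive scan is quadratic in total sequence; it is designed for
  thousands × hundreds of sequences, not reference-database scale.
* The inference stand-in tests marginal associations only; it will report
  indirect correlations that conditional-independence methods remove.
* Radiality and closeness conventions vary between tools; comparisons
  across software should verify the formulas above.
* With heavy dominance (large `lognormal_sigma`) the recovered abundance
  share of small bins becomes noisy at low depth; the default depth keeps
  this well inside the stated recovery band.
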