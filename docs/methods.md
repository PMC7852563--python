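# Methods

`mdmnet` quantifies the ecological contribution of taxonomically
unresolved ("microbial dark matter", MDM) taxa to microbial community
structure. This note documents the models, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Unknown designation

A taxon is Unknown at a rank when its lineage label there is empty or
one of the placeholder tokens produced by SILVA-style open-reference
annotation: `uncultured`, `uncultured bacterium`, `Unknown`,
`Unassigned`, `Ambiguous taxa`, `NA` (case-insensitive, underscore and
space variants treated as equal — SILVA exports differ across
versions). Unknown status propagates downward: an OTU Unknown at
family is Unknown at genus, whatever deeper text says. Taxonomic
"levels" relabel OTU-level nodes; counts are never summed across OTUs
unless the `aggregate="sum"` switch is used. The raw label is kept
alongside the flag, since "uncultured" entries deep in a lineage can
still carry information a user may want to inspect.

## Network inference

Counts are centered-log-ratio transformed with pseudocount 1
(`log(x+1)` minus the per-sample mean log), then a sparse
conditional-dependence graph is estimated by Meinshausen–Bühlmann (MB)
neighborhood selection: each taxon's standardized CLR column is
regressed on all others with an L1 penalty (scikit-learn coordinate
descent, tolerance 1e-6); supports are symmetrized with the "or" rule
(the neighborhood-selection literature default; "and" is available).
Under the `(1/2n)‖y − Xb‖² + λ‖b‖₁` parameterization with
unit-variance columns, any penalty at or above the largest absolute
empirical correlation yields an empty graph, which fixes the top of
the penalty path.

The penalty is chosen by StARS at instability threshold β = 0.05:
edge-presence frequencies are estimated over 20 subsamples of size
`min(⌊10√n⌋, ⌊0.8n⌋)` drawn without replacement; per-edge instability
is `2θ(1−θ)`; the per-penalty mean over all node pairs is monotonized
by a running maximum from the sparse end, and the smallest penalty
(densest graph) with monotonized instability ≤ β is selected before a
full-data refit. The penalty path holds 20 log-spaced values from
λ_max down to 0.05·λ_max. Twenty values is the SpiecEasi default; the
0.05 floor was chosen because on all data we generate, selection at
β = 0.05 lands well above it (typically 0.3–0.5 of λ_max) while the
dense tail below it dominates solver time without ever being selected.
Both are configurable (`n_lambda`, `lambda_min_ratio`).

SparCC and Pearson correlation networks are alternate constructions.
SparCC follows the classic algorithm: per-sample fractions drawn from
Dirichlet(counts + 1), log-ratio variation matrix, approximate
basis-variance linear system, iterative exclusion of the
strongest-correlated pair above 0.1 (up to 10 rounds, with guards that
keep each taxon in at least three pairs and abort a round that drives
basis variances negative), averaged over 20 resampled iterations.
Correlation matrices are binarized at |r| ≥ 0.3 with two-sided p ≤
0.05 (Pearson p from the t transform). **The 0.3 cutoff is a
documented default, not a published value** — source work on these
methods does not state the threshold used to binarize correlation
matrices into networks.

## Centralities

Unweighted throughout. Degree is the incident-edge count; betweenness
the unnormalized Brandes sum (endpoints excluded); closeness is
`1 / Σ d(v,u)` over nodes reachable from `v`, computed within each
connected component and undefined (NaN) for isolated nodes — matching
the R igraph functions this analysis style is built on, which warn on
disconnected graphs but return per-component values. The hub score is
the principal eigenvector of the (unweighted) adjacency matrix,
computed by power iteration from the all-ones vector (tolerance 1e-10)
with a dense symmetric eigensolver fallback for oscillating
(bipartite-like) spectra, scaled so the maximum entry is 1. On an
undirected graph hub and authority scores coincide.

Betweenness is reported unnormalized; rank-based comparisons are
unaffected, but medians across networks of different sizes are not
directly comparable — bear this in mind when reading the long-format
comparison tables.

## The Original / Without-Unknown / Bootstrap experiment

From one prevalence-filtered table: the Original network over all
OTUs; the Without-Unknown network re-inferred from scratch (not a
subgraph deletion) after deleting every OTU Unknown at the chosen
rank; and 100 Bootstrap networks, each re-inferred after deleting an
equal-sized uniform random subset of Known OTUs. The inference seed is
held fixed across all networks so the contrast isolates node removal
from StARS subsampling noise; bootstrap replicates differ only in the
removed subset. Node-level centrality values from all bootstrap
replicates are pooled into a single null distribution per metric
(per-replicate medians are retained for a sensitivity view).

Distributions are compared with two-sided Wilcoxon rank-sum tests.
For group sizes ≤ 8 the two-sided p (double the smaller tail, capped
at 1) is computed exactly by enumeration over assignments, which
remains exact under ties; larger groups use the tie-corrected normal
approximation with continuity correction. Holm adjustment is applied
within each metric across its three contrasts (the adjustment family
is ambiguous in the style of analysis this follows; three-per-cell was
chosen and is the smaller, more conservative family). Direction is
taken from the rank-sum statistic rather than group medians: inferred
degree distributions are small-integer and tie-heavy, and medians
frequently coincide despite a clearly significant shift.

### Why the raw Original-vs-Without contrast is not a null

Removing a fraction q of nodes uniformly at random removes about
1 − (1−q)² of the edges among survivors, so the Without network's
degree and betweenness distributions sit below the Original's even
when Unknown labels carry no information. The raw Original-vs-Without
Wilcoxon contrast therefore detects *node removal*, not
*Unknown-ness*. This is precisely the confound the Bootstrap ensemble
controls: under uninformative labels the Without-Unknown network is
exchangeable with a bootstrap replicate. The package accordingly
exposes `ComparisonResult.detects_unknown_effect()`, which declares an
Unknown effect only when the Original-vs-Without decrease is
significant *and* the Without network also sits significantly below
the equal-removal Bootstrap pool. That rule is calibrated (it stays
quiet under random labels) but has limited power at desk-scale network
sizes, where hub-edge recovery is partial; both facts are measured by
the test suite. All three raw contrasts are always reported.

## Hub prioritization and operon mining

Nodes are ranked by hub score with deterministic tie-breaks (degree
descending, then id). The Known/Unknown hub-score difference uses a
two-sided Welch t-test (pooled-variance available via flag; the
classic description "Student's t test" does not pin the variant). The
top five Known and Unknown hub sequences are exported as FASTA probes.

BLAST hits of hub probes against metagenome scaffolds are retained at
≥ 95% identity and ≥ 95% query coverage (inclusive; coverage from
column 13 when present, otherwise `100·(|qend−qstart|+1)/query length`
so minus-strand hits count their full span); scaffolds with ≥ 50 genes
are kept. Genes are flagged hypothetical by case-insensitive substring
("hypothetical", plus "unknown function" and "DUF") and
adaptation-related against a keyword list (a packaged default of ~50
stress/metabolism gene families ships with the package and is a plain
editable text file). Same-strand genes are chained into operons when
the intergenic gap (next start − running max end − 1, floored at 0) is
≤ 5000 bp — exactly single linkage on the interval-gap distance cut at
5000, verified against a brute-force O(n²) implementation. "5000 bp or
less" (≤) was preferred over a strict reading; both the gap definition
(intergenic vs start-to-start) and a hard ten-gene operon-size cap are
available as switches. An operon is a putative adaptation operon when
some hypothetical member has an adaptation-flagged gene among its ten
gap-nearest operon neighbors, each within 5000 bp.

## Synthetic data

Communities follow a logistic-normal–multinomial model: latent MVN
with covariance the inverse of a planted sparse precision matrix,
per-sample softmax to compositions, multinomial at fixed depth. Zeros
arise from depth and composition; the per-taxon baseline log-abundance
spread is calibrated by bisection (Poisson zero-probability
approximation on a pilot) to hit a target zero fraction, accurate to
within a few points across 0.3–0.7.

Planted precision matrices must be positive definite, which caps
partial correlations: a hub of degree d cannot carry uniform partial
correlations above ~1/√d (spectral bound). The constructions used:

- **hub** (default): `n_hubs = 4` hubs joined in a ring (a clique
  would consume the PD budget — ρ(K_k) = k−1), spokes attached
  round-robin with probability 0.25 per non-hub, background
  Erdős–Rényi edges at 0.02. Hub-incident edges share the hub
  cluster's spectral budget uniformly (`c = 0.95·s/ρ(cluster)`, about
  0.3 at the defaults); background edges get a flat 0.3·s. This keeps
  hub edges detectable and lets the recovered graph's principal
  eigenvector concentrate on the planted hubs.
- **band**: width-1 chain; **random**: Erdős–Rényi; both
  degree-normalized (`s/√(d_i d_j)`), coupling `s = 0.95`.

Defaults (50 taxa, 400 samples, depth 5·10⁴, target zero fraction
0.05) emulate a *prevalence-filtered* network-input table — filtering
exists to reduce sparsity, and network inputs in this analysis style
retain only taxa present in ≥ 30–40% of samples. High-sparsity tables
(majority of taxa in ≤ 20% of samples), as seen before filtering, are
generated by raising `target_sparsity`. Unknown labels are planted on
hub nodes with probability 0.8 by default (recreating the
Unknowns-as-top-hubs phenomenon as a testable scenario) and filled to
the requested fraction at random; a uniform-label null mode supports
type-I checks.

The comparison experiment is exercised at a denser scenario —
`spoke_prob = 1.0`, background 0.05, `unknown_fraction = 0.45` (the
observed regime is 45–62% Unknown among connected nodes),
`hub_unknown_prob = 1.0`, 600 samples — because at the sparse default
the Wilcoxon tests have little power on tie-heavy degree
distributions. Problem sizes in the test suite (e.g. a 30-taxon,
300-sample grid for the 100-run null scan, 10 StARS subsamples there
instead of 20) were chosen so the full suite completes on a single
CPU in well under half an hour.

What the generator does *not* emulate: read-level noise, chimeras and
OTU clustering artifacts; compositional bias between samples beyond
multinomial closure; phylogenetic correlation between taxa; real
prevalence structure (zeros are exchangeable across samples given the
composition, not clustered by study or site). Passing tests therefore
demonstrate that the *pipeline* recovers planted structure under its
own model assumptions — not that those assumptions hold for any
particular 16S survey.

## Numerical and degenerate-input conventions

Fraction-to-sample prevalence thresholds round as `ceil(round(f·n, 9))`
so 40% of 260 samples is exactly 104. Fisher's exact test on a
degenerate margin returns p = 1 with a warning. SparCC basis variances
that solve negative are clipped to machine epsilon with a warning. An
all-identical-samples table has zero StARS variability and selects the
densest penalty; when no penalty meets β the sparsest is returned with
a warning flag on the network. Empty graphs are an error for
centralities; isolated nodes carry NaN closeness and are dropped from
closeness contrasts. All generators and inference routines are pure
functions of their seeds; CLI outputs embed the package version, a
config hash and the seed, and rerunning a command reproduces files
byte for byte.

## Known limitations

- StARS at β = 0.05 is conservative: recall of weak edges (partial
  correlation ≲ 0.25) is limited at n ≈ 400 regardless of depth, which
  bounds how prominently high-degree hubs can appear in recovered
  graphs (their per-edge strength is PD-capped at ~1/√d).
- The raw Original-vs-Without contrast conflates node-removal and
  Unknown effects (see above); use `detects_unknown_effect()` or read
  the Without-vs-Bootstrap contrast alongside it.
- The SparCC/Pearson binarization threshold is a convention, not a
  reproduced value.
- BIOM support is read-only (HDF5 2.x layout via h5py).
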