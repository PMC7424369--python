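# Methods

## Model and procedure

The unit of analysis is the within-sample relative expression ordering
(REO): for genes A and B and one sample, the relation expr(A) > expr(B) or
expr(A) < expr(B). Every statistic in the package is a function of these
order relations only, so all results are invariant under any strictly
monotone transform of the expression values — the pipeline is deliberately
agnostic about whether its input is linear- or log-scale, and the test suite
asserts bit-identical output under log and positive-affine transforms.

**Stable pairs.** In a group of samples, a pair with direction consistent in
k of n informative samples is scored with the one-tailed binomial upper tail
P(X ≥ k), X ~ Binomial(n, 0.5), evaluated through the survival function so
it is accurate for n in the tens of thousands. Samples where the two values
are exactly equal are excluded from n: a tie supports neither direction, and
excluding it keeps the Bernoulli null valid. The test is one-tailed with k
the majority count; no two-tailed doubling is applied. BH adjustment runs
over the multiplicity of all C(G, 2) pairs, including pairs untestable
because every sample ties (they enter as p = 1). Because p depends only on
(k, n), the adjustment is computed over the multiset of distinct p-values
weighted by their counts — bit-identical to naive BH on the full vector
(tested), but O(#distinct) rather than O(#pairs) in the sort.

**Reversal ratio.** Two groups' stable-pair sets are intersected by pair
identity; of the m common pairs, the k with opposite directions are reversal
pairs and k/m is the reversal ratio. m = 0 yields an explicitly undefined
ratio (None), not an error. The comparison is symmetric in its arguments.

**REO-disruption DEGs.** Per gene, over its common stable partners, the 2×2
table (#partners below it, #above it) × (group 1, group 2) is tested with
the two-sided Fisher exact test (standard minimum-likelihood convention, as
in mainstream statistics environments), BH-adjusted across genes with at
least one remaining partner. Genes flagged at FDR < α have their pairs
removed from all genes' backgrounds and the procedure repeats — flagging is
recomputed from scratch each iteration — until two consecutive iterations
flag the identical set (a fixed point; re-running changes nothing, tested)
or `max_iter` (default 10) is reached, in which case the last iteration's
calls are returned with `converged = False`. Direction is up-in-group-2 when
the gene sits above a larger share of partners under group-2 directions;
equal shares mean no directional evidence, so the gene is reported with
direction `none` and not flagged. BH is applied per iteration; the
contingency construction follows the published sketch of the method rather
than any particular implementation's internals, and is documented here as a
faithful re-implementation, not a bit-exact clone.

**Age association.** For each pair, samples with known age are split by the
pair's REO direction; sides smaller than `min_group` (default 5 — tiny sides
make the test powerless and inflate the multiplicity; configurable) cause
the pair to be skipped and excluded from BH. All C(G, 2) pairs passing the
size filter are tested, not only group-stable ones. The Mann–Whitney U test
is exact when both sides have ≤ 25 samples and the pooled ages are tie-free,
otherwise the normal approximation with tie and continuity corrections;
pooled zero-variance ages short-circuit to p = 1 (the null is exact and the
asymptotic variance degenerates).

**Balance tests.** 2×2 Fisher exact on the cross-tabulation of the grouping
factor with each other binary factor, after dropping unknowns; a factor with
≠ 2 observed levels is an error, not a silent reduction.

**Enrichment.** Upper-tail hypergeometric P(X ≥ x) including the observed
overlap (the standard convention), BH across the collection. The universe
defaults to the genes of the analysed expression matrix and is always
explicit in the output records, because the p-value depends strongly on it.
Sets with fewer than 2 genes inside the universe are skipped and excluded
from the multiplicity.

**Probe collapsing.** Probes mapping to zero or multiple genes are dropped;
multiple probes on one gene average arithmetically per sample. Gene IDs are
opaque strings, ordered lexicographically — that ordering is the canonical,
tie-free pair orientation (gene_a < gene_b) used for all set operations.

## Synthetic data: what it emulates and what it does not

The generator draws each sample as mu_g · exp(ε), ε ~ N(0, σ²) i.i.d., with
baselines mu geometrically spaced (log-step 0.3 by default) over a latent
rank template shared by both groups. Since only order matters, the single
relevant property is the probability that noise flips a pair one rank apart:
Φ(−step/(σ√2)) ≈ 1.7% at the defaults (σ = 0.1) — "highly stable REOs".
Planted DEGs replace a gene's baseline so its template rank moves by at
least `rank_shift` positions; moves are planned with a safety margin of
n_deg positions (other planted moves can shave off at most n_deg − 1) and
realized displacements are verified against the minimum. Ground truth
records the planted genes, directions, realized displacements, and the exact
reversal count between the two noiseless templates by exhaustive scan.

Fixed-seed scenarios pin the study conditions: `smoking-like` (200 genes,
20+20 samples, 10 planted DEGs with rank shift ≥ 30) is the many-DEG case;
`sex-like` (6 DEGs, grouping coupled to the sex label, planted genes tagged
with sex-chromosome cytobands) and `race-like` (3 DEGs) are the sparse
cases; `age-null` (100 genes, 60 samples, no planted effect, ages uniform on
37–80 years independent of expression) validates the null of the age test.
The age-null scenario uses a tighter template spacing (log-step 0.15) with
σ = 0.3 so that near-rank pairs split the cohort into two sizeable REO
groups — without mixed orderings there is nothing for a per-pair age test to
act on; expression-to-age coupling remains absent either way. Desk-scale
problem sizes (hundreds of genes, tens of samples) were chosen as the
package's validation conditions; correctness of the pair machinery at scale
is established by oracle equivalence at ≤ 100 genes plus a numerically
stable tail evaluation, not by re-running cohort-sized pair spaces.

The generator does **not** emulate probe-level microarray artifacts, batch
effects, correlated gene modules, heavy-tailed or count noise, or
platform intensity distributions. Passing tests therefore demonstrate that
the statistics behave as designed under the stated model — stable orderings
plus independent multiplicative noise — not that real cohorts meet those
assumptions; on real data the stable-pair fraction and reversal ratios will
differ, though the monotone-invariance and calibration properties carry
over.

## Numerical and design choices

- Binomial and hypergeometric tails via scipy survival functions; Fisher
  exact via scipy with an LRU cache keyed on the table (RankCompV2 re-tests
  many identical tables across genes and iterations).
- Pair enumeration streams in fixed-size blocks (default 10⁶ pairs), so
  memory is O(block × samples) regardless of C(G, 2); a deterministic
  top-variance gene cap is available for desk-scale runs of large matrices.
- Tie-breaks: pair orientation is lexicographic; enrichment output sorts by
  (p, set name); direction ties in DEG calling resolve to "none"/unflagged.
- Degenerate inputs error early and explicitly: < 2 genes or samples, no
  common stable pairs, all-unknown ages, empty universe/query, factors
  without exactly two levels, infeasible rank shifts.
- All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
  identical configuration implies byte-identical synthetic cohorts.

## Known limitations

- The DEG caller is the population-level variant only; individual-sample
  DEG calling against a fixed normal background is out of scope.
- Fisher p-values for very large partner counts rely on scipy's exact
  routine, which is fine at hundreds of partners but is the runtime
  bottleneck for much denser graphs.
- The age test, like any per-pair split test, has no power for pairs whose
  ordering is (nearly) unanimous — such pairs are skipped by design.
- GEO/SOFT/CEL parsing, normalisation and annotation retrieval are out of
  scope; inputs are plain TSV/GMT.
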