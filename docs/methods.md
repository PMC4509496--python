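# Methods

This note documents the models, the numerical choices, and the design
decisions taken where the procedure left genuine latitude. It assumes the
pipeline overview in the README.

## Motif model

A motif of length *l* is a column-stochastic 4×l PWM Θ together with *l*−1
adjacent-pair tables Φ_{i,i+1} (4×4, each summing to 1) capturing
dinucleotide dependence between neighbouring positions. Both are estimated
from background-subtracted counts, so every entry is strictly positive by
construction (pseudocounts, below) and log-space evaluation never
underflows for l ≤ 12.

The window score is

    LLR(s) = Σ_i log θ_{i,s_i} + Σ_i log Φ_{i,i+1}(s_i, s_{i+1}) − log p0(s)

with p0 the third-order Markov background. All logarithms are natural, so
scores are in nats; the base only rescales the integer threshold grid and
no ranking depends on it. Note that the statistic multiplies the
mononucleotide factor U and the pair factor V, so single-letter preference
is counted twice — once directly and once inside the pair tables. This
redundancy is retained deliberately: it is the ranking statistic the
procedure defines, it is monotone in the quantities of interest, and
"fixing" it would change every threshold downstream. One practical
consequence matters: a position whose column and pair tables are uniform
contributes log(1/4) + log(1/16) − log(1/4) = log(1/16) ≈ −2.77 nats to
every window. Uninformative columns therefore *cost* score, which is why
cluster merging must not dilute motifs with weakly covered flanks (see
Clustering).

### Information content

Motifs are ranked by the KL divergence of the motif distribution from the
mononucleotide background. The joint p(s | Θ, Φ) is not defined by Θ and Φ
alone; the only coherent joint consistent with adjacent-pair tables is the
first-order chain

    p(s) = θ_1(s_1) · Π_{i≥2} Φ_{i−1,i}(s_{i−1}, s_i) / m_{i−1}(s_{i−1}),

m being the row marginal of Φ. Under this factorization the sum over all
4^l words is computed exactly by propagating the chain's position marginals
(O(l·16) work); a literal-enumeration mode exists for l ≤ 10 and the two
agree to 1e-9 in tests. IC ≥ 0 always, with equality exactly when the
motif chain equals the background product.

## Background model

The control set fits Markov conditionals of orders 0–3 by maximum
likelihood with add-one pseudocounts. Scoring a window uses order 0, 1 and
2 at its first three positions (context taken within the window, so a
window's score does not depend on where it sits in a sequence) and order 3
thereafter. A control set under 1000 total bases is refused — 256
third-order contexts cannot be estimated from less. θ_0 (mononucleotide)
and Φ_0 (dinucleotide joint) come from the same fit; IC uses θ_0 only,
while LLR uses the full order-3 chain.

## Mining thresholds

λ_f is derived from P_occ, the probability that one randomly mutated
instance of the consensus equals one *specific* mutated word. The i-th
mutation class has binomial mass P_d(i) spread uniformly over C(l,i)·3^i
words, so P_occ sums P_d(i)/(C(l,i)·3^i) for i = 1..d. The i = 0 term is
excluded by default: the exact consensus is not a mutated instance, and
only the i ≥ 1 form reproduces the worked threshold λ_f = 0.02667 for
(6,1), p_con = 0.8, ZOOPS; `include_exact_term=True` restores the full sum
for comparison. λ_f is clamped into its validity range [1/|S_t|, 1] with a
logged warning.

Word frequency f(u, S) is the total occurrence count divided by the number
of sequences (matching the worked example's arithmetic, 19/600 = 0.0317),
for all three occupancy models; a sequences-containing-u variant
(`freq_mode="presence"`) is available since the validity range 1/|S_t| ≤
λ_f ≤ 1 suggests per-sequence presence. A word absent from the control set
has growth rate +∞ and passes any λ_g.

Choosing the mining conservation parameter deserves care: p_con enters only
through λ_f, and *smaller* p_con (higher conservation) gives a *lower*
threshold — the mutated mass concentrates on fewer words, so each specific
neighbour is expected to be rarer. At desk scale (hundreds of sequences)
λ_f derived from p_con = 0.2 admits words at ~3 occurrences per 600
sequences, which floods the seed list with Poisson coincidences; the
default p_con = 0.8 keeps the count threshold above the background
expectation while still trivially catching the consensus and its common
neighbours. The recovery study below runs discovery at defaults for exactly
this reason.

Emerging seeds are capped at 1000 per length (descending test count) as a
guard against pathological inputs; typical runs produce a few dozen to a
few hundred.

## Neighborhood qualification

All E = Σ C(l,i)·3^i words at Hamming distance 1..d are scored
independently with the pooled two-proportion z statistic on window counts
(degenerate pooled rates return z = 0 rather than NaN). Qualification
keeps every instance with z > 1.643 (one-sided 5%); instances are grouped
by their mutated-position set — a single position at d = 1 — and a group
with no instance above threshold contributes its maximum-positive-z member
instead, if any. The reference word always qualifies. Grouping by the
position *tuple* at d ≥ 2 is this package's reading of the per-position
fallback, chosen because it reduces exactly to the published per-position
behaviour at d = 1.

Qualified instances are weighted by their occurrence counts (test counts in
M1; control counts rescaled by N1/N2 in M2), not counted once: the count
matrices are explicitly built "by adding up the counts", and unweighted
construction would discard enrichment magnitude. The same qualified word
set feeds both matrices.

### Pseudocounts

"5% pseudocounts per position" is implemented as 5% of the column's
post-subtraction total, split evenly over the four letters (16 cells for Φ
tables); a flat +0.05-per-cell alternative is exposed. A column of
M = max(M1 − M2, 0) that is entirely zero becomes uniform, with a log
message.

## Clustering

Motifs are agglomerated greedily in descending-IC order. Similarity is the
Harbison score max over admissible overlap alignments of 1 − D, with D the
per-column Euclidean distance normalized to [0, 1]. The minimum overlap is
7 columns, relaxed to 5 (capped at the shorter motif) only when a motif is
shorter than 7. Ties between equally similar shifts prefer the smaller
|shift|, negative before positive, so clustering is deterministic given
input order.

Two choices here departed from the most obvious construction, both for the
same reason — under the scoring statistic above, weakly covered columns
poison a motif:

* **Membership is judged against the cluster's founding (highest-IC)
  model**, not the growing merge. A drifting representative widens the
  admissible-shift window at every join and accretes shifted fragments
  without bound (merges from an 8-mer seed were observed to reach length 14
  on synthetic data, at which point no window in the test set scored above
  the μ ≥ 0 grid). Founder-based membership keeps all members within
  ±(l − min_overlap) of the seed.
* **Merged normalization ties the pseudocount mass to the best-covered
  column** (5% of the maximum column total, applied to every column) rather
  than each column's own total. Counts are summed at the best shift over
  the union of covered columns, and a column contributed by a single
  low-count member would otherwise normalize to a spuriously near-certain
  distribution.

Merged Φ tables are rebuilt from the summed dinucleotide counts, not
interpolated. Reverse-complement orientations are compared only in
both-strands mode. Merged IC is recomputed from the merged model.

## FDR thresholding and output

FDR(μ) = (I2·N1/N2)/I1 over the integer grid μ = 0..⌈max LLR⌉, defined as
0 when I1 = I2 = 0 and +∞ when I1 = 0 < I2. The selected μ is the smallest
integer with FDR below the limit (0.2 by default), maximizing sensitivity
among valid thresholds; if none qualifies the motif is excluded from the
report. Motifs with no predicted site at their selected μ are likewise
excluded as vacuous. Reported motifs are sorted by IC (ties: larger
supporting count, then seed), truncated to the top 50. Consensus strings
use the argmax letter per column, lowercased where the maximum probability
is below 0.5.

Both-strands processing is off by default — the counting formulas are
strand-agnostic — and is exposed as a flag; minus-strand sites are reported
on forward coordinates.

## Synthetic data generator

`make_background` draws i.i.d. (or supplied-Markov) sequences; defaults
emulate the discovery setting of peak-centered 200 bp test segments and
500 bp flanking controls, 600 of each. `plant_motif` implants instances of
a consensus: exactly one per sequence (OOPS), Bernoulli(occupancy) (ZOOPS,
default 0.8), or Poisson(occupancy) capped by capacity (TCM — the
two-component-mixture occupancy is not pinned to a distribution anywhere,
so the generator documents its own choice). Each instance mutates exactly
i ~ Binomial(d, p_con) positions at uniform positions and letters — the
same process the λ_f derivation assumes. Placement is uniform without
overlap; ground truth is returned and can be written as BED.

What the generator does *not* emulate: real peak sets have non-uniform,
GC-biased, repeat-containing backgrounds, position-dependent motif
placement (centrally enriched in peaks), co-occurring cofactor motifs, and
control sets that share genomic composition with the test set. Passing the
recovery study therefore demonstrates the machinery — mining thresholds,
qualification, merging, FDR control — under the idealized mutation model,
not performance on real ChIP-seq.

## Recovery study and problem sizes

The acceptance-level study plants an (8,1) motif with p_con = 0.2
(high conservation: 80% exact copies) under ZOOPS occupancy 0.8 into
600×200 bp test sequences against 600×500 bp uniform controls, and runs
discovery at default parameters restricted to l = 8 — the planted length,
keeping the study focused and fast (~3 s). Across ten generator seeds the
top-IC reported motif's consensus contained the planted consensus exactly,
site-level recall at the selected μ ranged 0.78–0.84 (the exact-copy
fraction — single-mutation instances score below the pair-penalized
threshold), and observed FDR stayed below 0.01. The unit suite uses smaller
fixtures (80–200 sequences) for speed.

## Known limitations

* The U·V double count makes LLR thresholds conservative for mutated
  instances: a single interior mutation pays one letter term plus two pair
  terms. Recall at the default FDR limit is therefore dominated by exact
  and edge-mutated instances.
* The integer μ grid starting at 0 cannot rescue a motif whose best windows
  score below 0 nats; such motifs are dropped rather than re-thresholded.
* Greedy IC-ordered clustering is order-stable but not globally optimal; a
  model similar to two founders joins the first.
* Memory scales with the window matrices (n_windows × l int8) cached per
  length during scanning — negligible at desk scale, ~1 GB per length at
  the 50 Mb upper end, where streaming would be preferable.
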