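# Methods

## Models

**i.i.d. (position-independent) models.** A model N assigns each base a
fixed probability P_N(i), i ∈ {A, C, G, T}, so the probability of a
sequence x of length L with base counts c_i is
P(x|N) = Π_i P_N(i)^{c_i}, and the raw score is
log2 P(x|N) = Σ_i c_i log2 P_N(i), in bits. The fixed-GC family is
symmetric within the GC and AT pairs: P(G) = P(C) = gc/2,
P(A) = P(T) = (1 − gc)/2; gc = 0.5 is the uniform model. The *target*
model refits P to the scored sequence's own maximum-likelihood
frequencies c_i/L; it is the full 4-parameter frequency model, not a
GC/AT-pooled one. Background models pool ML frequencies over a sequence
collection. Zero probabilities are representable: a raw score may be
−∞ (a base present in x but impossible under N) and is an ordinary
minimal score, never NaN; a log-odds where family and null are both −∞
raises a distinct error rather than producing NaN silently.

**Weight array matrices.** A WAM of order k stores, per position p, the
conditional distribution of the base at p given the k preceding bases
(marginals for p ≤ k). Default k = 1 (adjacent-dinucleotide
dependencies, the classic WAM; k = 0 degenerates to a PWM). Estimation
uses additive smoothing, P_p(b|ctx) = (n(ctx,b) + α)/(n(ctx) + 4α) with
default α = 1: random negatives inevitably contain dinucleotide contexts
absent from motif training sets, and α = 0 would make them unscorable.
With α = 0, unobserved contexts are marked *unusable* and scoring
through one raises an error — deliberately distinct from the −∞ returned
for a zero-probability base at an observed context. Consensus positions
are modelled like any other position; the training data makes them
near-deterministic, up to pseudocount dilution.

**Log-odds.** S(x) = log2 P(x|F) − log2 P(x|N), equal priors, positive
call iff S > 0 strictly (S = 0 is negative). All scores are in bits; the
sign/threshold structure of every result is base-invariant, log2 is
simply fixed and documented. The null-swap identity
S_N(x) = S_U(x) + log2 P(x|U) − log2 P(x|N) adapts scores computed
against a hard-wired uniform null to any other null; it is algebraically
exact and is tested against direct scoring to 1e-9. A new null assigning
x probability zero makes the swapped score +∞; this degenerate case is
flagged with a warning rather than raised, since the caller may
legitimately want "the null rules x out".

## The stratified generator

For each W = j/100, j = 0..100: K1 = ⌊L_free·W⌋ bases drawn uniformly
over {G, C}, L_free − K1 over {A, T}, concatenated and shuffled by a
uniform permutation of the positions (numpy's `Generator.permuted`,
equivalent to Fisher–Yates). A consensus motif, when present, occupies
fixed positions excluded from the random construction (L_free = L − |motif|)
and contributes its own bases to the recomputed composition. Sequences
are binned by the integer mark round(100·gc/L), rounding half away from
zero in exact integer arithmetic; each occupied mark is pruned to
exactly N sequences, keeping the first N in generation order (batches
are deterministic in composition, so this keeps whole batches). Mark
collisions make the totals a pure arithmetic consequence of (L, motif):
3150 at L = 62, 5050 at L = 100, 3450 at L = 70 with AG at 49–50. All
randomness flows from one seeded `default_rng`; datasets are
reproducible byte for byte. The generator emits strict ACGT only — no
IUPAC ambiguity mode — and performs no dinucleotide-preserving shuffles.

## Synthetic family models

Real curated training sets (splice-site databases, RNA-family
alignments) are emulated by a ground-truth acceptor-like WAM: every
non-consensus conditional distribution is drawn from a Dirichlet centred
on the symmetric fixed-GC distribution at the requested average GC, with
concentration 10 (moderate position-specific preferences — informative
but not degenerate positions, the regime in which real splice-site WAMs
operate); consensus positions (the acceptor AG) are point masses.
Training sets of 1000 sequences are sampled from the truth and a WAM is
fitted back with k = 1, α = 1 — so the scored family model carries
exactly the kind of estimated compositional bias the study is about.
The default family GC levels are 38%, 50% and 65% (low / medium / high),
the spread observed in GC-partitioned acceptor-site training data; the
labeled benchmark uses a 19%-GC genomic background with a 25%-GC family
to emulate a strongly AT-rich genome.

What this emulation does *not* reproduce: real splice-site structure
(branch point, polypyrimidine tract lengths), non-AG consensus
violations, genomic negatives drawn from a real genome's composition
(our negatives are GC-stratified by design, which is what makes the
per-mark analyses possible), and any secondary-structure-aware family
model — scores for such models are accommodated only through the
null-swap adapter. Passing tests therefore demonstrate the
composition-bias mechanics of null-model choice, not absolute
performance numbers on any real dataset.

## Experiment sizing and numerical choices

* Study default N = 50 per mark: forced by 5050 = 101 × 50 at L = 100;
  it is the scale at which specificity counts are stable.
* The **peak-location** analysis (per-mark mean target-null log-odds of
  an i.i.d. family of GC g peaks at mark round(100·g)) uses N = 30000
  per mark. The peak is real but shallow: between adjacent marks the
  mean changes by ~0.03 bits, while the within-mark spread contributed
  by the random G/C and A/T splits is ~1.4 bits, so the argmax of a
  per-mark mean needs ~10⁴–10⁵ sequences per mark to be a stable
  statistic. 30000 gives a ≥4σ margin for the adjacent-mark comparison
  at g = 0.5 (the flattest case) and runs in well under a minute
  vectorised.
* WAM parameter recovery is checked on 10000 samples from a truth WAM
  whose conditionals are Dirichlet(10,10,10,10) draws: probabilities
  stay in a range where every context is observed ≥ ~1000 times and the
  ML estimate's 3σ error stays below the 0.05 tolerance.
* Percentages in count tables are rounded half away from zero to
  integers; denominators are always reported explicitly.
* Undefined precision (no positive prediction) is reported as absent
  (None/NaN), never as zero; per-mark PR points require strictly more
  than 5 positive samples at the mark, and failing marks are omitted,
  not zero-filled.
* Tie-breaks: `argmax`/`idxmax` take the first of tied marks; ties do
  not occur at the sample sizes used.
* The ROC sweep (`roc_points`) is convenience output only.

## Known limitations

* The generator's mark bookkeeping reproduces the printed set sizes at
  L = 62, 100 and 70 + AG, but at L = 164 the same rule yields 4250
  (85 occupied marks), not 5050; the binning that would produce 5050 at
  that length is not reconstructible, so no count is forced there.
* The target null's dominance inequality S_target ≤ S_fixed is exact
  per sequence; its *strictness* in aggregate (strictly fewest positive
  counts) is an empirical property of the synthetic families and holds
  at the default study conditions.
* Order k and pseudocount α of the WAMs are exposed as parameters rather
  than fixed: defaults k = 1, α = 1.
* No order-≥1 Markov nulls, reversed-sequence or composite nulls, no
  E-value/p-value calibration, no best-path (Viterbi-style) scoring and
  no genome scanning.
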