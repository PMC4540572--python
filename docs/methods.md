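# Methods

## Binding model

An mPWM over an L-bp site consists of an independent L×4 matrix (columns
A,C,G,T) and zero or more dependency groups, each a 4^d table (d ∈ {2,3})
over the joint nucleotides of d distinct, possibly non-adjacent positions.
Positions belong to at most one group; the independent positions are the
complement of the group-covered set. A window's score is the sum of the
independent-position weights plus, per group, the weight of the tuple read at
the group's positions in their declared order. Matrix rows at group-covered
positions are kept in the file for positional readability but never scored;
the weight converter writes zeros there.

Count matrices hold raw tallies, frequency matrices per-block relative
frequencies (each independent row and each group table sums to 1, tolerance
1e−6 for text rounding), weight matrices the natural-log ratios
W = ln(f / f_max) per block. Under that normalization the maximum of every
block is 0, so the maximal window score — attained by the consensus: argmax
nucleotide per independent position, argmax tuple per group — is 0. Because
groups are position-disjoint, the maximal score is computable blockwise
without enumerating 4^L sites. Only the natural logarithm is supported.

A model whose group tables carry product-of-marginals frequencies scores
every site identically to the group-free PWM built from the same marginals
(max of a product of independent marginals = product of maxes), which is the
sanity anchor for the dependency machinery and is enforced in the tests.

## Building models from alignments

`counts_from_alignment` tallies per-position counts at **all** positions and
joint d-tuple counts per declared group, so group tables always marginalize
to the matrix rows at member positions. `frequencies_from_counts` applies
additive smoothing: f = (c + pc)/(N + 4·pc) per position and
f = (c + pc)/(N + 4^d·pc) per group tuple. The default pseudocount is 0.5
per cell — standard small-sample smoothing; with it, weights are finite for
any alignment, a site seen once scores 0 at its own nucleotides, and every
mismatch scores negative.

Symmetrization (for TFs binding as head-to-head dimers) averages the model
with its reverse complement **in count/frequency space** — averaging log
ratios would break the max-0 normalization — and requires the group layout to
be mirror-consistent (each group's mirrored position set is itself a declared
group). The result equals its own reverse-complement model and is a fixed
point of the operation.

`revcomp_model` maps position p to L+1−p, complements nucleotide columns,
re-sorts each group's mapped positions ascending and re-keys its table along
the induced permutation with complemented bases; it satisfies
score_rc(s) = score(revcomp(s)) for all sites and is an involution.

## Scanning

Every window start on the forward strand yields up to two hits: the window
scored as read (+) and its reverse complement (−), both reported at the same
forward-strand start so a single coordinate axis serves plotting and
occupancy. Windows containing N are skipped entirely — no penalty score is
invented for ambiguous bases; lowercase (soft-masked) input is scored as
uppercase, and any non-ACGT letter is normalized to N on input. Modes:
`all` (every hit), `threshold` (score ≥ limit; inclusive, so a published
cutoff retains sites exactly at it), `best` (single top hit, ties broken by
smallest start, then + strand). Overlapping and nested hits are all reported;
occupancy needs them. Sequences shorter than L produce no hits, not an error.
TSV output is 1-based inclusive (stated in its header); the API is 0-based
half-open.

## Occupancy

Kd = exp((b − score)/a) with a > 0, so Kd is strictly decreasing in score;
the binding probability is the single-site isotherm p = [X]/([X] + Kd),
p = 0.5 exactly when [X] = Kd. Defaults: a = 1, b = 0; when no concentration
is supplied, [X] = e^(b/a), which pins the maximal-score site (score 0 for a
normalized model) at p = 0.5. Note the units: shifting b by c multiplies
every Kd by e^(c/a), so probabilities are invariant under b → b+c combined
with [X] → e^(c/a)·[X].

Region occupancy is the **sum** of per-site probabilities over both strands —
the expected number of bound sites — optionally restricted to scores ≥ limit.
The sum (rather than 1 − Π(1−p)) keeps occupancy additive across sites and
regions, matching its use for comparing regions. Known limitation: no steric
exclusion or TF–TF competition; overlapping sites (including a palindromic
site counted on both strands) contribute independently, so occupancy can
exceed what a physical lattice model would allow in dense clusters.

## ROC evaluation

The per-sequence statistic is either the best-site score or the predicted
occupancy. Thresholds sweep the distinct pooled values from +∞ downward with
the rule statistic ≥ t → "bound"; the curve runs (0,0) → (1,1) and the AUC is
its trapezoidal area, which equals the Mann–Whitney probability
P(pos > neg) + ½·P(pos = neg) exactly (ties produce diagonal segments).
Direction is fixed as higher = bound; a model worse than chance shows AUC
< 0.5 rather than being silently flipped. Records shorter than the model are
dropped with a logged count. No confidence interval is attached to the AUC.

## Synthetic data

The fixtures module generates all test inputs; everything is deterministic
per seed (numpy `default_rng`).

* **Random models**: per-position and per-group frequencies from a flat
  Dirichlet, converted to weights; group positions sampled disjointly.
* **Backgrounds**: order-0 i.i.d. sequences with a chosen GC content
  (default 0.5, split equally between G and C). No Markov structure, no
  repeats, no soft-masking — the simplest null for random genomic sampling.
* **Positives**: the model's consensus written at random non-overlapping
  positions (rejection sampling, capped at 10,000 attempts), on a chosen or
  random strand, with ground truth recorded.
* **Negative sets**: one negative per positive with the identical length,
  rejection-sampled anywhere in the supplied genome such that it overlaps no
  positive interval and no other negative (cap 10,000 attempts per interval;
  failure reports the lengths that could not be placed). Chromosomes are
  chosen uniformly, not length-weighted.

Passing tests on these fixtures show the machinery is correct (scoring,
coordinates, strand bookkeeping, the isotherm, ROC identities); they do not
show that an mPWM predicts in-vivo binding — real promoters have repeat
structure, composition bias and co-factor context absent from an order-0
background.

## Numerical choices and problem sizes

Exhaustive scoring oracles run at L ≤ 6 (4^L enumeration); scan oracles use
seeded ≤ 1 kb sequences; the negative-sampler check uses a synthetic 1 Mb
genome; null-AUC checks use 100 sequences per class against the Mann–Whitney
null standard deviation. Score agreement is asserted at 1e−9 (sums of ≤ ~20
logs; double precision leaves ample headroom), revcomp/symmetry identities at
1e−12. Model files serialize floats with Python's shortest round-trip repr,
making parse∘write exact. Dependency tables are written in lexicographic
tuple order (AA..TT / AAA..TTT) for deterministic serialization; ties in
consensus extraction resolve to the alphabetically first nucleotide or tuple.
TSV outputs round scores and occupancies to 6 decimals and contain no
timestamps, so reruns are byte-identical.

## Out of scope

Dependency detection (groups are user input), de-novo motif discovery,
import of JASPAR/TRANSFAC/MEME formats, non-DNA alphabets, k-mer/HMM models,
fitting (a, b) from affinity data, cooperative or competitive binding, and
genome-scale indexed scanning.
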