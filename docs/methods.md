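# Methods

## Quality model

A phred score Q encodes the probability that a called base is wrong as
P_err = 10^(−Q/10); the complementary correctness probability is
p = 1 − 10^(−Q/10). We assume base errors are independent given the
qualities, so the probability that the k-window starting at position i was
read correctly is the product P_{w,i} = ∏_j (1 − 10^(−Q(i+j)/10)). Scores
are decoded from FASTQ with offset 33 by default (offset 64 available);
decoded values are capped at 93 — the highest value Sanger FASTQ can encode
— and a warning is logged if more than 10% of bases exceed 60 under offset
33, the signature of a phred+64 file read with the wrong offset.
Programmatically constructed reads may carry qualities beyond 93; this is
deliberate, since 1 − 10^(−q/10) rounds to exactly 1.0 in double precision
once q > 160, which is the clean way to express "this base is certain" in
tests and controls.

## Word counting

Words of length k over {A,C,G,T} are indexed lexicographically (A<C<G<T)
via 2-bit codes; windows are half-open [i, i+k) and overlap freely. Any
window containing a non-ACGT base (N, ambiguity codes) is skipped in both
the plain counts X_w and the quality-weighted counts X_w^q — assigning an
arbitrary quality to an uncalled base would put invented mass into the
statistics. The "number of positions" n−k+1 appearing in expected-count
terms is consequently the number of *valid* windows for that read.

Optional reverse-complement mode pools each word with its reverse
complement into the canonical (lexicographically smaller) index;
palindromic words are not doubled. The expected-count term pools the same
way: the expectation of a pooled count is the sum of the two words'
expectations, so the product vector n·p_w·E(P_w) is pooled, not p and E
separately.

## Quality redistribution

A base called with correctness p leaves mass 1 − p on its three
alternatives. Redistribution credits, for each position j of an occurrence
and each alternative base a, the neighbour word w' = w with position j
substituted by a, with mass

    (1 − p_j) · f(a) / Σ_{a'≠called} f(a') · ∏_{l≠j} p_l

where f are the read's base frequencies (a dataset-global override exists).
Only single-base substitutions are generated — simultaneous two-base errors
contribute O((1−p)²) mass at quadrupled cost. If a read's composition
contains zeros, frequencies get a pseudocount of 0.5 per base before
normalisation so the weights remain defined for degenerate (e.g.
homopolymer) reads. The original word always keeps its full P_{w,i}, so
one occurrence can deposit up to 1 + (k·(1−p)-ish) total mass across its
neighbourhood; the per-position credit is bounded by the missing mass of
that position.

The vectorised implementation computes leave-one-out window products with
forward/backward cumulative products; a simple per-occurrence loop
(`substitution_credits`) implements the identical rule and the two are
cross-checked against an independent string-based oracle in the tests.

## Expected word probabilities

E(P_w) is estimated once over the whole read set, never per cluster or per
iteration:

- **AWP** — Σ_x X_w^q / Σ_x X_w, the mean occurrence probability of w.
- **AQP** — the per-position mean phred Q̄_w[j] over all occurrences,
  converted back: E(P_w) ≈ ∏_j (1 − 10^(−Q̄_w[j]/10)). Averaging on the
  phred (log) scale before exponentiating makes AQP slightly more
  optimistic than AWP on heterogeneous qualities (Jensen), which matches
  its observed stability.

Both estimators consume *non-redistributed* occurrence probabilities even
when redistribution is enabled for the profile vectors: redistribution is a
modification of X_w^q, and feeding it back into E(P_w) would make the
centring circular. Words never observed in the dataset fall back to the
dataset's mean per-base correctness raised to the k — a neutral value that
keeps D₂*^q denominators finite without distorting observed words.

## Pairwise statistics

Centred counts use each read's own i.i.d. background: p_w is the product of
the read's base frequencies over the letters of w. For two reads of
different lengths and compositions the single-n denominator of D₂\* is
undefined, so the cross term uses the geometric mean
√(n_X·p_w(X)·E_w · n_Y·p_w(Y)·E_w), which is symmetric and collapses to the
single-n form when the reads share n and composition. Terms with a zero
denominator (p_w = 0, or X̃ = Ỹ = 0 for D₂ˢ) contribute 0 — the limit
value — rather than raising.

KL-type measures add a pseudocount of 1/4^k to every entry before
normalising and use base-2 logarithms; the symmetrised version averages the
two directions. Base and pseudocount affect scale only, not rankings.

Similarities become dissimilarities through the cosine-style transform
d = 1 − S_xy/√(S_xx·S_yy), clamped to [0, 2]. At perfect quality
(correctness exactly 1) X^q = X and E ≡ 1, so every quality-weighted
statistic equals its classical counterpart at machine precision; this
reduction is asserted exactly in the tests.

## Clustering

Lloyd-style k-means under any configured measure. Centroids are arithmetic
means of member vectors — quality-weighted counts for the D^q measures, raw
counts for D-types, frequency-normalised vectors for L₂/KL — with the
centroid's expected-count term built from the mean of the members' valid
window counts and base frequencies. Initial centroids are c distinct
profiles drawn uniformly without replacement; run r of the multi-restart
uses seed + r, and profiles are ordered by read id internally so results do
not depend on input order. Assignment ties break toward the lowest centroid
index; an emptied cluster is reseeded with the profile farthest from its
current centroid.

Because the centred and KL measures do not guarantee monotone convergence,
each run tracks the best (lowest-distortion) assignment seen and stops at
an assignment fixpoint, at `max_iter` (default 100), or after
`max_no_improve` (default 10) iterations without improving on the best
solution; the best solution — not the last — is returned, and the best of
the `runs` restarts (default 5) wins. Distortion is the sum of members'
dissimilarities to their assigned centroids.

## Recall rate

For each source sequence S, the cluster C holding the plurality of S's
reads is found (ties toward the lowest cluster index) and recall(S) is the
fraction of S's reads in C; the reported value is the unweighted mean over
sources. The definition is degenerate for c=1 (everything scores 1.0), so
it is only meaningful at a fixed cluster count.

## Simulator

The generator emulates a controlled read-simulation experiment at desk
scale. References are order-1 Markov chains by default: each reference
draws a base composition from Dirichlet(25·1) (per-component sd ≈ 0.04,
a realistic spread of compositional diversity among transcripts) and
transition rows from Dirichlet(composition × 20), giving every reference
its own dinucleotide character the way real transcripts differ in, e.g.,
CpG content. This matters: the centred D-type statistics normalise away
each read's own composition, so i.i.d. references would leave them almost
nothing to work with, which is a property of i.i.d. toy data, not of the
statistics. Plain i.i.d. generation (`markov_order=0`) and explicit
compositions remain available as controls.

Reads sample a reference and a start uniformly. Per-base phreds follow an
Illumina-like profile — mean declining linearly along the read (default
38 → 20) plus integer Gaussian noise (sd 3), clamped to [2, 40] — and each
base is substituted with probability 10^(−Q/10), so qualities are
statistically consistent with the injected errors. Optional extra channels:
additional mismatches at a configured rate (the colliding base's quality is
lowered to at most −10·log₁₀(rate), keeping qualities informative),
insertions (a uniform random base emitted without advancing along the
reference) and deletions (a reference base skipped); reads keep fixed
length by continuing to walk the reference, which must be long enough to
cover a read plus a 3σ deletion margin.

What the simulator does *not* model: position-dependent error spectra,
homopolymer-specific indels, paired ends, platform-specific quality
miscalibration, and real transcriptome redundancy (paralogs, splice
isoforms, shared domains). Passing clustering tests on this generator shows
the statistics exploit quality signal and k-mer structure as designed; it
does not certify recall numbers on real libraries, where between-reference
similarity is the binding constraint.

## Problem sizes in the test suite

The bundled experiments run at desk scale, chosen to exercise the full
pipeline while keeping the suite quick: the separability check uses 500
error-free reads of length 200 from 2 references (k=2, c=2, every measure,
recall ≥ 0.95); the quality-signal comparison uses 3-reference mixtures of
3000 reads at ~10% quality-consistent mismatch rate (flat mean phred 10)
over 10 seeds, comparing median recall of D₂*^q (AQP) against D₂\* at
k=2, c=3. Oracle-agreement suites use 50 random profile pairs at
k ∈ {1,2,3} with a relative tolerance of 1e−9.
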