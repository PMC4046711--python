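# Methods

This note documents the models implemented in `mpalign`, the defaults and
their rationale, the numerical choices, what the synthetic benchmark does
and does not emulate, and the package's known limitations.

## Joint substitution model

All scoring rests on a position-independent joint symbol-pair probability
P(a, b): symmetric, strictly positive, summing to 1 over ordered pairs,
with marginals p(a) = Σ_b P(a, b).  It serves simultaneously as the
pair-HMM match-state emission and as the data term of the message-passing
update.

* **Protein default** — the published BLOSUM62 target (qij) frequency
  table, symmetrized and renormalized (the 4-decimal published entries sum
  to 0.9987 over the full symmetric table).  Internal consistency check:
  converting the table back to half-bit log-odds against its own marginals
  reproduces the published integer BLOSUM62 scores for 92% of pairs exactly
  and all pairs within ±1.5 half-bits — the residual is the rounding noise
  of the 4-decimal frequencies.  Any alternative table can be supplied as a
  text file (alphabet header plus full or lower-triangular matrix); the
  algorithms are agnostic to the specific table.
* **Nucleotide default** — a one-parameter scheme with uniform marginals:
  total mismatch probability 0.2 spread evenly over the twelve ordered
  mismatch pairs.
* **Ambiguity codes** (X/B/Z/J for protein, IUPAC for nucleotide) are
  marginalized over their compatible residues, weighted by the model
  marginals.  This keeps real FASTA input from hard-failing without biasing
  scores.  `*` and `-` are rejected in unaligned input.

## Pair-HMM

Three hidden states: M emits an aligned pair from P(a, b); I_x and I_y emit
a single symbol (default emission: the model marginals, which keeps the
match/insert odds ratio interpretable).  Two topologies: `full` (insertion
states may interchange) and `no_ix_iy` (those transitions blocked).  The
full topology makes the path→alignment map many-to-one — for x = AAACGG,
y = AAATTA, twenty distinct paths produce the alignment
{(1,1),(2,2),(3,3)} — while the blocked topology cannot produce that
alignment at all; both facts are asserted in the test suite, and this
state-path ambiguity is the motivation for scoring symbol pairs rather than
whole paths.

Transitions derive from three interpretable parameters: gap-open δ
(M→I_x = M→I_y, default 0.02), gap-extend ε (I_x→I_x, default 0.7), and a
single termination probability τ shared by all states (default 0.01, mean
sequence length ≈ 1/τ).  In the full topology the I_x→I_y switch equals δ.
The start distribution is (1−2δ, δ, δ).  These defaults are ProbCons-like
in structure; they are not a reproduction of any published fitted values.
An explicit END is also reachable from the virtual START with probability
Σ_s start(s)·τ(s), so a model with τ = 1 everywhere generates the empty
pair; non-empty paths carry the complementary factor.

All recursions (forward, backward, Viterbi) run in log space with
log-sum-exp, jit-compiled with numba.  Full-table routines are used for
posterior decoding; the total observation probability additionally has a
constant-memory rolling recursion with emissions computed on the fly, used
for very long sequences (a 10,000 × 10,000 forward pass needs O(M) memory).
Posterior matrices are clipped to [0, 1] against rounding noise; Viterbi
traceback ties break toward M, then I_x, then I_y.

## Message passing

The confidence matrix C is iterated as

    c'(i,j) = λ·½·[c(i−1,j−1) + c(i+1,j+1)] + (1−λ)·P(x_i, y_j),

synchronously (every cell reads the previous iteration; this is what makes
the sweep trivially parallelizable), with out-of-range neighbors
contributing zero, followed by spectral-norm normalization C ← C/‖C‖₂ and a
Frobenius-norm convergence test on the normalized difference (default tol
1e-6, max_iter 1000).  Design choices that were genuinely open:

* **Neighbor aggregation**: the two messages are averaged (½·sum), keeping
  the λ convex-combination reading of the update; with the spectral
  normalization the fixed point is identical up to scale to the summed
  variant at a reweighted λ.
* **Initialization**: `random` (i.i.d. uniform(0,1), seeded), `uniform`
  (all ones), or `seed_alignment` (indicator of a preliminary alignment).
  Empirically the converged matrix is independent of the random seed for
  λ < 1: the update is an affine contraction (the neighbor operator has
  spectral norm ≤ 1, scaled by λ) followed by projection onto the unit
  sphere, so iterates forget the start.  `random` is the default.
* **Spectral norm** is computed by power iteration on AᵀA with a
  deterministic nonnegative start vector (never orthogonal to the Perron
  vector of a nonnegative matrix), warm-started across sweeps; convergence
  is declared on the eigenvalue residual (tolerance 1e-10), with an exact
  SVD fallback for small matrices if the iteration stalls.
* **Coordinates** are 1-based and inclusive everywhere in the public data
  model and on disk.

λ controls gap behavior: at λ = 0 the matrix is the bare data term; larger
λ propagates support along diagonals, which penalizes gap openings.  The
test suite verifies the implied invariant (mean gap openings in the MEA
alignment at λ = 0.75 ≤ that at λ = 0.25 over 100 simulated pairs) and the
monotone SN trend in λ.  The default λ = 0.75 is the most accurate of the
three canonical settings (0.25, 0.5, 0.75) on every benchmark slice we
compute.

## MEA decoding

Any nonnegative score matrix is decoded with the Needleman-Wunsch-style
recurrence D(i,j) = max(D(i−1,j−1)+S(i,j), D(i−1,j), D(i,j−1)), zero gap
scores, deterministic traceback (diagonal, then up, then left).  A pair is
included only if S(i,j) > 0, so tied-at-zero regions are left unaligned
rather than padded with meaningless pairs.  An exhaustive enumerator of all
monotone matchings (guarded to sides ≤ 8) serves as the brute-force oracle.

## Synthetic benchmark and what it shows

Benchmark pairs are sampled from the generative pair-HMM, so the truth (the
M columns of the sampled path) is exact.  Divergence is a single knob
t ∈ [0, 1] that geometrically flattens the joint emission toward the
product of marginals, P_t ∝ P^(1−t)·(p pᵀ)^t: t = 0 gives ~33% identical
true columns under the protein default, t = 1 gives ~6% (chance).  The
shipped study conditions — 200 pairs, t = 0.5 (≈15% column identity,
comparable to "twilight zone" orphan pairs), min length 50 (mean length ≈ 140 after the minimum-length resampling),
δ = 0.02, ε = 0.7, τ = 0.01, full topology — were fixed once as a realistic
low-identity regime.

What passing tests show: the scorers and decoders are exact against
enumeration oracles; the message-passing contracts (normalization, fixed
point, determinism, λ-monotonicity of gaps and of SN) hold; everything is
finite at length 10,000.

What they do not show: real-benchmark accuracy rankings.  On data generated
by the pair-HMM itself, the inference pair-HMM shares the generator's exact
transition structure, so forward-backward posterior decoding is close to
Bayes-optimal there and outscores message passing (mean SN ≈ 0.58 vs 0.31
at the shipped conditions) — an inherent bias of a pair-HMM-generated
surrogate in favor of the pair-HMM baseline.  Real curated protein
benchmarks, where no method matches the generating process of evolution,
are a different regime, and relative method rankings measured here do not
transfer to them.  The λ trend (higher λ, higher SN/PPV) is reproduced on
the synthetic data.

## Degenerate inputs and edge cases

Empty sequences are rejected by the aligners; an all-zero score matrix
cannot be normalized (raised as a numerical error); a seed alignment must
fit the sequence lengths; `no_ix_iy` parameter sets with nonzero insert
switches are rejected at construction; non-terminating samplers (all τ = 0)
are refused.  All probabilities are validated to sum correctly within 1e-9
at construction time.

## Problem sizes

Default test and reproduction sizes — 200 benchmark pairs of mean length
~100, 100-case enumeration cross-checks at total length ≤ 8, one
10,000-length robustness pair — keep a full run on a single CPU in the
low minutes while leaving every statistical check with ≥ 3σ separation.

## Known limitations

* No training of emissions or transitions from data (tables are inputs).
* MEA is global; no local (Smith-Waterman-style) variant, no affine gap
  penalty inside the MEA step, single best alignment only.
* Posterior decoding at length 10,000 needs the full tables (~5 GB); only
  the total-probability recursion is constant-memory.
* The aligned-FASTA rendering of a pair set places unaligned x residues
  before unaligned y residues between anchors; this is a documented
  convention, not information carried by the pair set.
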