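# mpalign — pairwise sequence alignment by passing messages

`mpalign` aligns two biological sequences (protein by default, nucleotide
supported) by estimating, for every candidate symbol pair (x<sub>i</sub>,
y<sub>j</sub>), a **symbol alignment confidence score** c<sub>xy</sub>(i, j)
∝ P(x<sub>i</sub> ~ y<sub>j</sub> | **x**, **y**), and then decoding the
**maximum expected accuracy (MEA)** alignment from the score matrix by
dynamic programming.  It is aimed at people building or studying
probabilistic aligners: it ships both the iterative **message-passing**
scorer and a complete reference **pair-HMM** (Viterbi, forward/backward,
posterior decoding, generative sampling), plus an SN/PPV evaluation harness
and a synthetic benchmark generator with known column-wise truth.

## The method

Instead of modeling insertions and deletions generatively, the
message-passing scheme estimates alignment confidence directly.  Each pair
(i, j) repeatedly exchanges messages with its two diagonal neighbors
(i−1, j−1) and (i+1, j+1):

```
c'(i, j) = λ · [ c(i−1, j−1) + c(i+1, j+1) ] / 2  +  (1 − λ) · P(x_i, y_j)
```

with c(i, j) = 0 outside the matrix.  P(a, b) is the joint occurrence
probability of the symbol pair — the match-state emission of a pair-HMM;
the default protein table is the published BLOSUM62 target frequencies
renormalized to sum to 1.  The weight λ ∈ [0, 1] balances the neighbor
messages (gap-penalizing, favors long contiguous blocks) against the data
term (gap-lenient).  After each synchronous sweep the matrix is normalized
by its spectral norm, **C** ← **C**/‖**C**‖₂, and iteration stops when the
Frobenius norm of the change falls below a tolerance (default 1e-6).
Because only normalized local scores are propagated, there is no global
observation probability P(**x**, **y**) to underflow — the scheme stays
finite on sequences of length 10,000 and beyond, where probability-space
pair-HMM recursions fail (observation probabilities are already ~1e-230 at
protein length 80).

The three-state pair-HMM baseline (M, I<sub>x</sub>, I<sub>y</sub>; both
the full topology and the variant that blocks I<sub>x</sub> ↔ I<sub>y</sub>
transitions) is implemented in log space and doubles as the synthetic-truth
generator: sampled state paths yield sequence pairs whose M columns are the
exact reference alignment.  Predicted alignments are scored as aligned-pair
sets: SN = TP/(TP+FN), PPV = TP/(TP+FP).

## Worked example

Generate three synthetic homologous pairs at low identity, align one, and
benchmark both methods against the known truth:

```
$ mpalign simulate bench --n-pairs 3 --min-len 40 --seed 11
bench/manifest.json

$ mpalign align bench/pair_000.fasta --method mp --lambda 0.75 -o mp_out -v
INFO mpalign: method=mp lambda=0.75 init=random seed=0 tol=1e-06 max_iter=1000
              iterations=54 converged=True aligned_pairs=175 score=1.89219

$ mpalign benchmark bench --methods mp:0.25,mp:0.75,pairhmm --seed 0 -o metrics.tsv
mp:0.25   n=3  mean_SN=0.2153  mean_PPV=0.2703
mp:0.75   n=3  mean_SN=0.4243  mean_PPV=0.4522
pairhmm   n=3  mean_SN=0.5941  mean_PPV=0.6249
```

`mp_out.aln.fasta` holds the aligned pair (two records, `-` gaps);
`mp_out.pairs.tsv` the 1-based aligned index pairs.  The message-passing
run converged in 54 sweeps; mean sensitivity rises with λ (0.22 → 0.42
here), the expected monotone λ trend.  On this pair-HMM-generated data the
pair-HMM posterior baseline itself is near Bayes-optimal and scores highest
— see `docs/methods.md` for why that is a property of the synthetic
benchmark, not of real alignment benchmarks.  The same numbers are
reproducible from the library API (`mpalign.align_pair`,
`mpalign.evaluate_benchmark`).

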