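# Methods

This note documents the models, statistics and procedures implemented in
`motifselect`, the design choices made where the design was genuinely
open, and what the synthetic experiments do and do not demonstrate.

## Problem setting

A transcription factor (TF) recognises short DNA motifs (typically 6–12
nt). Given a *TFBS sample* — n aligned binding-site sequences of equal
length l over {A, C, G, T} — we want a generative model of the motif
good enough to classify new sequences as sites or non-sites. The
package implements two models at opposite ends of the
complexity/expressiveness trade-off, measures how much the extra
expressiveness buys on a given sample, and learns a rule that predicts
which model to use from cheap sample features.

## Position weight matrix (PWM)

The PWM assumes positional independence. Probabilities are estimated
with a data-dependent pseudocount:

    p̂(b_i, j) = (n_ij + ψ_i) / (n + Σ_i ψ_i),   ψ_i = α · f_i,   α = 1/(10 n)

where n_ij counts nucleotide b_i at position j and f_i counts b_i
anywhere in the sample. Scores are log-odds in bits against a
background (null) model q: W_ij = log2(p̂(b_i,j)/q(b_i)); a sequence
scores the sum of its per-position entries.

Because ψ_i = α·f_i is *zero* for a nucleotide absent from the entire
sample, p̂ cells can be exactly zero despite the pseudocount's smoothing
intent. We keep the formula verbatim: such cells score −∞, which
propagates through sums and ranks below any finite threshold. An
optional `min_prob` floor (default off) renormalises columns after
flooring for users who want finite scores everywhere.

The null model is either uniform (default in all synthetic experiments)
or genome mononucleotide frequencies; a zero frequency is floored at
1e-6 and the vector renormalised, because the log-odds denominator may
not vanish.

## Acyclic probabilistic finite automaton (APFA)

The APFA organises states in levels 0..l; every nucleotide edge moves
one level right, and every level-l state emits end-of-sequence (EOS)
into the final state. The probability of a sequence is the product of
edge probabilities along its unique path, so a state can condition the
next symbol's distribution on (an equivalence class of) the prefix read
so far — exactly the inter-position dependence a PWM cannot express.

Learning folds the sample's prefix tree level by level:

* **Similarity.** Two states are similar when the L1 distance between
  their gamma-smoothed next-symbol conditionals is ≤ `mu`. The L1 range
  is [0, 2]: `mu = 2` always merges (the APFA then factorises into the
  per-column model), `mu = 0` merges only identical conditionals.
* **Evidence.** Only states with arrival count ≥ `m0` participate in
  similarity comparisons. A state below `m0` lacks the evidence to
  stand alone and is folded into its most similar eligible neighbour
  unconditionally; if the level has no eligible state it is retained.
* **Order and closure.** States are examined in deterministic order
  (arrival count descending, ties by lexicographically smallest
  arriving prefix); similarity is closed transitively within a level
  (connected components merge). Merging two states also merges, per
  symbol, the subtrees they lead into, before the next level is
  processed. Determinism is required for reproducible cross-validation.
* **Smoothing.** Final edge probabilities are
  (count + γ)/(arrivals + 4γ). Since all sample sequences share one
  length, EOS mass is meaningful only at level l, where it is 1 from
  every state; interior smoothing is therefore over the 4 nucleotides
  and the EOS factor of every sequence probability is 1.
* **Completion.** Smoothing gives every interior state four positive
  edges, including symbols never observed there. Such an edge needs a
  destination: we route it to the heaviest state of the next level
  (largest arrival count, ties by smallest prefix). Any choice leaves
  the automaton stochastic — total sequence mass is 1 regardless —
  but the heaviest state has the best-estimated continuation.

Scoring is the log-odds H(s) = log2 P(s) − log2 Π_i q(s_i) in bits,
directly comparable to the PWM score.

The default hyperparameter grid is mu ∈ {0.1, 0.3, 0.6, 1.0},
m0 ∈ {2, 5, 10}, γ ∈ {0.1, 0.5, 1.0} (36 points). The synthetic
recovery experiments in the test suite and acceptance script use a
compact 4-point subset (mu ∈ {0.3, 1.0} × m0 ∈ {2, 10}, γ = 0.5) —
exploratory runs showed the comparison's direction is insensitive to
the grid, and the compact grid keeps hundreds of nested CVs cheap.

## Dependency measures and features

For positions (j, h) the joint distribution is smoothed with a 1/n
pseudocount per cell: P(b_j, b_h) = (N + 1/n)/(n + 16/n); marginals are
its row/column sums. On this table:

* **Cramér's V** = sqrt(χ²/(min(c−1, r−1)·n)) with c = r = 4, where χ²
  is computed from the smoothed joint and the product of its marginals.
* **Symmetric Theil's U** = 2·I/(H_j + H_h) — mutual information
  normalised by the mean entropy. Entropies and I are computed in nats;
  U is invariant to the logarithm base.

Both live in [0, 1] and are symmetric, so aggregation runs over the
l(l−1)/2 unordered pairs. Because the measures are evaluated on the
smoothed table, a finite sample with independent positions gives values
near but not exactly 0; the exact-zero case (a factorising smoothed
joint, e.g. the balanced 16-pair sample) is exercised analytically in
tests.

A sample's feature vector is (n, mIC, mean V, max V, mean U, max U),
where IC = Σ p̂·W (bits, with the 0·log 0 = 0 convention so zero cells
contribute nothing) and mIC = IC/l.

## Non-positive sequences

Negatives for testing are manufactured from the background genome:
16,000 random fragments of 1,000 nt (both configurable; experiments
here use 1,000 fragments against synthetic genomes), each shuffled
character-wise, sliced into non-overlapping l-windows left to right,
pooled, permuted, and truncated to min(500,000; 100·n). Shuffling
conserves composition but destroys dinucleotide and motif structure.
Fragments never span FASTA record boundaries; fragments containing
ambiguous bases are redrawn within a 10× oversampling budget. They are
"non-positive" rather than negative: nothing certifies a shuffled
window is not a site.

## Nested 7-fold cross-validation and model comparison

One seeded 7-fold partition of positives (and, in parallel, of
non-positives) serves both loops. Inner loop, iteration i: fold i is
the untouched test fold, fold i+1 calibrates, the other five train.
Each grid point's APFA is scored by Average Precision (AP — the
estimator of area under the precision-recall curve, computed with tied
scores grouped at one threshold) on the calibration fold plus its
matching non-positive fold, averaged over the seven iterations; ties in
mean AP prefer larger mu, then m0, then γ (more merging, more
smoothing — the simpler automaton). Classification thresholds for both
models are the across-iteration averages of the F1-optimal cuts
(candidates are midpoints between adjacent distinct pooled scores;
classification is score ≥ cut). Outer loop, iteration i: both models
train on the six non-test folds (PWM, and APFA with the selected
hyperparameters) and record AP on test fold i plus non-positive fold i.

The seven paired AP values feed Cohen's D:

    D = (mean AP_APFA − mean AP_PWM) / s,
    s = sqrt(((n−1)s²_APFA + (n−1)s²_PWM) / (2n−2)),  n = 7

with the convention that a degenerate pooled s (≤ 1e-12, i.e. constant
AP vectors) yields D = 0 for equal means and ±∞ otherwise. D ≥ 0.4
labels the sample APFA-preferred; below that the models are considered
similar and the simpler PWM is recommended. The default seed for every
randomised task is 11.

## Preference decision tree

Each evaluated sample becomes an instance: six features, binary label
(1 iff D ≥ 0.4). A Gini decision tree of depth ≤ 3 is fit; accuracy is
estimated by stratified 10-fold CV (folds reduced with a warning when
the rarer class has fewer than 10 members). The tree is exported as an
explicit JSON rule whose splits send `feature ≥ threshold` to the
right, APFA-leaning branch — the same inclusive convention as D ≥ 0.4.
Exactness at the boundary differs from scikit-learn's `>` only at
threshold equality, which cannot occur for training points (thresholds
are midpoints of observed values). All six features are candidates;
on our synthetic corpora the tree retains a single dependency feature.
The bundled `default_rule()` was retrained on a 40-sample synthetic
corpus (seed 11) and its threshold is a synthetic-data value; users
with real data should retrain via `motifselect train-rule`.

## Synthetic data: what it emulates and what it does not

The generator draws each position independently from per-position
marginals (default: Dirichlet-perturbed uniform, concentration 10 — 
mildly informative columns, so PWMs have nonzero IC without
saturating), then applies couplings (source j, target h, strength ρ,
bijective nucleotide map): with probability ρ the target symbol is
overwritten by map(source symbol). ρ = 0 is full independence; ρ = 1 a
deterministic functional dependence. Couplings apply in list order, so
chains create higher-order dependence. Labeled corpora mix coupled
(ρ = 1, source position 1–3, target adjacent, random bijection) and
independent samples, tagged with ground truth. Genomes are i.i.d.
draws from a composition model.

This emulates the *dependence structure* that separates the two model
classes, which is the property under test. It does not emulate real
TF binding energetics, motif flanking composition, genomic repeat
structure, sequencing noise, or motif-discovery artifacts. Passing
recovery tests therefore shows the pipeline detects and acts on
position dependence when it exists and abstains when it does not — not
that any particular accuracy carries over to real TFBS collections.

## Numerical choices and degenerate inputs

* Scores are bits throughout; −∞ is the sentinel for zero probability
  and propagates correctly through sums, sorting and AP.
* 0·log 0 and 0·(−∞) contribute 0 (information-theoretic convention).
* PWM columns sum to 1 within 1e-9 (asserted in tests); APFA per-state
  outgoing probabilities likewise; exhaustive APFA mass within 1e-9.
* Exhaustive enumeration refuses l > 8 (4^l blow-up guard).
* A genome with no usable A/C/G/T characters, an empty FASTA, mixed
  lengths, ambiguous bases, and multiple uppercase runs in a JASPAR
  record are all hard errors (with a `keep_longest_run` escape hatch
  for the last); nothing is silently dropped, because n enters the
  pseudocount formulas.
* All randomness flows through `numpy.random.default_rng` seeds; two
  runs with one seed are bit-identical, including the full nested CV.

## Problem sizes used by the test suite and acceptance script

Dependency-recovery runs use l = 8, n = 500, 10 seeds per condition;
selector-recovery corpora use 40 samples of n = 100 each, 10 seeds;
synthetic genomes are 200 kb with 1,000 background fragments. The
worked statistic values (V = 0.43033, U = 0.22395 on
{"AA","AA","CC","CC"}) were derived by hand from the definitions and
are re-derived by independent brute-force oracles in the tests.

## Known limitations

* The APFA learner is a deterministic, level-wise folding scheme;
  other merge orders or distance measures (e.g. KL-based) could yield
  different automata of similar quality. mu is interpreted on the L1
  scale of one-step conditionals.
* Thresholds calibrated by F1 are reported but not used by AP-based
  comparison; they matter only for downstream hard classification.
* `n_sequences` never acquires importance on synthetic corpora because
  corpus samples share one n; with real heterogeneous collections it
  may.
* Genome-wide scanning, variable-length motifs, dinucleotide PWMs and
  higher-order dependency statistics are out of scope.
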