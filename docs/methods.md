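# Methods

## Scope

`pepgen` implements the in-silico sequence-design stage of a
VEGF-mimetic peptide discovery workflow: corpus curation, a
character-level LSTM language model over peptide sequences, stochastic
sequence generation, physicochemical screening, and similarity ranking
against the QK reference peptide (`KLTWQELYQLKYKGI`). Structure-guided
refinement (docking, expert point mutations, molecular dynamics) and
all experimental assays are deliberately out of scope; the pipeline
ends at a ranked candidate list with a documented extension point (the
ranking TSV / `DesignReport.top_candidates`).

## Corpus curation

Peptides are length-banded to 8–20 residues and de-redundated at a 30%
pairwise-identity threshold by a greedy keep-first scan in input order
(deterministic and auditable; the curation report records every drop
with the kept peptide that triggered it).

Identity is defined on a Needleman–Wunsch global alignment with match
+1, mismatch 0 and linear gap penalty −1:
`identity = identical columns / alignment length`, gap columns counted
in the denominator. Among equally optimal alignments the identical-column
count is maximised exactly from the forward/backward DP matrices; for
this scoring scheme the alignment score satisfies
`score = matches − gap columns`, so the alignment length at maximal
matches is determined (`(|a| + |b| + matches − score) / 2`) and
maximising matches also maximises the identity fraction itself — the
metric is therefore well defined without a traceback tie-break. Whether
the 30% threshold in the original workflow was applied to a local or a
global identity is not knowable from the outside; the global definition
above is this package's documented choice. Substitution-matrix scoring
(BLOSUM/PAM) is a non-goal: for 8–20-mers at a coarse 30% cut, unit
match scoring is standard and reproducible.

## Synthetic corpus

The real training set (81 PDB-derived helical fragments) is not
bundled; `sample_corpus` emulates its statistical structure:

* **n = 81** unique peptides, lengths uniform on [8, 20];
* **helix-biased composition**: helix-favouring residues
  (A, L, E, K, Q, M, R) at weight 2, helix breakers (G, P) at 0.3, all
  others at 1;
* **motif implantation**: with probability 0.5 a peptide carries the
  QK-derived 5-mer `WQELY` at a uniform random offset, giving the model
  learnable non-uniform structure;
* **identity cap**: rejection resampling enforces pairwise identity
  < 0.30 (a cap of 1.0 disables the constraint); sampling aborts with a
  clear error after 1000 consecutive rejections.

One `numpy.random.default_rng` stream per call, seeded explicitly:
corpora are byte-identical given the same spec.

Two interactions of these defaults are worth knowing. First, the
identity cap suppresses motif carriers: two peptides shorter than ~17
residues that both carry an intact `WQELY` already exceed 30% identity,
so intact carriers stabilise at roughly 4–6 of 81 rather than half.
Second, the cap forces the corpus to be nearly memoryless *across*
sequences, which bounds what any next-residue model can score on it
(below). The generator emulates corpus-level statistics only — it does
not model secondary structure, positional composition gradients, or
the phylogenetic correlations of real PDB fragments — so green tests
here demonstrate pipeline correctness and reproducibility, not that a
model trained on synthetic data would propose biologically active
peptides.

## Sequence model

A single-layer LSTM with the standard gate equations (input, forget,
output gates and candidate cell; `h₀ = c₀ = 0`), a 50-dimensional
residue embedding, and a dense softmax output over the 22-token
vocabulary (20 residues + START + END). Each peptide of length L
contributes L+1 supervised (prefix → next token) examples, the last
one targeting END so the model learns where peptides stop. Training
minimises mean sparse categorical cross-entropy with Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8) over mini-batches of **32
prefix examples** for exactly 200 epochs — with ~81 peptides of mean
length 14 that is ≈1000 examples and ≈32 optimiser steps per epoch.
Batched prefixes are left-padded with a reserved padding index that is
masked out of the recurrence, the loss and the accuracy. The 80/20
train/hold-out split, parameter initialisation (uniform embedding,
Glorot input kernels, orthogonal recurrent kernels, unit forget-gate
bias) and batch shuffling all draw from one seeded generator, so
training is bitwise reproducible single-threaded.

The implementation is plain numpy (forward, backpropagation through
time, Adam). Correctness is enforced two independent ways in the test
suite: the forward pass is checked against a hand-written pure-Python
evaluation of the gate equations on a 1-unit model (1e-10), and the
analytic gradients are checked against central finite differences over
every parameter of a small model (1e-5).

Per-epoch trace metrics (loss and argmax accuracy on the training and
hold-out sets) are evaluated with end-of-epoch weights on the full
sets — not running averages over the epoch's mini-batches — so the
final-epoch figure is a clean property of the final model.

### Generation

Sequences are generated by iterative next-residue prediction from
START + an optional seed prefix, sampling from the softmax with
temperature scaling (`logits / T`; `T = 0` means argmax) until END or
20 emitted residues. The START token is masked out of the sampling
distribution, so emitted strings are always over the 20-residue
alphabet. Generation keeps the recurrent state incrementally and is
reproducible from its own RNG seed.

### The accuracy ceiling on identity-capped corpora

Final-epoch *training* accuracy on the default synthetic corpus is
89.6–90.0%, and this is exactly the Bayes-optimal value, not an
optimisation shortfall: whenever two training sequences share a prefix,
any model must make the same prediction for both, so the maximal
accuracy is `Σ_prefixes max-target-count / Σ pairs` over the training
set's prefix tree. With 65 training sequences over a 20-letter,
near-uniform alphabet, the first one or two positions of each sequence
collide heavily (~100 unavoidable errors in ~1000 pairs), and the 30%
identity cap *forbids* the shared prefixes that would reduce those
collisions — a counting argument (every non-modal sequence costs at
least one error at its branch point) bounds any 65-sequence corpus in
this length band at ≈93.5%, and identity-capped ones at ≈89–90%. The
trained model reaches that ceiling exactly in all tested seeds, which
is the strongest available evidence that the optimiser and architecture
are doing their job; the corresponding acceptance test asserts the
published >90% level and therefore documents a shortfall of ~0.4
percentage points that is a property of the corpus constraints, not of
the model. Hold-out accuracy is near chance by the same logic: a
mutually dissimilar corpus can only be memorised, and the published
behaviour is read as training-set accuracy.

## Physicochemical screening

* **Molecular weight**: sum of average (isotope-averaged) residue
  masses + one water, free unmodified termini. This reproduces the
  published QK value (1911 Da) exactly; monoisotopic masses do not.
  (The published VMP3 value of 1810 Da is not reproducible from the
  unmodified sequence, which computes to ≈1771 Da under any standard
  average-mass table — consistent with a terminal modification or a
  typesetting slip; it is reported as computed.)
* **GRAVY**: mean Kyte–Doolittle hydropathy.
* **Net charge**: two conventions, reported separately and never
  conflated — an integer formal count at physiological pH (+1 per
  Arg/Lys, −1 per Asp/Glu, His neutral, termini cancel, Cys/Tyr
  excluded) used by the filter, and the continuous
  Henderson–Hasselbalch charge (reported at pH 7.4).
* **Isoelectric point**: unique root of the Henderson–Hasselbalch
  charge — strictly decreasing in pH — located by bisection on [0, 14]
  to 1e-3 pH units, with a Bjellqvist-style pKa set (N-term 7.5,
  C-term 3.55; side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98,
  K 10.0, R 12.0; Cys treated as reduced and ionisable). Both the mass
  table and the pKa set are overridable dataclasses.
* **Filter thresholds** (all inclusive): length ≥ 10, formal charge in
  [−2, +2], GRAVY in [−1.0, +1.0].

Terminal modifications (acetylation/amidation) are a non-goal; all
values assume free termini.

## Similarity ranking

Unit-cost Levenshtein distance by dynamic programming, normalised as
`1 − d / max(|a|, |b|)` — the most common normalisation, bounded in
[0, 1] and equal to 1 iff the strings are identical (normalising by the
reference length alone would not be). Filter-passing candidates are
sorted by similarity descending with deterministic tie-breaks (smaller
edit distance, then lexicographic), making the ranking a pure function
of the candidate set.

## Pipeline

`run_design` chains corpus → curation → training → generation →
exact-duplicate removal → screening → ranking, logs each stage at INFO,
and writes all artifacts plus a JSON report with provenance (config
hash, seeds, version). Stage randomness derives from one global seed
(corpus = seed, model = the generator config's seed, generation =
seed + 1, all reduced mod 2³¹), so identical config + seed reproduces
every artifact byte-for-byte; a failed stage leaves partial artifacts
next to a `FAILED` marker naming the stage. Defaults: 500 generated
sequences, top-6 reported — mirroring the six candidates carried
forward in the original workflow — both configurable.

`wound_closure_percent` implements the scratch-assay closure metric
`100 × (A₀ − Aₜ) / A₀` used downstream of design; negative values
(wound expansion) are permitted with a warning.

## Numerical and testing notes

* Softmax is computed with max-subtraction; sigmoids with the
  numerically stable two-branch form.
* Determinism claims are tested bitwise (traces, weights, artifact
  files) under single-threaded numpy.
* Edit-distance correctness is cross-checked against an exhaustive
  recursion oracle (every pair of strings of length ≤ 5 over a 3-letter
  alphabet, plus the frozen value d = 12 for the VMP3/QK pair) and
  against `edlib` on random peptide pairs; alignment identity is
  cross-checked against Biopython's `PairwiseAligner` enumerating all
  optimal alignments; MW/GRAVY/pI are cross-checked against Biopython's
  `ProtParam` (pI within a few tenths of a unit — Biopython adds
  residue-specific terminal pKa corrections).
* On a memorizable corpus of k distinct equiprobable peptides of
  length L, mean cross-entropy has the irreducible floor
  `ln(k) / (L+1)`; the suite asserts convergence to within 0.05 nats of
  that floor (and below 0.05 absolute for k = 1).
* Test problem sizes (corpus sizes 12–81, 2–200 epochs) are chosen so
  the default suite exercises every path, including three full
  200-epoch training runs for the accuracy criterion, in a few minutes
  on one CPU.
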