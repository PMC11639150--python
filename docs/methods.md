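# Methods

## Problem setting and model

`hybrec` treats hybrid long-read correction as sequence labeling. Short
reads aligned onto a long read vote, position by position, for the base
that should be there; a bidirectional GRU learns the mapping from the
per-position vote summary (plus its sequence context) to the corrected
base, which also lets it extrapolate into stretches with no short-read
coverage instead of leaving them untouched or trimming them away.

The classifier is a single Bi-GRU layer with a dense softmax head. Per
direction and time step t, with input x_t and hidden state h:

    Z_t  = σ(x_t W_xz + h W_hz + b_z)            update gate
    R_t  = σ(x_t W_xr + h W_hr + b_r)            reset gate
    H̃_t = tanh(x_t W_xh + (R_t ⊙ h) W_hh + b_h)  candidate state
    H_t  = Z_t ⊙ h + (1 − Z_t) ⊙ H̃_t

The output layer acts on the concatenation of the forward and backward
hidden states, `softmax(W_yh [H_t^fwd, H_t^bwd] + b_y)`, the standard
bidirectional readout; with 128 hidden units per direction this is a
256-wide input to the 5-way softmax. (A readout over `[H_t, H̃_t]` would
be dimensionally consistent too, but discards the backward pass, which
defeats the purpose of a bidirectional encoder; we use the bidirectional
concatenation.)

The model is implemented directly in NumPy with hand-derived
backpropagation through time and Adam. An analytic-vs-central-finite-
difference gradient check (relative error < 1e−4 on small instances) in
the test suite is the arbiter of correctness for the backward pass.

## Feature encoding

Field order: counts of A, T, G, C (forward-strand alignments), a, t, g, c
(reverse-strand), deletion flag `#`, ambiguity flag `*`, coverage flag
`SR`. Conventions the underlying data formats do not fix, and the choices
made here:

- **Case = strand.** A query base contributes to the lowercase counter
  when its alignment is reverse-strand. Strand is the only per-base binary
  channel recoverable from SAM flags, and splitting counts by strand lets
  the model notice strand-biased artefacts. Labels pool both cases — the
  corrected base is strand-free.
- **Ambiguity flag.** `*` is set when the number of alignments showing *no*
  base at the slot (deletion or short insertion) exceeds the number
  supporting a base. At inserted slots the no-base count is (alignments
  covering the anchor) − (alignments inserting at least offset+1 bases);
  at original slots it is deletions plus query-N bases. Uncovered slots
  always carry `*` = 1 and `SR` = 0 together with a one-hot of the long
  read's own base.
- **Labels.** Majority base over pooled counts; ties broken by the fixed
  precedence A > T > G > C for determinism. Slots where no-base evidence
  wins, or where deletions outnumber the best base, are labeled `*` so the
  corrector can remove spurious long-read bases. Uncovered slots are
  labeled with the long read's own base. `−1` is a PAD sentinel produced
  only by windowing and masked from loss and metrics.
- **Query N bases** count toward coverage but toward no base field and do
  not raise the deletion flag; a separate N counter keeps the column
  invariant (bases + deletions + N = coverage) exact.
- **Insertion slots per anchor** = the maximum inserted length observed
  there; reads inserting fewer bases contribute to the no-base counter at
  the surplus offsets. Insertion strings at one anchor are aligned by
  offset, not by a mini-MSA — at short-read error rates, competing
  insertion alleles at one anchor are nearly always a shared prefix.
- Secondary/supplementary alignments are dropped by default (flag-gated in
  `read_sam`). CIGAR `M`, `=` and `X` are walked identically.

## Windowing and data streaming

Windows are 1,000 positions long; consecutive windows share a 200-position
seam so the recurrent state never starts cold mid-read, and the seam
predictions of a non-first window are discarded at restoration time.
Trailing partial windows are padded (zero features, PAD labels) rather
than dropped, honouring the no-trimming policy. Within every window the
first 80% of positions are training positions, the next 10% validation,
the last 10% test; the split is positional so every role retains local
sequence context. Training batches stream window-by-window from the
chunked HDF5 dataset with at most one batch plus one read's encoding in
memory; train order is shuffled per epoch from the run seed, other roles
keep on-disk order.

## Training

Cross-entropy over non-PAD positions, Adam at learning rate 1e−3, at most
200 epochs, early stopping when the *training* loss has not improved for 5
consecutive epochs (validation-loss monitoring is available via
`TrainConfig.monitor`). Parameters from the best monitored epoch are
returned. Initialization is Glorot-uniform weights with zero biases,
seeded; training is deterministic given the seed up to BLAS reduction
order. Divergence (non-finite loss) aborts with a diagnostic rather than
continuing.

## Correction semantics

Label `*` at an original slot deletes the long-read base; at an inserted
slot it suppresses the candidate insertion. Prediction always covers *all*
positions of a read — the 80/10/10 split governs training only, since
whole reads must be corrected. Reads with zero short-read coverage are
emitted unchanged, and output order and read count always equal the input.
Per-read provenance (kept / substituted / inserted / removed / suppressed
slot counts, summing to the absolute length) is logged and optionally
written as TSV.

## Synthetic data

The simulator emulates exactly the structure the method consumes: a
uniform i.i.d. genome; long reads from uniform source intervals with
independent per-base substitution/insertion/deletion errors (defaults
0.06/0.05/0.04 ≈ 15% total, nanopore-like; a PacBio-like ≈ 13% preset;
insertion lengths geometric with mean ≈ 1.4); substitution-only short
reads (default 0.5%) at configurable coverage, about half
reverse-complemented; and oracle alignments whose CIGARs are composed
exactly from the recorded edit scripts — kept reference positions give M,
long-read deletions give query-side I, long-read insertions between kept
positions give D. Each read's edit script replays it from the reference
byte-exactly, which the tests assert.

Deliberately absent: homopolymer- or context-dependent error profiles,
chimeric reads, quality-score correlation, paired-end short reads, and
heuristic alignment noise. Tests passing on this generator therefore show
the pipeline's bookkeeping and learning behaviour are correct under the
method's own assumptions, not that the error model matches any particular
instrument.

## Evaluation

Identity at desk scale is computed per read against its *known* true
reference interval: 1 − edit_distance / max(len) from a unit-cost global
(Needleman–Wunsch) alignment via edlib. This stands in for whole-genome
mapping identity (aligned bases / total bases) and sidesteps the question
of how a mapper counts partially aligned blocks. N50 sorts descending and
returns the read containing base ⌈total/2⌉ of the concatenation. Genome
fraction is the union length of true source intervals over the genome
length. Min–max normalization `(x − min)/(max − min)` is provided for
cross-run comparison tables and refuses all-equal inputs.

## Problem sizes used in the test suite

The packaged checks run at desk scale by design: the worked-example
fixture (43-base read, five alignments); encoder cross-validation on 100
simulated pileups (1.2 kb genomes); windowing round trips on 1,000 random
lengths; gradient checks at T = 5, h = 3; separable-task training on a
12 kb genome (5 × 2 kb long reads, 20× short reads, 32 hidden units); and
the end-to-end improvement run on a 50 kb genome (8 × 3 kb long reads at
~13% error, 30× short reads at 0.5% error, 3 seeds, 32 hidden units, 10
epochs). The module defaults keep the published settings (1,000/200
windows, 128 hidden units, lr 1e−3, patience 5, ≤ 200 epochs); the smaller
sizes above are the package's own choice for fast, deterministic test
runs, and the same pipeline scales to larger inputs unchanged.

## Known limitations

- The per-anchor offset alignment of insertion alleles can misalign
  genuinely different insertion sequences (no local re-alignment or indel
  normalization is attempted).
- Base qualities are parsed but unused; counts are unweighted.
- Whole-window prediction is O(T) sequential per direction in Python/NumPy;
  throughput is adequate for method study, not production-scale datasets.
- An all-`*` prediction yields an empty corrected sequence; this is
  warned about and the FASTA writer emits a single `N` placeholder so the
  record count is preserved.
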