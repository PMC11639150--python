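# hybrec

Hybrid error correction of long sequencing reads with a bidirectional GRU.

Third-generation long reads (PacBio, Oxford Nanopore) carry ~13–15% mixed
substitution/insertion/deletion errors; Illumina-style short reads are
~0.1–1% accurate but short. `hybrec` corrects long reads by aligning short
reads onto them and treating correction as per-position sequence labeling:

1. **Pileup.** Short-to-long alignments (SAM with CIGARs) are walked into
   per-position counts of matching bases (split by strand), deletion
   evidence and insertion events.
2. **Absolute positions.** Because inserted short-read bases have no
   long-read coordinate, the coordinate axis is expanded: behind every
   insertion anchor, as many extra slots are reserved as the longest
   insertion observed there. This keeps features and labels in strict
   one-to-one correspondence and makes the correction invertible.
3. **Encoding.** Every absolute position becomes an 11-field feature vector
   — counts of `A,T,G,C,a,t,g,c` (upper = forward strand, lower = reverse),
   a deletion flag `#`, an ambiguity flag `*`, and a coverage flag `SR` —
   and a majority-vote label in `{A:0, T:1, G:2, C:3, *:4}`.
4. **Model.** A bidirectional GRU (update gate `Z_t = σ(X_tW_xz + H_{t−1}W_hz + b_z)`,
   reset gate `R_t`, candidate `H̃_t = tanh(X_tW_xh + (R_t ⊙ H_{t−1})W_hh + b_h)`,
   state `H_t = Z_t ⊙ H_{t−1} + (1 − Z_t) ⊙ H̃_t`) with a softmax output
   layer classifies each position into the 5 classes. Training uses
   cross-entropy, Adam (lr 0.001) and early stopping on training loss. The
   network is implemented directly in NumPy with hand-derived
   backpropagation through time, verified against finite differences.
5. **Windowing.** Encoded reads are cut into 1,000-position windows with a
   200-position seam shared between neighbours; within each window the
   first 80% of positions train the model, the next 10% validate, the last
   10% test. Batches stream from a chunked HDF5 dataset.
6. **Correction.** Predicted labels are stitched across windows (seams
   dropped), `*` predictions delete spurious long-read bases or suppress
   candidate insertions, and base predictions at inserted slots add bases.
   Reads without short-read coverage pass through unchanged — no read is
   ever trimmed, split or dropped.

A synthetic-data module generates genomes, error-laden long reads, accurate
short reads and *oracle* alignments (CIGARs composed exactly from the
recorded edit scripts), so the whole pipeline runs and is tested without an
external aligner.

## Worked example

The encoder on the five-read textbook pileup (a 43-base long read, five
concordant short reads covering positions 1–31, with insertions behind
positions 3, 10 and 15 and a two-base deletion at 28–29):

```python
from hybrec.synthetic_data import figure_fixture
from hybrec.alignment_io import build_pileup, coverage_fraction
from hybrec.encoding import encode_read

long_read, alignments = figure_fixture()
pileup = build_pileup(long_read, alignments)
encoded = encode_read(pileup, None, long_read)

print("reserved insertion slots:", encoded.map.reserved)
print("original length:", encoded.map.original_length,
      "-> absolute length:", encoded.absolute_length)
for pos in (1, 4, 20, 21):
    print(f"abs {pos:>2}: features {encoded.features[pos-1].tolist()}"
          f"  label {encoded.labels[pos-1]}")
print("coverage fraction: %.3f" % coverage_fraction([pileup]))
```

prints

```
reserved insertion slots: {2: 1, 9: 2, 14: 3}
original length: 43 -> absolute length: 49
abs  1: features [0, 0, 0, 5, 0, 0, 0, 0, 0, 0, 1]  label 3
abs  4: features [0, 5, 0, 0, 0, 0, 0, 0, 0, 0, 1]  label 1
abs 20: features [0, 0, 0, 5, 0, 0, 0, 0, 0, 0, 1]  label 3
abs 21: features [0, 0, 0, 2, 0, 0, 0, 0, 0, 1, 1]  label 4
coverage fraction: 0.721
```

Absolute position 1 is covered by five short-read `C`s (feature field 4,
label `C`); position 4 is the slot reserved for the `T` all five reads
insert behind position 3; positions 20–21 belong to the anchor where two
reads insert `GCC` and three insert `GC` — the third slot sees `C` only
twice against three no-base rows, so its ambiguity flag is set and its
label is `*`.

The full pipeline on a small simulated dataset:

```sh
hybrec pipeline --outdir run --genome-length 6000 --n-long 3 \
    --long-mean-len 1200 --coverage 20 --hidden 16 --batch-size 2 \
    --max-epochs 40 --seed 3
```

finishes in well under a minute on one CPU core and logs

```
hybrec INFO identity 0.8613 -> 0.9925
```

i.e. mean alignment identity of the three long reads against their true
reference intervals rises from 86.1% (~14% simulated error) to 99.3% after
correction. `run/report.json` holds the full metric report (total/aligned
bases, identity, N50, genome fraction) for the raw and corrected reads.

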