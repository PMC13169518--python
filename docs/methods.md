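# Methods

## Problem and model

RNA G-quadruplexes (RG4s) are four-stranded structures formed by guanine-rich
RNA; the proteins that recognise them (RG4-binding proteins, RG4BPs) are
typically intrinsically disordered and enriched in RGG/RG repeats and in the
residues Gly, Ser, Tyr, Phe and Arg. `g4rep` predicts RG4BPs from primary
sequence and localises the candidate binding region, in four stages:

1. **Curation.** Exact duplicates are removed and sequences outside the
   closed length interval [50, 2500] are discarded.  Two rounds of greedy
   clustering follow: at 90 % identity / 50 % bidirectional coverage one
   representative per cluster is kept (redundancy removal); the
   representatives are then re-clustered at 20 % identity / 50 % coverage —
   below the 20–35 % "twilight zone" where homology escapes detection — and
   those clusters are the atomic units of an 80/8/12 train/validation/test
   split, so homologous sequences can never straddle a split boundary.
   Classes are balanced per split by randomly dropping negatives only.
2. **Encoding.** One-hot (L x 20, alphabetical column order
   `ACDEFGHIKLMNPQRSTVWY`) or externally computed per-residue embeddings
   (e.g. 1280-dimensional protein-language-model vectors) loaded from disk.
   Batches are zero-padded to the batch maximum with a boolean validity mask.
3. **Classification.** One of five architectures maps the padded batch to a
   per-sequence binding probability B: (1) two stacked LSTM layers, (2) the
   same with additive attention between the LSTM layers, (3)/(4) variants of
   (1)/(2) with a same-padded 1-D convolution + ReLU in front, and (5)
   convolution + ReLU only.  All five end in two position-wise fully
   connected layers, each followed by a sigmoid, and a masked mean pool over
   valid positions.  Training minimises binary cross-entropy with Adam and
   early stopping on validation loss.
4. **Localization and statistics.** A sliding window of length n combines the
   window-mean disorder (an input profile, one value in [0,1] per residue)
   with the window's G/S/Y/F/R density into the composite G; a gate emits B
   where G >= T and 0 elsewhere, and runs of consecutive passing windows are
   merged into candidate regions.  Downstream statistics: Fisher's exact test
   for disorder enrichment among high-scoring proteins, confidence-band
   summaries, and residue/triplet composition around RG/RGG motifs.

## Key formulas and conventions

* **Identity/coverage.**  Global alignment (BLOSUM62, gap open −11 / extend
  −1) with free terminal gaps.  Identity = matches / columns of the aligned
  core (first to last aligned pair; internal gap columns count in the
  denominator); coverage of each sequence = its core span / its length, and
  both coverages must clear the threshold.  Free terminal gaps make identity a
  core property and push length mismatch into coverage, which is what the
  50 %-coverage rule is for.
* **Clustering.**  Greedy incremental, longest-first, candidate vs cluster
  representative (the founder, hence the longest member).  This is the
  standard representative-based heuristic (the same family as CD-HIT/MMseqs2
  cluster modes); it is deterministic and exactly reproducible by a
  brute-force re-implementation, which the tests exploit.  An exact
  reproduction of any particular external tool's cluster boundaries is not a
  goal — the leakage guarantee is what matters, and it is asserted directly
  by all-vs-all identity checks across splits.
* **Split packing.**  Whole clusters, largest first (ties shuffled under the
  seed), each into the split with the largest remaining deficit toward the
  0.80/0.08/0.12 targets; achieved fractions are within ±(largest cluster /
  dataset size).  A cluster larger than the training target is an error that
  advises a stricter first-round threshold.
* **Attention.**  Additive scoring e_i = vᵀ tanh(W h_i + b), masked softmax
  over valid positions, context c = Σ α_i h_i; each position is recombined as
  h_i + c.  The residual sum (rather than concatenation) keeps the second
  LSTM's input width equal to the hidden size; either is defensible, one had
  to be fixed.
* **Pooling reading.**  The two FC+sigmoid layers act position-wise and the
  mean pool aggregates their per-position outputs over valid positions.  The
  alternative (pool LSTM states first) is a different model; the
  per-position-then-pool reading keeps every architecture mask-exact and
  padding-invariant, which the tests assert to 1e-6.
* **AUROC.**  Rank-based (Mann–Whitney), ties counted half; tests verify
  equality with exhaustive pair enumeration, with trapezoidal ROC area and
  with scikit-learn's implementation.
* **BCE.**  Probabilities clamped to [1e-12, 1−1e-12] before the log.
* **Window score.**  Φ(Σd, ρ) = (Σd/n)·ρ — the product of window-mean
  disorder and motif density.  Only the score's range ("0 up to the maximum
  average disorder") is externally constrained; the product is the simplest
  form with that range that vanishes when either signal is absent and is
  monotone in both.  Φ is one small function (`g4rep_score`) and can be
  replaced wholesale.
* **Window length and gate threshold.**  n = 15 by default (RGG boxes span
  roughly 10–25 residues); T defaults to the 60th percentile of the protein's
  own window scores, so the gate adapts to each protein's overall disorder
  level; both are configurable, and T can be absolute.  Boundary convention:
  G = T passes.  Coordinates in all outputs are 1-based inclusive.
* **Percentages** in enrichment reports are rounded half-away-from-zero to
  integers; log2 enrichments use a 0.5 pseudocount per category; motif
  matches may overlap (RG/RGG tile in real RGG boxes); the flank default is
  ±5 residues.

## Numerical core

No GPU tensor framework is used: the architectures run on a small
reverse-mode automatic-differentiation engine (`g4rep.autodiff`) over numpy
float64 arrays, with the LSTM unrolled per time step, same-padded convolution
expressed as k shifted matrix products, and masked softmax/pooling as
primitive-level operations.  Every architecture's gradients were verified
against central finite differences during development, and repeated forward
passes are bitwise stable in single-threaded use.  Adam uses the conventional
moment defaults (0.9/0.999, eps 1e-8).  Parameters initialise from a uniform
fan-in scheme under the model seed.

## Training protocol and scales

`TrainConfig` defaults encode the full-scale protocol: learning rate 1e-5,
batch size 16, early stopping (patience 20) with epoch caps of 1400 (one-hot)
/ 400 (embeddings).  That protocol is sized for a corpus of ~2200 curated
proteins and language-model embeddings.  The package's own demonstrations run
at desk scale instead: the synthetic benchmark trains architecture 1 on
one-hot input with hidden size 32, learning rate 1e-3 and at most 15 epochs
on 400 training sequences of length 80–200 — enough for the planted signal to
be learned to held-out AUROC >= 0.9 in about a minute on one CPU.  These
scaled runs demonstrate that the machinery learns and generalises under the
homology-safe split; they do not reproduce, and are not claimed to reproduce,
published accuracy on real proteomes.

## Synthetic data: what it does and does not emulate

`generate_dataset` plants, in each positive, one contiguous span (30 % of the
sequence by default) whose composition shifts 0.35 of its probability mass
onto G/S/Y/F/R/N/Q, with Poisson-placed RGG/RG repeats (rate 6 per 100
residues) and a disorder profile drawn Beta(8,2) inside the span and
Beta(2,8) outside; negatives are uniform background with Beta(2,8) disorder.
Background composition is uniform over the 20 residues by default (an
empirical frequency vector can be supplied); the package's claims on this
data are relative (positives vs negatives, span vs flank), so the background
choice is not load-bearing.  `generate_homology_families` copies each random
ancestor into its family with independent point substitutions (the ancestor
itself is the first member), giving member-vs-ancestor identity ≈ 1 − rate;
there are no indels, no substitution-matrix realism and no phylogeny.
Passing tests therefore certify the pipeline's correctness and leakage
guarantees, not biological generalisation: real disorder profiles come from
an external per-residue predictor and are consumed as TSV input, and the
composition-based profiles here are synthetic stand-ins for tests only.

## Degenerate inputs and edge policies

Nonstandard residues (B, J, O, U, X, Z) are retained in sequences and encoded
as all-zero rows with a warning — rejecting them would silently shrink real
proteomes.  Empty FASTA files parse to empty datasets with a warning;
duplicate ids are an error listing the offenders.  Sequences shorter than the
window length are scored as one whole-sequence window.  AUROC on a
single-class evaluation set is reported as missing, not 0.  An all-masked
sequence (no valid positions) is rejected before any computation.

## Known limitations

* The greedy clusterer is O(n·clusters) pairwise alignments and is meant for
  datasets up to a few thousand sequences; an external clustering tool can be
  substituted upstream by supplying its cluster table to the split stage.
* The autodiff engine is single-threaded and unbatched across time steps;
  training beyond a few thousand medium-length sequences is slow.
* Embedding generation is out of scope: the package consumes precomputed
  per-residue matrices (TSV directory or .npz) and validates shape only.
* The gate threshold's percentile default is a heuristic; region-level
  agreement with any particular published server is not claimed.
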