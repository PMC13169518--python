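# g4rep

Prediction of RNA G-quadruplex-binding proteins (RG4BPs) from primary
sequence, with residue-level localization of the candidate binding region.

RNA G-quadruplexes (RG4s) are four-stranded structures formed by
guanine-rich RNA.  The proteins that bind them are central to RNA metabolism
and stress-granule biology but are expensive to identify experimentally, and
they share recognisable sequence signatures: intrinsically disordered
regions enriched in RGG/RG repeats and in Gly, Ser, Tyr, Phe and Arg.
`g4rep` is a toolkit for researchers who want to screen protein sequences for
RG4-binding propensity and to ask *where* in a candidate the binding region
lies.

## What it computes

**Binding score B.**  A recurrent sequence classifier (five architectures:
stacked LSTMs, optionally with additive attention between the layers and/or
a 1-D convolution in front, plus a convolution-only baseline) maps each
protein — one-hot encoded or represented by precomputed per-residue
language-model embeddings — to a probability B ∈ [0, 1] of RG4 binding.
Training data pass through a leakage-free curation pipeline: exact
deduplication, length filtering to [50, 2500], 90 %-identity redundancy
removal, 20 %-identity clustering (below the homology "twilight zone"), and a
cluster-aware 80/8/12 split with per-split class balancing.

**Window score G.**  For every length-n window (default 15),

    G = (mean disorder of the window) x (G/S/Y/F/R density of the window)

so 0 <= G <= window-mean disorder, peaking where structural flexibility and
the characteristic composition coincide.  A gate passes B through wherever
G >= T and emits 0 elsewhere; runs of passing windows merge into candidate
regions.  Per-residue disorder profiles are an input (TSV), produced by any
external disorder predictor.

**Enrichment statistics.**  Fisher's exact test for disorder enrichment
among high-scoring proteins, confidence-band summaries of prediction scores,
and residue/triplet composition around RG/RGG motifs.

## Worked example

Disorder enrichment among high-confidence predictions, from the published
human-proteome counts (419 of 552 proteins scoring above 0.95 carry a
disorder annotation, against 11310 of all 20435):

```python
from g4rep.enrichment import ContingencyTable, fisher_exact

odds, p = fisher_exact(ContingencyTable(419, 133, 11310, 9125))
print(f"odds ratio = {odds:.2f}, p = {p:.2e}")
```

```
odds ratio = 2.54, p = 5.68e-23
```

High-scoring proteins are ~2.5-fold enriched in disorder — the hallmark
association between intrinsic disorder and G4 binding.

Localizing the binding region of a synthetic RGG-box protein (a 19-residue
RGG-rich disordered span planted at positions 50–68 of a 117-residue
sequence):

```python
import numpy as np
from g4rep.g4score import DisorderProfile, score_protein, top_window

seq = "M" + "AEKLVD" * 8 + "RGGRGGYSSRGGYGGFRGG" + "AEKLVD" * 8 + "L"
d = np.full(len(seq), 0.15)
d[49:68] = 0.92                      # disordered span
gt = score_protein(seq, DisorderProfile("demo", d), B=0.96, n=15, T=0.3)
tw = top_window(gt.track)
print(f"top window {tw.start}-{tw.end}  G={tw.G:.3f}  rho={tw.motif_density:.3f}")
print("candidate regions:", gt.regions)
```

```
top window 50-64  G=0.920  rho=1.000
candidate regions: [(44, 74)]
```

The top-scoring window sits inside the planted RGG box (all 15 residues in
the motif set, so G equals the window-mean disorder), and the merged
candidate region is the set of windows overlapping the span.

## Command line

The pipeline stages are exposed as subcommands of a single `g4rep` entry
point — `simulate`, `curate`, `split`, `train`, `evaluate`, `predict`,
`score`, `enrich` — reading and writing plain-text formats (FASTA, TSV,
JSON).  `g4rep <command> --help` lists the options of each stage;
`--seed` makes any stage reproducible.

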