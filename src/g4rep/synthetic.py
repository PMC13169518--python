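"""Seeded generators of synthetic protein datasets with planted structure.

Two generators cover the framework's assumptions end to end:

* :func:`generate_dataset` — a labelled classification set.  Positives carry
  one contiguous "disordered" span in which the residue composition is biased
  toward the G4-binding vocabulary (G, S, Y, F, R plus the guanine-contacting
  N and Q) and RGG/RG repeats are planted; the paired disorder profile is
  drawn high (Beta(8,2)) inside the span and low (Beta(2,8)) outside.
  Negatives are pure background with a low flat profile.  The truth table
  records each planted span so localization can be scored against it.
* :func:`generate_homology_families` — families of point-mutated copies of
  random ancestors, for exercising clustering and the split leakage guard.

Everything is reproducible from the config seed.  These sequences emulate
compositional structure only — no real domain grammar, no indels, no
phylogeny — so they test the machinery, not biological generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .g4score import DisorderProfile
from .seq_io import STANDARD_AA, LabeledSequence, SequenceDataset

#: Residues over-represented in positive disordered spans: the window-score
#: motif set plus Asn/Gln.
BIASED_RESIDUES = "GSYFRNQ"

SPAN_BETA = (8.0, 2.0)  # disorder inside planted spans
BACKGROUND_BETA = (2.0, 8.0)  # disorder elsewhere / in negatives


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (80, 200)
    #: expected RGG/RG insertions per 100 residues of a positive sequence
    motif_rate: float = 6.0
    #: extra probability mass concentrated on BIASED_RESIDUES inside spans
    motif_set_bias: float = 0.35
    #: fraction of a positive sequence covered by the elevated-disorder span
    disorder_span_fraction: float = 0.30
    seed: int = 0
    background_freqs: tuple[float, ...] | None = None  # length 20, sums to 1

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.motif_set_bias <= 1 and 0 <= self.disorder_span_fraction <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs)
            if f.size != 20 or abs(f.sum() - 1) > 1e-9 or (f < 0).any():
                raise ValueError("background_freqs must be 20 nonnegative values summing to 1")


@dataclass(frozen=True)
class PlantedSpan:
    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive


def _background_probs(cfg: SynthConfig) -> np.ndarray:
    if cfg.background_freqs is not None:
        return np.asarray(cfg.background_freqs, dtype=float)
    return np.full(20, 1.0 / 20)


def _span_probs(cfg: SynthConfig) -> np.ndarray:
    """Background composition with ``motif_set_bias`` extra mass spread evenly
    over the biased residue set."""
    p = _background_probs(cfg) * (1.0 - cfg.motif_set_bias)
    extra = cfg.motif_set_bias / len(BIASED_RESIDUES)
    for aa in BIASED_RESIDUES:
        p[STANDARD_AA.index(aa)] += extra
    return p


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int) -> str:
    idx = rng.choice(20, size=n, p=probs)
    return "".join(STANDARD_AA[i] for i in idx)


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[SequenceDataset, dict[str, DisorderProfile], list[PlantedSpan]]:
    """Generate (sequences, disorder profiles, planted-span truth table)."""
    rng = np.random.default_rng(cfg.seed)
    bg = _background_probs(cfg)
    span_p = _span_probs(cfg)

    records: list[LabeledSequence] = []
    profiles: dict[str, DisorderProfile] = {}
    truth: list[PlantedSpan] = []

    for i in range(cfg.n_pos):
        sid = f"pos{i:04d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        span_len = max(3, int(round(cfg.disorder_span_fraction * L)))
        span_start = int(rng.integers(0, L - span_len + 1))  # 0-based

        seq = list(_draw(rng, bg, L))
        seq[span_start : span_start + span_len] = list(_draw(rng, span_p, span_len))

        # plant RGG / RG repeats inside the span
        n_motifs = rng.poisson(cfg.motif_rate * L / 100.0)
        for _ in range(n_motifs):
            motif = "RGG" if rng.random() < 0.7 else "RG"
            hi = span_start + span_len - len(motif)
            if hi < span_start:
                continue
            pos = int(rng.integers(span_start, hi + 1))
            seq[pos : pos + len(motif)] = list(motif)

        d = rng.beta(*BACKGROUND_BETA, size=L)
        d[span_start : span_start + span_len] = rng.beta(*SPAN_BETA, size=span_len)

        records.append(LabeledSequence(sid, "".join(seq), label=1))
        profiles[sid] = DisorderProfile(sid, d)
        truth.append(PlantedSpan(sid, span_start + 1, span_start + span_len))

    for i in range(cfg.n_neg):
        sid = f"neg{i:04d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        records.append(LabeledSequence(sid, _draw(rng, bg, L), label=0))
        profiles[sid] = DisorderProfile(sid, rng.beta(*BACKGROUND_BETA, size=L))

    return SequenceDataset(records, provenance="synthetic"), profiles, truth


def generate_homology_families(
    n_families: int,
    members_per_family: int,
    mutation_rate: float,
    seed: int = 0,
    length: int = 150,
) -> tuple[SequenceDataset, dict[str, int]]:
    """Families of point-mutated copies of independent random ancestors.

    The first member of each family is the ancestor itself; the rest are
    mutated copies, so member-vs-ancestor identity is ~(1 - mutation_rate).
    Cross-family sequences are independent.  Returns the dataset and the
    planted family label per id.
    """
    if not (0.0 <= mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    uniform = np.full(20, 1.0 / 20)
    records: list[LabeledSequence] = []
    families: dict[str, int] = {}
    for fam in range(n_families):
        ancestor = _draw(rng, uniform, length)
        for m in range(members_per_family):
            seq = list(ancestor)
            for pos in range(length):
                if m > 0 and rng.random() < mutation_rate:
                    choices = [aa for aa in STANDARD_AA if aa != seq[pos]]
                    seq[pos] = choices[int(rng.integers(0, 19))]
            sid = f"fam{fam:03d}_m{m:02d}"
            records.append(LabeledSequence(sid, "".join(seq), label=fam % 2))
            families[sid] = fam
    return SequenceDataset(records, provenance="synthetic-families"), families


def write_truth_table(truth: list[PlantedSpan], path) -> None:
    with open(path, "w") as fh:
        fh.write("# planted disordered motif spans; coordinates 1-based inclusive\n")
        fh.write("seq_id\tspan_start\tspan_end\n")
        for t in truth:
            fh.write(f"{t.seq_id}\t{t.start}\t{t.end}\n")
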