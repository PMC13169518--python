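"""Per-residue feature encodings and padded batch construction.

Two feature sources feed the classifiers: a 20-dimensional one-hot encoding
computed here, and externally produced per-residue embedding matrices (e.g.
from a protein language model, 1280-dimensional) loaded from disk.  Either
way a sequence becomes an L x D float matrix; batching pads every matrix to
the batch maximum length with all-zero rows and records validity in a boolean
mask, so downstream pooling can ignore the padding entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import STANDARD_AA, SequenceDataset

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class EncodedSequence:
    seq_id: str
    features: np.ndarray  # (L, D) float
    mask: np.ndarray  # (L,) bool, all True before padding
    label: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.features.ndim != 2:
            raise ValueError(f"{self.seq_id}: features must be 2-D")
        if self.mask.shape != (self.features.shape[0],):
            raise ValueError(f"{self.seq_id}: mask length != feature rows")
        if not np.isfinite(self.features).all():
            raise ValueError(f"{self.seq_id}: non-finite feature values")


@dataclass
class EncodedBatch:
    """Sequences padded to a common length, with masks marking real residues."""

    seq_ids: list[str]
    features: np.ndarray  # (B, T, D)
    mask: np.ndarray  # (B, T) bool
    labels: np.ndarray | None = None  # (B,) float in {0,1}, or None

    def __len__(self) -> int:
        return self.features.shape[0]


def one_hot(seq, alphabet: str = STANDARD_AA) -> EncodedSequence:
    """One-hot encode a sequence: L x 20 binary matrix, alphabetical column
    order.

    Nonstandard residues (B, J, O, U, X, Z) map to an all-zero row with a
    logged warning; there is no dedicated pad symbol — padding is expressed by
    the mask, not the features.
    """
    if len(seq.residues) == 0:
        raise ValueError(f"{seq.id}: cannot encode an empty sequence")
    index = {aa: i for i, aa in enumerate(alphabet)}
    L = len(seq.residues)
    feats = np.zeros((L, len(alphabet)))
    n_nonstandard = 0
    for i, aa in enumerate(seq.residues):
        j = index.get(aa)
        if j is None:
            n_nonstandard += 1
        else:
            feats[i, j] = 1.0
    if n_nonstandard:
        logger.warning(
            "%s: %d nonstandard residue(s) encoded as zero rows", seq.id, n_nonstandard
        )
    return EncodedSequence(seq.id, feats, np.ones(L, dtype=bool), label=seq.label)


def encode_dataset(ds: SequenceDataset, alphabet: str = STANDARD_AA) -> list[EncodedSequence]:
    return [one_hot(rec, alphabet) for rec in ds]


def decode_one_hot(enc: EncodedSequence, alphabet: str = STANDARD_AA) -> str:
    """Inverse of :func:`one_hot` on standard residues ('X' for zero rows)."""
    out = []
    for row in enc.features:
        out.append(alphabet[int(np.argmax(row))] if row.sum() > 0 else "X")
    return "".join(out)


def load_embeddings(path: str | Path, ds: SequenceDataset) -> list[EncodedSequence]:
    """Load precomputed per-residue embeddings for every sequence in ``ds``.

    Two container dialects are accepted:

    * a **directory** of per-id TSV files (``<seq_id>.tsv``, one row per
      residue, one column per embedding dimension), or
    * a single **.npz archive** keyed by seq_id.

    Every id in the dataset must be present, each matrix must have exactly one
    row per residue, and the embedding dimension must be uniform.
    """
    path = Path(path)
    if path.is_dir():
        loader = lambda sid: _load_tsv_matrix(path / f"{sid}.tsv")
        available = {p.stem for p in path.glob("*.tsv")}
    else:
        archive = np.load(path)
        loader = lambda sid: np.asarray(archive[sid], dtype=np.float64)
        available = set(archive.files)

    missing = [r.id for r in ds if r.id not in available]
    if missing:
        raise KeyError(f"embeddings missing for ids: {missing}")

    out: list[EncodedSequence] = []
    dim: int | None = None
    for rec in ds:
        mat = loader(rec.id)
        if mat.ndim != 2 or mat.shape[0] != len(rec.residues):
            raise ValueError(
                f"{rec.id}: embedding has shape {mat.shape}, expected "
                f"({len(rec.residues)}, D)"
            )
        if dim is None:
            dim = mat.shape[1]
        elif mat.shape[1] != dim:
            raise ValueError(
                f"{rec.id}: embedding dimension {mat.shape[1]} != {dim} seen earlier"
            )
        out.append(
            EncodedSequence(rec.id, mat, np.ones(mat.shape[0], dtype=bool), label=rec.label)
        )
    return out


def save_embeddings(items: list[EncodedSequence], path: str | Path) -> None:
    """Write embeddings in the dialect implied by ``path`` (dir vs .npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, **{e.seq_id: e.features for e in items})
    else:
        path.mkdir(parents=True, exist_ok=True)
        for e in items:
            np.savetxt(path / f"{e.seq_id}.tsv", e.features, delimiter="\t", fmt="%.8g")


def _load_tsv_matrix(p: Path) -> np.ndarray:
    mat = np.loadtxt(p, delimiter="\t", dtype=np.float64, ndmin=2)
    return mat


def make_batch(items: list[EncodedSequence]) -> EncodedBatch:
    """Pad a collection of encoded sequences to the batch maximum length.

    Pad positions carry all-zero feature rows and False mask flags; valid
    positions are copied verbatim.
    """
    if not items:
        raise ValueError("cannot batch an empty collection")
    dims = {e.features.shape[1] for e in items}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions in batch: {sorted(dims)}")
    D = dims.pop()
    T = max(e.features.shape[0] for e in items)
    B = len(items)
    feats = np.zeros((B, T, D))
    mask = np.zeros((B, T), dtype=bool)
    for i, e in enumerate(items):
        L = e.features.shape[0]
        feats[i, :L] = e.features
        mask[i, :L] = e.mask
    labels = None
    if all(e.label is not None for e in items):
        labels = np.array([float(e.label) for e in items])
    return EncodedBatch([e.seq_id for e in items], feats, mask, labels)


def iter_batches(
    items: list[EncodedSequence], batch_size: int, shuffle: bool = False, seed: int = 0
):
    """Yield :class:`EncodedBatch` chunks of at most ``batch_size`` items."""
    order = np.arange(len(items))
    if shuffle:
        np.random.default_rng(seed).shuffle(order)
    for start in range(0, len(items), batch_size):
        chunk = [items[i] for i in order[start : start + batch_size]]
        yield make_batch(chunk)
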