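"""Homology-aware dataset curation: clustering, splitting, balancing.

Train/validation/test leakage through homologous pairs is the dominant source
of optimistic bias in protein classifier benchmarks.  The pipeline here
performs two rounds of clustering — a 90 %-identity round that collapses
near-duplicates to one representative each, and a 20 %-identity round (below
the "twilight zone") whose clusters are the atomic units of the split — so no
two sequences sharing detectable homology can land in different splits.
Both rounds require 50 % bidirectional alignment coverage.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .alignment import pairwise_identity
from .seq_io import LabeledSequence, SequenceDataset

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.80, 0.08, 0.12)


@dataclass(frozen=True)
class ClusterAssignment:
    seq_id: str
    cluster_id: int
    representative: bool
    identity_threshold: float
    coverage_threshold: float


@dataclass
class ClusteredSplit:
    train_ids: set[str]
    val_ids: set[str]
    test_ids: set[str]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    cluster_map: list[ClusterAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [self.train_ids, self.val_ids, self.test_ids]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"splits overlap: {sorted(overlap)[:5]}")

    def split_of(self, seq_id: str) -> str:
        for name, ids in zip(SPLIT_NAMES, (self.train_ids, self.val_ids, self.test_ids)):
            if seq_id in ids:
                return name
        raise KeyError(seq_id)

    @property
    def all_ids(self) -> set[str]:
        return self.train_ids | self.val_ids | self.test_ids


def cluster(
    ds: SequenceDataset,
    identity: float,
    coverage: float = 0.5,
    **align_kwargs,
) -> list[ClusterAssignment]:
    """Greedy incremental clustering against cluster representatives.

    Sequences are taken in order of decreasing length (ties by id); each joins
    the first existing cluster whose representative it matches at
    ``>= identity`` with both coverages ``>= coverage``, otherwise it founds a
    new cluster.  The founder — the longest member, given the ordering — is
    the representative.  Deterministic for a given dataset.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must be in (0, 1]")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")

    ordered = sorted(ds.records, key=lambda r: (-len(r), r.id))
    reps: list[LabeledSequence] = []
    assignments: list[ClusterAssignment] = []
    for rec in ordered:
        joined = None
        for cid, rep in enumerate(reps):
            res = pairwise_identity(rec.residues, rep.residues, **align_kwargs)
            if (
                res.identity >= identity
                and res.coverage_a >= coverage
                and res.coverage_b >= coverage
            ):
                joined = cid
                break
        if joined is None:
            joined = len(reps)
            reps.append(rec)
            is_rep = True
        else:
            is_rep = False
        assignments.append(
            ClusterAssignment(
                seq_id=rec.id,
                cluster_id=joined,
                representative=is_rep,
                identity_threshold=identity,
                coverage_threshold=coverage,
            )
        )
    return assignments


def two_round_reduce(
    ds: SequenceDataset,
    round1_identity: float = 0.90,
    round2_identity: float = 0.20,
    coverage: float = 0.5,
    **align_kwargs,
) -> tuple[SequenceDataset, list[ClusterAssignment]]:
    """Two-round homology reduction.

    Round 1 clusters at 90 %/50 % and keeps one representative per cluster;
    round 2 clusters the surviving representatives at 20 %/50 % and returns
    those clusters for split construction (no sequence is removed in round 2).
    """
    round1 = cluster(ds, round1_identity, coverage, **align_kwargs)
    rep_ids = [a.seq_id for a in round1 if a.representative]
    reduced = ds.subset(rep_ids, provenance="homology-reduced")
    clusters20 = cluster(reduced, round2_identity, coverage, **align_kwargs)
    logger.info(
        "two_round_reduce: %d -> %d representatives in %d round-2 clusters",
        len(ds),
        len(reduced),
        len({a.cluster_id for a in clusters20}),
    )
    return reduced, clusters20


def cluster_split(
    reduced: SequenceDataset,
    clusters20: list[ClusterAssignment],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> ClusteredSplit:
    """Assign whole round-2 clusters to train/val/test by greedy bin packing.

    Clusters are placed largest-first (ties broken by a seeded shuffle) into
    the split with the largest remaining deficit relative to its target count,
    so achieved fractions land within +-(largest cluster / dataset size) of the
    targets while homologous sequences never straddle a split boundary.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    members: dict[int, list[str]] = {}
    for a in clusters20:
        members.setdefault(a.cluster_id, []).append(a.seq_id)

    n = len(reduced)
    targets = [f * n for f in fractions]
    largest = max((len(m) for m in members.values()), default=0)
    if largest > targets[0]:
        raise ValueError(
            f"a single cluster of size {largest} exceeds the training target "
            f"({targets[0]:.1f} sequences); use a stricter first-round identity "
            "threshold"
        )

    rng = random.Random(seed)
    order = list(members.items())
    rng.shuffle(order)  # seeded tie-break among equal-sized clusters
    order.sort(key=lambda kv: -len(kv[1]))

    assigned: list[set[str]] = [set(), set(), set()]
    for _, ids in order:
        deficits = [targets[k] - len(assigned[k]) for k in range(3)]
        k = max(range(3), key=lambda i: deficits[i])
        assigned[k].update(ids)

    return ClusteredSplit(
        train_ids=assigned[0],
        val_ids=assigned[1],
        test_ids=assigned[2],
        fractions=fractions,
        cluster_map=clusters20,
    )


def balance(split: ClusteredSplit, ds: SequenceDataset, seed: int = 0) -> ClusteredSplit:
    """Balance classes by randomly dropping negatives, per split, keeping all
    positives.

    Each of the three sets independently subsamples its negatives (seeded) down
    to its positive count; raises if any set has fewer negatives than
    positives.
    """
    rng = random.Random(seed)
    new_sets: list[set[str]] = []
    for name, ids in zip(SPLIT_NAMES, (split.train_ids, split.val_ids, split.test_ids)):
        pos = sorted(i for i in ids if ds[i].label == 1)
        neg = sorted(i for i in ids if ds[i].label == 0)
        if len(neg) < len(pos):
            raise ValueError(
                f"{name} split has {len(neg)} negatives < {len(pos)} positives; "
                "cannot balance by removing negatives only"
            )
        keep_neg = rng.sample(neg, len(pos))
        new_sets.append(set(pos) | set(keep_neg))
    return ClusteredSplit(
        train_ids=new_sets[0],
        val_ids=new_sets[1],
        test_ids=new_sets[2],
        fractions=split.fractions,
        cluster_map=split.cluster_map,
    )


def write_cluster_table(assignments: list[ClusterAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tcluster_id\trepresentative\n")
        for a in assignments:
            fh.write(f"{a.seq_id}\t{a.cluster_id}\t{int(a.representative)}\n")


def write_split_table(split: ClusteredSplit, ds: SequenceDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tsplit\tlabel\n")
        for rec in ds:
            if rec.id in split.all_ids:
                lab = "" if rec.label is None else str(rec.label)
                fh.write(f"{rec.id}\t{split.split_of(rec.id)}\t{lab}\n")
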