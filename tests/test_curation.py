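import numpy as np
import pytest

from g4rep.alignment import pairwise_identity
from g4rep.curation import (
    ClusteredSplit,
    balance,
    cluster,
    cluster_split,
    two_round_reduce,
)
from g4rep.seq_io import LabeledSequence, SequenceDataset
from g4rep.synthetic import generate_homology_families


def greedy_cluster_oracle(records, identity, coverage):
    """Independent brute-force of the greedy representative rule, driven by a
    precomputed all-pairs identity/coverage matrix."""
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    pair = {}
    for r in ordered:
        for s in ordered:
            res = pairwise_identity(r.residues, s.residues)
            pair[(r.id, s.id)] = res
    reps, labels = [], {}
    for r in ordered:
        for cid, rep in enumerate(reps):
            res = pair[(r.id, rep.id)]
            if (res.identity >= identity and res.coverage_a >= coverage
                    and res.coverage_b >= coverage):
                labels[r.id] = cid
                break
        else:
            labels[r.id] = len(reps)
            reps.append(r)
    return labels


class TestCluster:
    def test_identical_pair_forms_one_cluster(self):
        ds = SequenceDataset(
            [LabeledSequence("a", "MKVLAWHEDT" * 3), LabeledSequence("b", "MKVLAWHEDT" * 3)]
        )
        out = cluster(ds, identity=0.9)
        assert len({a.cluster_id for a in out}) == 1
        assert sum(a.representative for a in out) == 1

    def test_unrelated_pair_forms_singletons(self):
        ds = SequenceDataset(
            [LabeledSequence("a", "AAAAAAAAAA"), LabeledSequence("b", "CCCCCCCCCC")]
        )
        out = cluster(ds, identity=0.2)
        assert len({a.cluster_id for a in out}) == 2

    def test_every_id_in_exactly_one_cluster_with_one_representative(self):
        ds, _ = generate_homology_families(4, 3, 0.05, seed=1, length=60)
        out = cluster(ds, identity=0.9)
        assert sorted(a.seq_id for a in out) == sorted(ds.ids)
        by_cluster = {}
        for a in out:
            by_cluster.setdefault(a.cluster_id, []).append(a)
        for members in by_cluster.values():
            assert sum(m.representative for m in members) == 1

    def test_matches_brute_force_oracle_on_mixed_toy_set(self):
        fam, _ = generate_homology_families(3, 4, 0.03, seed=5, length=50)
        rng = np.random.default_rng(9)
        extra = [
            LabeledSequence(f"rnd{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 55)))
            for i in range(5)
        ]
        ds = SequenceDataset(fam.records + extra)
        got = {a.seq_id: a.cluster_id for a in cluster(ds, identity=0.9, coverage=0.5)}
        want = greedy_cluster_oracle(ds.records, 0.9, 0.5)
        assert got == want

    def test_invariant_to_id_relabelling(self):
        ds, _ = generate_homology_families(3, 3, 0.05, seed=2, length=60)
        relabelled = SequenceDataset(
            [LabeledSequence(f"x{r.id}", r.residues, r.label) for r in ds]
        )
        a = cluster(ds, identity=0.9)
        b = cluster(relabelled, identity=0.9)
        assert [x.cluster_id for x in a] == [x.cluster_id for x in b]


class TestTwoRoundReduce:
    def test_duplicates_collapse_and_round2_counts(self):
        ds = SequenceDataset(
            [LabeledSequence(f"a{i}", "MKVLAWHEDTMKVLAWHEDT") for i in range(3)]
            + [LabeledSequence("b", "CCCPPPCCCPPPCCCPPPQQ")]
        )
        reduced, clusters20 = two_round_reduce(ds)
        assert len(reduced) == 2
        assert len({a.cluster_id for a in clusters20}) == 2

    def test_mutually_dissimilar_set_is_unchanged(self):
        # compositionally disjoint sequences: pairwise identity is exactly 0
        ds = SequenceDataset(
            [LabeledSequence(f"s{i}", aa * 60) for i, aa in enumerate("ACDEF")]
        )
        reduced, clusters20 = two_round_reduce(ds)
        assert sorted(reduced.ids) == sorted(ds.ids)
        assert len({a.cluster_id for a in clusters20}) == 5

    def test_output_size_equals_round1_cluster_count(self):
        ds, _ = generate_homology_families(6, 3, 0.05, seed=3, length=70)
        round1 = cluster(ds, identity=0.9)
        reduced, _ = two_round_reduce(ds)
        assert len(reduced) == len({a.cluster_id for a in round1})


class TestClusterSplit:
    def _singletons(self, n, length=60):
        rng = np.random.default_rng(42)
        ds = SequenceDataset(
            [
                LabeledSequence(
                    f"s{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length)),
                    label=i % 2,
                )
                for i in range(n)
            ]
        )
        return ds, cluster(ds, identity=0.2)

    def test_ten_singletons_split_8_1_1(self):
        ds, clusters = self._singletons(10)
        split = cluster_split(ds, clusters, fractions=(0.8, 0.1, 0.1), seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (8, 1, 1)

    def test_big_cluster_stays_whole(self):
        family, _ = generate_homology_families(1, 5, 0.02, seed=4, length=60)
        rng = np.random.default_rng(1)
        extra = [
            LabeledSequence(f"r{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60)))
            for i in range(5)
        ]
        ds = SequenceDataset(family.records + extra)
        clusters = cluster(ds, identity=0.2)
        split = cluster_split(ds, clusters, seed=0)
        fam_ids = set(family.ids)
        sides = [fam_ids & s for s in (split.train_ids, split.val_ids, split.test_ids)]
        assert sum(bool(s) for s in sides) == 1  # wholly inside one split

    def test_oversized_cluster_raises_with_advice(self):
        family, _ = generate_homology_families(1, 8, 0.02, seed=6, length=60)
        clusters = cluster(family, identity=0.2)
        with pytest.raises(ValueError, match="stricter"):
            cluster_split(family, clusters, fractions=(0.5, 0.25, 0.25), seed=0)

    def test_splits_disjoint_and_cover(self):
        ds, clusters = self._singletons(25)
        split = cluster_split(ds, clusters, seed=3)
        assert split.all_ids == set(ds.ids)

    def test_cross_split_identity_below_threshold(self):
        """Leakage guard: no cross-split pair reaches 20% identity with 50%
        coverage on a planted-family dataset."""
        ds, _ = generate_homology_families(8, 3, 0.05, seed=8, length=80)
        reduced, clusters20 = two_round_reduce(ds)
        split = cluster_split(reduced, clusters20, seed=1)
        groups = [
            [reduced[i].residues for i in ids]
            for ids in (split.train_ids, split.val_ids, split.test_ids)
        ]
        for gi in range(3):
            for gj in range(gi + 1, 3):
                for a in groups[gi]:
                    for b in groups[gj]:
                        res = pairwise_identity(a, b)
                        leak = (
                            res.identity >= 0.2
                            and res.coverage_a >= 0.5
                            and res.coverage_b >= 0.5
                        )
                        assert not leak


class TestBalance:
    def _split_with(self, n_pos, n_neg):
        rng = np.random.default_rng(17)
        recs = [
            LabeledSequence(f"p{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50)), 1)
            for i in range(n_pos)
        ] + [
            LabeledSequence(f"n{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50)), 0)
            for i in range(n_neg)
        ]
        ds = SequenceDataset(recs)
        split = ClusteredSplit(set(ds.ids), set(), set())
        return ds, split

    def test_negatives_subsampled_to_positive_count(self):
        ds, split = self._split_with(20, 35)
        out = balance(split, ds, seed=0)
        pos = [i for i in out.train_ids if ds[i].label == 1]
        neg = [i for i in out.train_ids if ds[i].label == 0]
        assert len(pos) == 20 and len(neg) == 20

    def test_all_positives_retained(self):
        ds, split = self._split_with(10, 15)
        out = balance(split, ds, seed=1)
        assert {i for i in ds.ids if ds[i].label == 1} <= out.train_ids

    def test_already_balanced_unchanged(self):
        ds, split = self._split_with(12, 12)
        out = balance(split, ds, seed=0)
        assert out.train_ids == split.train_ids

    def test_deterministic_under_seed(self):
        ds, split = self._split_with(8, 20)
        a = balance(split, ds, seed=5)
        b = balance(split, ds, seed=5)
        assert a.train_ids == b.train_ids

    def test_too_few_negatives_raise(self):
        ds, split = self._split_with(10, 5)
        with pytest.raises(ValueError, match="negatives"):
            balance(split, ds, seed=0)
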