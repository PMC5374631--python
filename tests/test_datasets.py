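import numpy as np
import pytest

from rbpbind import (
    MotifModel,
    RegionRecord,
    make_ratio_datasets,
    redundancy_filter,
    sample_negatives_random,
    sample_negatives_upstream,
    split_train_test,
    synth_generate,
)
from rbpbind.datasets import pairwise_identity
from rbpbind.seq_io import NEGATIVE, POSITIVE, SequenceRecord

from conftest import make_records, random_rna


def mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGU" if b != seq[p]])
    return "".join(out)


class TestRandomNegatives:
    def test_count_length_and_alphabet(self, tiny_genome):
        negs = sample_negatives_random(tiny_genome, n=30, length=25, seed=1)
        assert len(negs) == 30
        assert all(len(r) == 25 and r.label == NEGATIVE for r in negs)
        assert all(set(r.sequence) <= set("ACGU") for r in negs)

    def test_exclusion_zones_respected(self, tiny_genome):
        exclude = [RegionRecord("chr1", 0, 500, "+")]
        negs = sample_negatives_random(
            tiny_genome, n=20, length=25, exclude=exclude, seed=2
        )
        for r in negs:
            o = r.origin
            if o.chrom == "chr1":
                assert o.start >= 500

    def test_reproducible_under_seed(self, tiny_genome):
        a = sample_negatives_random(tiny_genome, n=10, seed=7)
        b = sample_negatives_random(tiny_genome, n=10, seed=7)
        c = sample_negatives_random(tiny_genome, n=10, seed=8)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_impossible_request_raises(self, tiny_genome):
        exclude = [
            RegionRecord("chr1", 0, 600, "+"),
            RegionRecord("chr2", 0, 300, "+"),
        ]
        with pytest.raises(ValueError, match="admissible"):
            sample_negatives_random(tiny_genome, n=5, exclude=exclude, seed=0)


class TestUpstreamNegatives:
    def test_coordinates_at_distance_one(self, tiny_genome):
        pos = RegionRecord("chr1", 100, 125, "+", rbp="FUS")
        (neg,) = sample_negatives_upstream([pos], tiny_genome, distance=1)
        assert (neg.origin.start, neg.origin.end) == (74, 99)
        assert neg.label == NEGATIVE and neg.rbp == "FUS"

    def test_minus_strand_upstream_is_genomic_downstream(self, tiny_genome):
        pos = RegionRecord("chr1", 100, 125, "-", rbp="FUS")
        (neg,) = sample_negatives_upstream([pos], tiny_genome, distance=1)
        assert (neg.origin.start, neg.origin.end) == (126, 151)

    @pytest.mark.parametrize("d", [1, 10, 1001])
    def test_never_overlaps_positive(self, tiny_genome, d):
        pos = RegionRecord("chr1", 300, 325, "+")
        negs = sample_negatives_upstream([pos], tiny_genome, distance=d)
        for neg in negs:
            assert neg.origin.end <= pos.start

    def test_off_chromosome_skipped(self, tiny_genome):
        pos = RegionRecord("chr1", 10, 35, "+")
        assert sample_negatives_upstream([pos], tiny_genome, distance=1) == []

    def test_distance_below_one_rejected(self, tiny_genome):
        with pytest.raises(ValueError):
            sample_negatives_upstream([], tiny_genome, distance=0)


class TestRedundancyFilter:
    def test_exact_duplicates_collapse(self, rng):
        s = random_rna(rng, 25)
        recs = make_records([s, s, s])
        assert len(redundancy_filter(recs, 0.8)) == 1

    def test_distant_pair_survives(self, rng):
        a = random_rna(rng, 25)
        b = mutate(a, range(0, 20, 2), rng)  # 10 substitutions: 60% identity
        kept = redundancy_filter(make_records([a, b]), 0.8)
        assert len(kept) == 2

    def test_close_pair_collapses(self, rng):
        a = random_rna(rng, 25)
        b = mutate(a, [3, 9, 15, 21], rng)  # 4 substitutions: 84% identity
        assert pairwise_identity(a, b) >= 0.8
        kept = redundancy_filter(make_records([a, b]), 0.8)
        assert [r.sequence for r in kept] == [a]

    def test_earlier_sequence_is_the_representative(self, rng):
        a = random_rna(rng, 25)
        b = mutate(a, [0], rng)
        kept = redundancy_filter(make_records([b, a]), 0.8)
        assert [r.sequence for r in kept] == [b]

    def test_idempotent(self, rng):
        recs = make_records([random_rna(rng, 25) for _ in range(12)])
        once = redundancy_filter(recs, 0.8)
        twice = redundancy_filter(once, 0.8)
        assert once == twice

    def test_two_set_mode_drops_against_reference(self, rng):
        a = random_rna(rng, 25)
        near = mutate(a, [5], rng)
        far = mutate(a, range(0, 20, 2), rng)
        kept = redundancy_filter(
            make_records([near, far]), 0.8, reference=make_records([a])
        )
        assert [r.sequence for r in kept] == [far]


class TestRatioDatasets:
    @pytest.fixture
    def pools(self, rng):
        pos = make_records([random_rna(rng, 25) for _ in range(20)], POSITIVE)
        neg = make_records([random_rna(rng, 25) for _ in range(250)], NEGATIVE)
        return pos, neg

    def test_default_ratios_and_counts(self, pools):
        pos, neg = pools
        sets = make_ratio_datasets(pos, neg, seed=0)
        assert sorted(sets) == [1, 2, 4, 6, 8, 10]
        for r, ds in sets.items():
            assert ds.ratio == (20, 20 * r)

    def test_negatives_are_nested(self, pools):
        pos, neg = pools
        sets = make_ratio_datasets(pos, neg, seed=0)
        ids = {r: {rec.id for rec in sets[r].negatives} for r in sets}
        assert ids[1] < ids[2] < ids[4] < ids[6] < ids[8] < ids[10]

    def test_pool_exhaustion_raises(self, pools):
        pos, _ = pools
        with pytest.raises(ValueError, match="pool"):
            make_ratio_datasets(pos, pos[:10], ratios=[10], seed=0)


class TestSplit:
    def test_partition_and_stratification(self, planted_motif):
        data = synth_generate(planted_motif, 100, 100, n_groups=4, seed=3)
        train, test = split_train_test(data, 0.7, seed=4)
        train_ids = {r.id for r in train.records}
        test_ids = {r.id for r in test.records}
        assert train_ids & test_ids == set()
        assert train_ids | test_ids == {r.id for r in data.records}
        # per (label, group) stratum: 25 records -> 17 or 18 in train
        for label in (POSITIVE, NEGATIVE):
            for g in data.groups():
                n = sum(
                    1
                    for r in train.records
                    if r.label == label and r.rbp == g
                )
                assert n in (17, 18)

    def test_reproducible_under_seed(self, synth_data):
        a, _ = split_train_test(synth_data, 0.7, seed=5)
        b, _ = split_train_test(synth_data, 0.7, seed=5)
        assert [r.id for r in a.records] == [r.id for r in b.records]

    def test_tiny_stratum_goes_to_train(self):
        records = make_records(["ACGUA"], POSITIVE) + make_records(
            ["GGGGG", "CCCCC"], NEGATIVE
        )
        from rbpbind import LabeledSequenceSet

        train, test = split_train_test(LabeledSequenceSet(tuple(records)), 0.7, 0)
        assert "s0" in {r.id for r in train.records}  # lone positive kept


class TestSynthGenerate:
    def test_lengths_alphabet_and_groups(self, planted_motif):
        data = synth_generate(planted_motif, 30, 50, n_groups=3, seed=0)
        assert data.ratio == (30, 50)
        assert all(len(r) == 25 for r in data.records)
        assert data.groups() == ["synRBP01", "synRBP02", "synRBP03"]

    def test_reproducible_under_seed(self, planted_motif):
        a = synth_generate(planted_motif, 10, 10, seed=42)
        b = synth_generate(planted_motif, 10, 10, seed=42)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_motif_columns_sum_to_one(self, planted_motif):
        np.testing.assert_allclose(
            planted_motif.position_probs.sum(axis=0), 1.0, atol=1e-12
        )

    def test_uniform_motif_equals_background(self):
        model = MotifModel.uniform(25)
        np.testing.assert_allclose(model.true_log_odds(), 0.0)

    def test_save_round_trips_labels(self, tmp_path, planted_motif):
        data = synth_generate(planted_motif, 5, 5, seed=1)
        data.save(tmp_path / "d.fasta", tmp_path / "d.tsv")
        sidecar = (tmp_path / "d.tsv").read_text().splitlines()
        assert sidecar[1].split("\t") == ["id", "label", "rbp", "origin"]
        assert len(sidecar) == 2 + 10
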