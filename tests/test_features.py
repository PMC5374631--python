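import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpbind import (
    assemble,
    build_pwm,
    encode_protein_ctd,
    encode_rna,
    kmer_composition,
)
from rbpbind.features import (
    CTD_LENGTH,
    AMINO_GROUPS,
    FeatureVector,
    LayoutError,
    build_design_matrix,
    composition_block,
)
from rbpbind.profiles import best_offset, profile_terms
from rbpbind.seq_io import NEGATIVE, POSITIVE

from conftest import make_records, random_rna

rna_strings = st.text(alphabet="ACGU", min_size=3, max_size=60)
protein_strings = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=80)


@pytest.fixture(scope="module")
def pwms():
    """Nowhere-zero training profiles over a 25-nt window."""
    rng = np.random.default_rng(7)
    pos = [random_rna(rng, 25) for _ in range(40)]
    neg = [random_rna(rng, 25) for _ in range(40)]
    return build_pwm(pos, neg, k=1), build_pwm(pos, neg, k=2)


class TestComposition:
    def test_homopolymer(self):
        np.testing.assert_allclose(kmer_composition("AAAAA", 1), [1, 0, 0, 0])

    def test_dinucleotide_hand_count(self):
        v = kmer_composition("ACGU", 2)
        expected = np.zeros(16)
        expected[[1, 6, 11]] = 1 / 3  # AC, CG, GU
        np.testing.assert_allclose(v, expected)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            kmer_composition("AC", 3)

    @settings(derandomize=True, max_examples=40)
    @given(seq=rna_strings)
    def test_each_sub_block_sums_to_one(self, seq):
        block = composition_block(seq)
        assert block.size == 84
        for lo, hi in ((0, 4), (4, 20), (20, 84)):
            assert block[lo:hi].sum() == pytest.approx(1.0, abs=1e-9)


class TestEncodeRna:
    def test_window_length_input_gives_133_features(self, pwms, rng):
        fv = encode_rna(random_rna(rng, 25), *pwms)
        assert len(fv) == 133
        assert fv.layout == (("mPWM", 25), ("dPWM", 24), ("composition", 84))

    def test_window_input_blocks_are_profile_terms(self, pwms, rng):
        mpwm, dpwm = pwms
        s = random_rna(rng, 25)
        fv = encode_rna(s, mpwm, dpwm)
        np.testing.assert_array_equal(fv.block("mPWM"), profile_terms(s, mpwm))
        np.testing.assert_array_equal(fv.block("dPWM"), profile_terms(s, dpwm))

    def test_long_input_same_length_best_window(self, pwms):
        """A 51-nt sequence still encodes to 133 features; its profile
        blocks match the exhaustively best-scoring 25-mer window and its
        compositions cover the whole sequence."""
        mpwm, dpwm = pwms
        rng = np.random.default_rng(21)
        s = random_rna(rng, 51)
        fv = encode_rna(s, mpwm, dpwm)
        assert len(fv) == 133
        # brute-force window search as the oracle
        scores = [
            profile_terms(s[o : o + 25], mpwm).sum() for o in range(51 - 25 + 1)
        ]
        o = int(np.argmax(scores))
        np.testing.assert_array_equal(
            fv.block("mPWM"), profile_terms(s[o : o + 25], mpwm)
        )
        np.testing.assert_array_equal(fv.block("composition"), composition_block(s))

    def test_short_input_zero_fills_uncovered_columns(self, pwms):
        mpwm, dpwm = pwms
        rng = np.random.default_rng(22)
        s = random_rna(rng, 20)
        fv = encode_rna(s, mpwm, dpwm)
        assert len(fv) == 133
        o = best_offset(s, mpwm)
        mono = fv.block("mPWM")
        # exactly the 5 uncovered mono columns are zero-filled
        uncovered = [j for j in range(25) if not (o <= j < o + 20)]
        assert len(uncovered) == 5
        assert all(mono[j] == 0 for j in uncovered)
        # covered columns carry the matrix scores of the aligned nucleotides
        for i, ch in enumerate(s):
            assert mono[o + i] == mpwm.score["ACGU".index(ch), o + i]
        # a di column needs both its nucleotides: >= 5 zero-filled
        di = fv.block("dPWM")
        covered_di = [j for j in range(24) if o <= j and j + 1 < o + 20]
        assert 24 - len(covered_di) >= 5
        assert all(di[j] == 0 for j in range(24) if j not in covered_di)

    def test_window_consistency_of_embedded_sequence(self, pwms):
        """Embedding a 25-mer at its best offset inside a longer sequence
        leaves the profile blocks unchanged."""
        mpwm, dpwm = pwms
        rng = np.random.default_rng(23)
        # the consensus sequence scores the column-wise maximum, so its own
        # window wins against any shifted placement
        core = "".join("ACGU"[i] for i in np.argmax(mpwm.score, axis=0))
        embedded = random_rna(rng, 8) + core + random_rna(rng, 8)
        assert best_offset(embedded, mpwm) == 8
        fv_core = encode_rna(core, mpwm, dpwm)
        fv_embedded = encode_rna(embedded, mpwm, dpwm)
        np.testing.assert_array_equal(
            fv_core.block("mPWM"), fv_embedded.block("mPWM")
        )
        np.testing.assert_array_equal(
            fv_core.block("dPWM"), fv_embedded.block("dPWM")
        )

    def test_too_short_for_compositions_raises(self, pwms):
        with pytest.raises(ValueError):
            encode_rna("AC", *pwms)


class TestProteinCtd:
    def test_length_is_63(self):
        assert encode_protein_ctd("MKVLAA").size == CTD_LENGTH == 7 + 21 + 35

    def test_homogeneous_sequence(self):
        v = encode_protein_ctd("AAAA")
        assert v[0] == 1.0  # group {A,G,V} composition
        np.testing.assert_allclose(v[1:7], 0.0)
        np.testing.assert_allclose(v[7:28], 0.0)  # no transitions
        np.testing.assert_allclose(v[28:33], [0.25, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(v[33:], 0.0)

    def test_transitions_hand_count(self):
        v = encode_protein_ctd("ACKA")
        comp = v[:7]
        np.testing.assert_allclose(comp, [0.5, 0.25, 0, 0, 0, 0.25, 0])
        trans = v[7:28]
        # unordered pairs in order (1,2),(1,3)..(1,7),(2,3)..: (g1,g2) is
        # index 0, (g1,g6) index 4, (g2,g6) index 9
        assert trans[0] == pytest.approx(1 / 3)
        assert trans[4] == pytest.approx(1 / 3)
        assert trans[9] == pytest.approx(1 / 3)
        assert trans.sum() == pytest.approx(1.0)

    def test_non_standard_letter_named(self):
        with pytest.raises(ValueError, match="'B'"):
            encode_protein_ctd("ABBA")

    def test_groups_partition_the_alphabet(self):
        all_aas = sorted(aa for group in AMINO_GROUPS for aa in group)
        assert all_aas == sorted("ACDEFGHIKLMNPQRSTVWY")

    @settings(derandomize=True, max_examples=40)
    @given(protein=protein_strings)
    def test_distribution_tuples_nondecreasing_in_unit_interval(self, protein):
        v = encode_protein_ctd(protein)
        dist = v[28:].reshape(7, 5)
        for row in dist:
            assert np.all(np.diff(row) >= 0)
            assert np.all((row >= 0) & (row <= 1))


class TestAssemble:
    def test_rna_only_and_with_protein(self, pwms, rng):
        fv = encode_rna(random_rna(rng, 25), *pwms)
        assert len(assemble(fv)) == 133
        combined = assemble(fv, encode_protein_ctd("MKVLAARST"))
        assert len(combined) == 196
        assert combined.layout[-1] == ("protein", 63)

    def test_protein_block_is_stable(self, pwms, rng):
        fv = encode_rna(random_rna(rng, 25), *pwms)
        a = assemble(fv, encode_protein_ctd("MKVLAARST"))
        b = assemble(fv, encode_protein_ctd("MKVLAARST"))
        np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_protein_length_rejected(self, pwms, rng):
        fv = encode_rna(random_rna(rng, 25), *pwms)
        with pytest.raises(LayoutError):
            assemble(fv, np.zeros(10))

    def test_layout_mismatch_detected(self):
        with pytest.raises(LayoutError):
            FeatureVector(values=np.zeros(5), layout=(("mPWM", 4),))


class TestDesignMatrix:
    def test_labels_and_shape(self, pwms, rng):
        recs = make_records(
            [random_rna(rng, 25) for _ in range(4)], label=POSITIVE
        ) + make_records([random_rna(rng, 25) for _ in range(4)], label=NEGATIVE)
        X, y, layout = build_design_matrix(recs, *pwms)
        assert X.shape == (8, 133)
        assert list(y) == [1] * 4 + [-1] * 4

    def test_composition_only_ablation(self, rng):
        recs = make_records([random_rna(rng, 25) for _ in range(3)], label=POSITIVE)
        X, _, layout = build_design_matrix(
            recs, None, None, blocks=("composition",)
        )
        assert X.shape == (3, 84)
        assert layout == (("composition", 84),)

    def test_protein_block_appended_per_rbp(self, pwms, rng):
        recs = make_records(
            [random_rna(rng, 25) for _ in range(3)], label=POSITIVE, rbp="FUS"
        )
        X, _, layout = build_design_matrix(
            recs, *pwms, protein_sequences={"FUS": "MKVLAARST"}
        )
        assert X.shape == (3, 196)
        assert layout[-1] == ("protein", 63)

    def test_missing_protein_raises(self, pwms, rng):
        recs = make_records([random_rna(rng, 25)], label=POSITIVE, rbp="QKI")
        with pytest.raises(KeyError, match="QKI"):
            build_design_matrix(recs, *pwms, protein_sequences={"FUS": "MKVL"})
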