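import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apopred import (AMINO_ACIDS, CKSAAPEncoder, CTD188Encoder, DPCEncoder,
                     EncoderConfig, LabeledDataset, ProteinRecord,
                     PseAACEncoder, encode_dataset)
from apopred.encoders import EncodingError, read_feature_matrix, write_feature_matrix
from apopred.sequence_io import AA_INDEX
from apopred.tables import PSEAAC_PROPERTY_NAMES, standardized_properties
from helpers import naive_pair_counts, naive_pseaac, random_protein

sequences = st.text(alphabet=AMINO_ACIDS, min_size=12, max_size=80)


class TestDPC:
    def test_hand_enumerated_dipeptides(self):
        v = DPCEncoder().encode("ACA")
        names = DPCEncoder().get_feature_names_out().tolist()
        assert v[names.index("DPC_AC")] == 0.5
        assert v[names.index("DPC_CA")] == 0.5
        assert v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 2

    def test_single_dipeptide(self):
        v = DPCEncoder().encode("AA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_length_contract_and_precondition(self):
        assert DPCEncoder().encode("ACDEFG").shape == (400,)
        with pytest.raises(EncodingError):
            DPCEncoder().encode("A")

    def test_counts_match_naive_enumeration(self, rng):
        enc = DPCEncoder()
        names = enc.get_feature_names_out().tolist()
        for _ in range(20):
            seq = random_protein(rng, int(rng.integers(2, 31)))
            v = enc.encode(seq) * (len(seq) - 1)
            expected = naive_pair_counts(seq, 0)
            got = {names[i][4:]: v[i] for i in np.flatnonzero(v)}
            assert got == pytest.approx(expected)


class TestCKSAAP:
    def test_homopolymer_k0(self):
        v = CKSAAPEncoder(k_max=0).encode("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_alternating_k1_block(self):
        enc = CKSAAPEncoder(k_max=1)
        names = enc.get_feature_names_out().tolist()
        v = enc.encode("ACAC")
        assert v[names.index("CKSAAP_k1_AA")] == 0.5
        assert v[names.index("CKSAAP_k1_CC")] == 0.5

    def test_block_denominator_is_L_minus_k_plus_1(self):
        # L=10, k=2: one DW pair at 2-gap -> 1/7
        seq = "DAAWAAAAAA"
        enc = CKSAAPEncoder(k_max=2)
        names = enc.get_feature_names_out().tolist()
        v = enc.encode(seq)
        assert v[names.index("CKSAAP_k2_DW")] == pytest.approx(1 / 7)

    def test_dimension_contract(self):
        for k_max in range(6):
            assert CKSAAPEncoder(k_max=k_max).encode("ACDEFGHIKL").shape == (
                400 * (k_max + 1),)

    def test_too_short_sequence_raises(self):
        with pytest.raises(EncodingError):
            CKSAAPEncoder(k_max=5).encode("ACDEF")

    def test_counts_match_naive_enumeration(self, rng):
        enc = CKSAAPEncoder(k_max=5)
        names = enc.get_feature_names_out()
        for _ in range(20):
            L = int(rng.integers(7, 31))
            seq = random_protein(rng, L)
            v = enc.encode(seq)
            for k in range(6):
                block = v[400 * k: 400 * (k + 1)] * (L - k - 1)
                expected = naive_pair_counts(seq, k)
                got = {names[400 * k + i][-2:]: block[i]
                       for i in np.flatnonzero(block)}
                assert got == pytest.approx(expected)


class TestCTD188:
    def test_dimension_and_first_block(self, rng):
        enc = CTD188Encoder()
        v = enc.encode(random_protein(rng, 50))
        assert v.shape == (188,)
        assert v[:20].sum() == pytest.approx(1.0)

    def test_single_group_degenerate(self):
        # all residues from the hydrophobic group CLVIMFW of the
        # hydrophobicity partition -> composition (0,0,1), no transitions
        enc = CTD188Encoder()
        names = enc.get_feature_names_out().tolist()
        v = enc.encode("CLVIMFWCLVIMFW")
        comp = [v[names.index(f"D188_hydrophobicity_comp{g}")] for g in (1, 2, 3)]
        assert comp == [0.0, 0.0, 1.0]
        for t in ("12", "13", "23"):
            assert v[names.index(f"D188_hydrophobicity_trans{t}")] == 0.0

    def test_distribution_points_of_known_sequence(self):
        # charge partition: K,R positive (group 1); sequence KAAAK (L=5)
        enc = CTD188Encoder()
        names = enc.get_feature_names_out().tolist()
        v = enc.encode("KAAAK")
        get = lambda pt: v[names.index(f"D188_charge_dist1_{pt}")]
        assert get("first") == pytest.approx(1 / 5)
        assert get("p25") == pytest.approx(1 / 5)   # ceil(0.25*2)=1st occurrence
        assert get("p50") == pytest.approx(1 / 5)
        assert get("p75") == pytest.approx(5 / 5)   # ceil(0.75*2)=2nd occurrence
        assert get("last") == pytest.approx(5 / 5)

    def test_absent_group_contributes_zeros(self):
        enc = CTD188Encoder()
        names = enc.get_feature_names_out().tolist()
        v = enc.encode("AAAAAAAAAA")  # no K/R, no D/E
        for g in (1, 3):
            for pt in ("first", "p25", "p50", "p75", "last"):
                assert v[names.index(f"D188_charge_dist{g}_{pt}")] == 0.0


class TestPseAAC:
    def test_gamma_zero_reduces_to_composition(self):
        v = PseAACEncoder(gamma=0).encode("AACC")
        assert v.shape == (20,)
        assert v[AA_INDEX["A"]] == 0.5 and v[AA_INDEX["C"]] == 0.5

    def test_dimension_is_20_plus_9_gamma(self, rng):
        for gamma in (1, 5, 10):
            v = PseAACEncoder(gamma=gamma).encode(random_protein(rng, 40))
            assert v.shape == (20 + 9 * gamma,)

    def test_too_short_for_gamma_raises(self):
        with pytest.raises(EncodingError):
            PseAACEncoder(gamma=10).encode("ACDEFGHIK")

    def test_matches_independent_naive_formula(self, rng):
        enc = PseAACEncoder(gamma=6, w=0.05)
        std = standardized_properties()
        for _ in range(10):
            seq = random_protein(rng, int(rng.integers(15, 60)))
            expected = naive_pseaac(seq, 6, 0.05, PSEAAC_PROPERTY_NAMES,
                                    std, AA_INDEX)
            np.testing.assert_allclose(enc.encode(seq), expected, atol=1e-12)

    def test_pure_function_bitwise_identical(self, rng):
        enc = PseAACEncoder(gamma=10)
        seq = random_protein(rng, 50)
        assert np.array_equal(enc.encode(seq), enc.encode(seq))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seq=sequences)
def test_normalization_invariants(seq):
    """DPC, each CKSAAP block, the 188D frequency block and the full PseAAC
    vector each sum to one."""
    assert DPCEncoder().encode(seq).sum() == pytest.approx(1.0, abs=1e-9)
    v = CKSAAPEncoder(k_max=5).encode(seq)
    for k in range(6):
        assert v[400 * k: 400 * (k + 1)].sum() == pytest.approx(1.0, abs=1e-9)
    assert CTD188Encoder().encode(seq)[:20].sum() == pytest.approx(1.0, abs=1e-9)
    assert PseAACEncoder(gamma=10).encode(seq).sum() == pytest.approx(1.0, abs=1e-9)


class TestEncodeDataset:
    def test_shape_names_and_roundtrip(self, tiny_dataset, tmp_path):
        X = encode_dataset(tiny_dataset, EncoderConfig("DPC"))
        assert X.shape == (3, 400)
        assert list(X.index) == tiny_dataset.ids
        path = tmp_path / "m.tsv"
        write_feature_matrix(X, path)
        back = read_feature_matrix(path)
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-12)
        assert list(back.columns) == list(X.columns)

    def test_row_permutation_equivariance(self, tiny_dataset):
        X = encode_dataset(tiny_dataset, EncoderConfig("188D"))
        perm = tiny_dataset.subset([2, 0, 1])
        Xp = encode_dataset(perm, EncoderConfig("188D"))
        np.testing.assert_array_equal(Xp.to_numpy(),
                                      X.loc[perm.ids].to_numpy())

    def test_identical_records_identical_rows(self):
        ds = LabeledDataset([ProteinRecord("a", "ACDEFGHIKLMNP"),
                             ProteinRecord("b", "ACDEFGHIKLMNP")])
        X = encode_dataset(ds, EncoderConfig("PseAAC", gamma=5))
        np.testing.assert_array_equal(X.iloc[0].to_numpy(), X.iloc[1].to_numpy())

    def test_error_names_offending_record(self):
        ds = LabeledDataset([ProteinRecord("ok", "ACDEFGHIKLMN"),
                             ProteinRecord("shorty", "ACD")])
        with pytest.raises(EncodingError, match="shorty"):
            encode_dataset(ds, EncoderConfig("CKSAAP", k_max=5))

    def test_unknown_encoder_rejected(self):
        with pytest.raises(EncodingError):
            EncoderConfig("WORD2VEC")
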