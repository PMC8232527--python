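"""Encoder correctness against brute-force oracles and closed-form dimensions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aptasearch import encoders as enc
from aptasearch.sequences import PROTEIN_ALPHABET, RNA_ALPHABET
from aptasearch.tables import load_ctd_groups, load_triad_classes

from .oracles import (
    auto_cov_direct,
    cross_cov_direct,
    ctd_direct,
    kmer_count_vector,
    pseaac_direct,
    pseknc_direct,
    triad_direct,
)

RNG = np.random.default_rng(20240901)


def random_seq(alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in RNG.integers(0, len(alphabet), length))


# --- dimensions are pure functions of the encoder parameters --------------

@pytest.mark.parametrize(
    "encoder,expected_dim",
    [
        (enc.KmerComposition(k=1, alphabet="protein"), 20),
        (enc.KmerComposition(k=2, alphabet="protein"), 400),
        (enc.KmerComposition(k=3, alphabet="protein"), 8000),
        (enc.ConjointTriad(alphabet="protein"), 343),
        (enc.ConjointTriad(alphabet="rna"), 64),
        (enc.CTD(), 147),
        (enc.PseKNC(k=2, lam=2), 18),
        (enc.PseKNC(k=3, lam=2), 66),
        (enc.PseAAC(lam=10), 30),
        (enc.AutoCovariance(unit_size=2, max_lag=2), 6),
        (enc.CrossCovariance(unit_size=2, max_lag=2), 12),
        (enc.AutoCrossCovariance(unit_size=2, max_lag=2), 18),
        (enc.AutoCovariance(unit_size=3, max_lag=2), 6),
    ],
)
def test_declared_dimension_matches_output(encoder, expected_dim):
    assert encoder.dimension == expected_dim
    seq = random_seq(
        RNA_ALPHABET if encoder.alphabet == "rna" else PROTEIN_ALPHABET, 40
    )
    vec = encoder.encode(seq)
    assert vec.shape == (expected_dim,)
    assert np.all(np.isfinite(vec))


def test_dimension_constant_across_lengths():
    for encoder in [
        enc.PseKNC(k=2),
        enc.PseAAC(),
        enc.CTD(),
        enc.AutoCrossCovariance(),
        enc.ConjointTriad(alphabet="rna"),
    ]:
        alphabet = RNA_ALPHABET if encoder.alphabet == "rna" else PROTEIN_ALPHABET
        dims = {
            encoder.encode(random_seq(alphabet, n)).shape for n in (25, 40, 80)
        }
        assert dims == {(encoder.dimension,)}


# --- k-mer composition ----------------------------------------------------

@pytest.mark.parametrize("alphabet,kind", [(RNA_ALPHABET, "rna"), (PROTEIN_ALPHABET, "protein")])
@pytest.mark.parametrize("k", [1, 2, 3])
def test_kmer_matches_sliding_window_oracle(alphabet, kind, k):
    for _ in range(100):
        seq = random_seq(alphabet, int(RNG.integers(10, 80)))
        got = enc.kmer_frequencies(seq, k, alphabet=kind)
        np.testing.assert_allclose(got, kmer_count_vector(seq, k, alphabet), atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(got >= 0)


def test_kmer_trivial_cases():
    v = enc.kmer_frequencies("AAAA", 1, alphabet="rna")
    np.testing.assert_allclose(v, [1.0, 0.0, 0.0, 0.0])
    np.testing.assert_allclose(
        enc.kmer_frequencies("ACGU", 1, alphabet="rna"), [0.25] * 4
    )


def test_kmer_too_short_errors():
    with pytest.raises(ValueError, match="too short"):
        enc.kmer_frequencies("AC", 3, alphabet="rna")


# --- covariance encoders --------------------------------------------------

@pytest.mark.parametrize("unit,table", [(2, "rna_dinucleotide"), (3, "rna_trinucleotide")])
def test_auto_covariance_matches_direct_sum(unit, table):
    for _ in range(100):
        seq = random_seq(RNA_ALPHABET, int(RNG.integers(12, 60)))
        got = enc.auto_covariance(seq, unit_size=unit, max_lag=2)
        np.testing.assert_allclose(got, auto_cov_direct(seq, table, unit, 2), atol=1e-10)


@pytest.mark.parametrize("unit,table", [(2, "rna_dinucleotide"), (3, "rna_trinucleotide")])
def test_cross_covariance_matches_direct_sum(unit, table):
    for _ in range(100):
        seq = random_seq(RNA_ALPHABET, int(RNG.integers(12, 60)))
        got = enc.cross_covariance(seq, unit_size=unit, max_lag=2)
        np.testing.assert_allclose(got, cross_cov_direct(seq, table, unit, 2), atol=1e-10)


def test_homopolymer_covariances_are_zero():
    np.testing.assert_allclose(enc.auto_covariance("A" * 12), 0.0, atol=1e-12)
    np.testing.assert_allclose(enc.cross_covariance("A" * 12), 0.0, atol=1e-12)


def test_combined_covariance_is_concatenation():
    seq = random_seq(RNA_ALPHABET, 30)
    combined = enc.AutoCrossCovariance(unit_size=2, max_lag=2).encode(seq)
    np.testing.assert_allclose(
        combined,
        np.concatenate([enc.auto_covariance(seq), enc.cross_covariance(seq)]),
    )
    assert len(combined) == 6 + 12


def test_covariance_too_short_errors():
    with pytest.raises(ValueError, match="too short"):
        enc.auto_covariance("ACGU", unit_size=3, max_lag=2)


# --- pseudo compositions --------------------------------------------------

@pytest.mark.parametrize("k", [2, 3])
def test_pseknc_weight_zero_reduces_to_kmer_frequencies(k):
    seq = random_seq(RNA_ALPHABET, 30)
    vec = enc.pseknc(seq, k=k, lam=2, w=0.0)
    np.testing.assert_allclose(vec[: 4**k], enc.kmer_frequencies(seq, k, "rna"))
    np.testing.assert_allclose(vec[4**k :], 0.0)


@pytest.mark.parametrize("k,lam", [(2, 1), (2, 3), (3, 2)])
def test_pseknc_matches_direct_formula(k, lam):
    for _ in range(100):
        seq = random_seq(RNA_ALPHABET, int(RNG.integers(k + lam + 2, 50)))
        got = enc.pseknc(seq, k=k, lam=lam, w=0.05)
        np.testing.assert_allclose(got, pseknc_direct(seq, k, lam, 0.05), atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(got >= 0)


def test_pseknc_hand_case_six_mer():
    got = enc.pseknc("ACGUAC", k=2, lam=1, w=0.05)
    assert got.shape == (17,)
    np.testing.assert_allclose(got, pseknc_direct("ACGUAC", 2, 1, 0.05), atol=1e-12)


def test_pseaac_weight_zero_is_padded_composition():
    seq = random_seq(PROTEIN_ALPHABET, 40)
    vec = enc.pseaac(seq, lam=5, w=0.0)
    np.testing.assert_allclose(vec[:20], enc.kmer_frequencies(seq, 1, "protein"))
    np.testing.assert_allclose(vec[20:], 0.0)


@pytest.mark.parametrize("lam", [1, 10])
def test_pseaac_matches_direct_formula(lam):
    for _ in range(100):
        seq = random_seq(PROTEIN_ALPHABET, int(RNG.integers(lam + 2, 60)))
        got = enc.pseaac(seq, lam=lam, w=0.05)
        np.testing.assert_allclose(got, pseaac_direct(seq, lam, 0.05), atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)


def test_pseaac_lambda_too_large_errors():
    with pytest.raises(ValueError):
        enc.pseaac("MKTAY", lam=5)


# --- conjoint triad and CTD ----------------------------------------------

def test_conjoint_triad_matches_enumeration_oracle():
    protein_classes = load_triad_classes()
    for _ in range(100):
        seq = random_seq(PROTEIN_ALPHABET, 40)
        np.testing.assert_allclose(
            enc.conjoint_triad(seq), triad_direct(seq, protein_classes), atol=1e-12
        )
    for _ in range(100):
        seq = random_seq(RNA_ALPHABET, 40)
        np.testing.assert_allclose(
            enc.conjoint_triad(seq, alphabet="rna"),
            triad_direct(seq, list(RNA_ALPHABET)),
            atol=1e-12,
        )


def test_conjoint_triad_range_and_max_normalization():
    vec = enc.conjoint_triad(random_seq(PROTEIN_ALPHABET, 40))
    assert np.all(vec >= 0) and np.all(vec <= 1)
    # some triad of 343 is certainly absent in a 40-mer, so f_min = 0 and
    # the most frequent triad maps exactly to 1
    assert vec.max() == pytest.approx(1.0)


def test_conjoint_triad_single_class_sequence():
    vec = enc.conjoint_triad("AGVAGV")  # all residues in one class
    assert np.count_nonzero(vec) == 1


def test_ctd_matches_positional_scan_oracle():
    groups = load_ctd_groups()
    for _ in range(100):
        seq = random_seq(PROTEIN_ALPHABET, 50)
        np.testing.assert_allclose(enc.ctd(seq), ctd_direct(seq, groups), atol=1e-12)


def test_ctd_composition_blocks_sum_to_one():
    vec = enc.ctd(random_seq(PROTEIN_ALPHABET, 61))
    for attr in range(7):
        assert vec[attr * 21 : attr * 21 + 3].sum() == pytest.approx(1.0)


def test_ctd_homopolymer_structure():
    seq = "A" * 10  # single group for every attribute
    vec = enc.ctd(seq)
    for attr in range(7):
        block = vec[attr * 21 : (attr + 1) * 21]
        assert np.all(block[3:6] == 0.0)  # no cross-group transitions
        dist = block[6:].reshape(3, 5)
        occupied = [g for g in range(3) if dist[g].any()]
        assert len(occupied) == 1
        assert dist[occupied[0], 0] == pytest.approx(1 / len(seq))


# --- pair encoding and purity ---------------------------------------------

def test_encode_pair_concatenates_component_encoders():
    apt, prot = random_seq(RNA_ALPHABET, 30), random_seq(PROTEIN_ALPHABET, 50)
    a_enc, p_enc = enc.PseKNC(k=3, lam=2), enc.KmerComposition(k=3, alphabet="protein")
    vec = enc.encode_pair(apt, prot, a_enc, p_enc)
    assert vec.shape == (66 + 8000,)
    np.testing.assert_array_equal(vec[:66], a_enc.encode(apt))
    np.testing.assert_array_equal(vec[66:], p_enc.encode(prot))


@given(st.integers(0, 2**31 - 1))
def test_encoders_are_pure(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(RNA_ALPHABET[i] for i in rng.integers(0, 4, 25))
    e = enc.PseKNC(k=2, lam=2)
    np.testing.assert_array_equal(e.encode(seq), e.encode(seq))


def test_registry_covers_full_grid():
    grid = enc.default_grid()
    assert len(grid) == 54
    assert len(enc.APTAMER_ENCODER_NAMES) == 9
    assert len(enc.PROTEIN_ENCODER_NAMES) == 6
    for apt_name, prot_name in grid[:6]:
        assert enc.aptamer_encoder(apt_name).dimension > 0
        assert enc.protein_encoder(prot_name).dimension > 0


def test_spec_round_trip():
    for e in [enc.PseKNC(k=3, lam=4, w=0.1), enc.CTD(), enc.KmerComposition(k=2)]:
        rebuilt = enc.encoder_from_spec(e.to_spec())
        assert rebuilt.get_params() == e.get_params()
        assert type(rebuilt) is type(e)


def test_sklearn_transform_interface():
    seqs = [random_seq(RNA_ALPHABET, n) for n in (20, 30, 40)]
    X = enc.PseKNC(k=2).fit(seqs).transform(seqs)
    assert X.shape == (3, 18)
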