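import numpy as np
import pytest

import oracles
from conftest import random_seq
from phageprom import (
    DataError,
    EncoderParams,
    PhysicochemicalIndexSet,
    dinucleotide_indices_6,
    encode_dacc,
    encode_kmer,
    encode_moran,
    encode_ncp,
    encode_one_hot,
    encode_pcpsednc,
    encode_pcpsetnc,
    encode_psednc,
    encode_pseeiip,
    encode_pseknc,
    encode_sequence,
    pad_positional,
    standardize_indices,
)
from phageprom.encoders import ENCODERS, encode_dac


def _raw_set(table, order="di", name="raw"):
    return PhysicochemicalIndexSet(name=name, order=order, table=table)


class TestPadPositional:
    def test_pads_to_99_with_zero_rows(self):
        m = encode_one_hot("ACGT")
        assert m.shape == (99, 4)
        assert np.all(m[4:] == 0)

    def test_identity_on_full_input(self):
        m = np.ones((99, 4))
        assert np.array_equal(pad_positional(m), m)

    def test_sum_preserved(self, rng):
        m = rng.random((40, 3))
        assert pad_positional(m).sum() == pytest.approx(m.sum())

    def test_rejects_oversized(self):
        with pytest.raises(DataError):
            pad_positional(np.ones((100, 4)))


class TestPositionalEncodings:
    def test_one_hot_codes(self):
        m = encode_one_hot("ACGT")
        assert np.array_equal(m[:4], np.eye(4))

    def test_one_hot_rows_sum_one_or_zero_for_n(self):
        m = encode_one_hot("ACGNT")
        sums = m.sum(axis=1)
        assert list(sums[:5]) == [1, 1, 1, 0, 1]

    def test_ncp_codes_unique_per_base(self):
        m = encode_ncp("ACGT")
        expected = {"A": (1, 1, 1), "C": (1, 0, 0), "G": (0, 1, 0), "T": (0, 0, 1)}
        rows = {b: tuple(m[i]) for i, b in enumerate("ACGT")}
        assert rows == expected
        assert len(set(rows.values())) == 4


class TestKmer:
    def test_two_windows_by_hand(self):
        v = encode_kmer("AACG", k=3)
        idx = {t: i for i, t in enumerate(
            sorted("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
        )}
        assert v[idx["AAC"]] == pytest.approx(0.5)
        assert v[idx["ACG"]] == pytest.approx(0.5)
        assert v.sum() == pytest.approx(1.0)

    def test_homopolymer(self):
        v = encode_kmer("AAAA", k=3)
        assert v[0] == pytest.approx(1.0) and v.sum() == pytest.approx(1.0)

    def test_n_windows_excluded(self):
        v = encode_kmer("AANAA", k=2)
        # only AA (twice) is ambiguity-free
        assert v[0] == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(DataError):
            encode_kmer("AC", k=3)

    def test_sums_to_one_matches_window_count(self, rng):
        for _ in range(10):
            seq = random_seq(rng, int(rng.integers(5, 60)))
            assert encode_kmer(seq, 3).sum() == pytest.approx(1.0)


class TestPseEIIP:
    def test_aaa_by_hand(self):
        v = encode_pseeiip("AAA")
        assert v[0] == pytest.approx(3 * 0.1260)
        assert np.count_nonzero(v) == 1

    def test_ttt_by_hand(self):
        v = encode_pseeiip("TTT")
        assert v[-1] == pytest.approx(3 * 0.1335)

    def test_mean_mode_divides_by_three(self):
        assert encode_pseeiip("AAA", mode="mean")[0] == pytest.approx(0.1260)

    def test_bounded_by_max_eiip_sum(self, rng):
        seq = random_seq(rng, 50)
        assert encode_pseeiip(seq).max() <= 3 * 0.1340 + 1e-12


class TestPseFamily:
    def test_psednc_lam0_is_dinucleotide_frequencies(self):
        seq = "ACGTACGTACGTACGT"
        v = encode_psednc(seq, EncoderParams(lam=0))
        assert np.allclose(v, encode_kmer(seq, 2))

    def test_psednc_w0_matches_lam0_head(self):
        seq = "ACGTTGCAACGTTGCA"
        v = encode_psednc(seq, EncoderParams(lam=3, w=0.0))
        head = encode_psednc(seq, EncoderParams(lam=0))
        assert np.allclose(v[:16], head)
        assert np.allclose(v[16:], 0.0)

    def test_pseknc_k2_lam0_equals_psednc(self):
        seq = "ACGTTGCAACGTTGCA"
        a = encode_pseknc(seq, EncoderParams(k=2, lam=0))
        b = encode_psednc(seq, EncoderParams(lam=0))
        assert np.allclose(a, b)

    def test_pcpsetnc_lam0_is_trinucleotide_frequencies(self):
        seq = "ACGTTGCAACGTTGCA"
        assert np.allclose(
            encode_pcpsetnc(seq, EncoderParams(lam=0)), encode_kmer(seq, 3)
        )

    @pytest.mark.parametrize("encoder,params", [
        (encode_psednc, EncoderParams(lam=2, w=0.1)),
        (encode_pseknc, EncoderParams(k=3, lam=2, w=0.1)),
        (encode_pcpsednc, EncoderParams(lam=2, w=0.1)),
        (encode_pcpsetnc, EncoderParams(lam=2, w=0.1)),
    ])
    def test_entries_sum_to_one_and_nonnegative(self, encoder, params, rng):
        for _ in range(10):
            seq = random_seq(rng, 30)
            v = encoder(seq, params)
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert (v >= 0).all()

    def test_lambda_too_large(self):
        with pytest.raises(DataError):
            encode_psednc("ACGT", EncoderParams(lam=10))


class TestCovarianceEncodings:
    def test_dac_zero_when_profile_constant(self):
        # index values equal for AC and CA -> constant profile on "ACAC..."
        table = {d: {"i1": 1.0 if d in ("AC", "CA") else float(i)}
                 for i, d in enumerate(oracles.DINUCS)}
        idx = standardize_indices(_raw_set(table))
        v = encode_dac("ACACACACAC", EncoderParams(max_lag=2, index_set=idx))
        assert np.allclose(v, 0.0)

    def test_dacc_dimension_n_squared_times_lag(self, raw_di6):
        sub = {d: {k: raw_di6[d][k] for k in ("twist", "roll")} for d in raw_di6}
        idx = _raw_set(sub)
        v = encode_dacc("ACGTACGTACGTACGTACGT", EncoderParams(max_lag=2, index_set=idx))
        assert v.shape == (2 * 2 * 2,)  # N^2 x LAG for N=2

    def test_lag_too_large(self):
        with pytest.raises(DataError):
            encode_dacc("ACGT", EncoderParams(max_lag=10))


class TestMoran:
    def test_constant_profile_yields_zero(self):
        table = {d: {"i1": 2.5 if d in ("AC", "CA") else float(i)}
                 for i, d in enumerate(oracles.DINUCS)}
        idx = standardize_indices(_raw_set(table))
        v = encode_moran("ACACACACACA", EncoderParams(max_lag=2, index_set=idx))
        assert np.allclose(v, 0.0)

    def test_periodic_profile_gives_unity_at_period_lag(self, raw_di6):
        # "AC" repeated: profile alternates P(AC), P(CA); lag 2 realigns it
        seq = "AC" * 10 + "A"  # 21-mer -> 20 windows (even)
        v = encode_moran(seq, EncoderParams(max_lag=2))
        n_idx = dinucleotide_indices_6().n_indices
        lag2 = v[1::2]
        assert lag2.shape == (n_idx,)
        assert np.allclose(lag2, 1.0, atol=1e-9)


class TestStandardize:
    def test_mean_zero_sd_one(self, raw_di6):
        std = standardize_indices(_raw_set(raw_di6))
        m = std.matrix()
        assert np.allclose(m.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(m.std(axis=0), 1.0, atol=1e-12)

    def test_idempotent(self, raw_di6):
        once = standardize_indices(_raw_set(raw_di6))
        twice = standardize_indices(once)
        assert np.allclose(once.matrix(), twice.matrix())

    def test_constant_index_rejected(self):
        table = {d: {"flat": 1.0} for d in oracles.DINUCS}
        with pytest.raises(DataError, match="flat"):
            standardize_indices(_raw_set(table))

    def test_incomplete_table_rejected(self):
        table = {d: {"i": 1.0} for d in oracles.DINUCS[:-1]}
        with pytest.raises(DataError, match="missing"):
            _raw_set(table)


SCHEME_DIMS = {
    "onehot": (99, 4),
    "ncp": (99, 3),
    "kmer": (64,),
    "pseeiip": (64,),
    "psednc": (18,),     # 16 + lam with lam=2
    "pseknc": (66,),     # 4^3 + 2
    "pcpsednc": (18,),
    "pcpsetnc": (66,),
    "dacc": (72,),       # 6^2 x 2
    "moran": (12,),      # 6 x 2
}


class TestRegistry:
    @pytest.mark.parametrize("scheme", sorted(ENCODERS))
    def test_closed_form_dimensions(self, scheme, rng):
        out = encode_sequence(random_seq(rng, 40), scheme, EncoderParams())
        assert out.shape == SCHEME_DIMS[scheme]

    @pytest.mark.parametrize("scheme", sorted(ENCODERS))
    def test_encoders_are_pure(self, scheme, rng):
        seq = random_seq(rng, 40)
        a = encode_sequence(seq, scheme, EncoderParams())
        b = encode_sequence(seq, scheme, EncoderParams())
        assert np.array_equal(a, b)

    def test_unknown_scheme(self):
        with pytest.raises(DataError, match="unknown"):
            encode_sequence("ACGT", "embedding")


@pytest.fixture(scope="module")
def seqs():
    rng = np.random.default_rng(2022)
    return [random_seq(rng, 20) for _ in range(25)]


class TestOracleAgreement:
    """Each encoder against its literal brute-force transcription."""

    def test_all_ten_schemes_match_oracles(self, seqs, raw_di6, raw_di38, raw_tri6):
        p6 = EncoderParams(lam=2, w=0.1, max_lag=2, k=3,
                           index_set=_raw_set(raw_di6))
        p38 = EncoderParams(lam=2, w=0.1, index_set=_raw_set(raw_di38))
        ptri = EncoderParams(lam=2, w=0.1, index_set=_raw_set(raw_tri6, order="tri"))
        pairs = {
            "onehot": (lambda s: encode_one_hot(s), oracles.oracle_one_hot),
            "ncp": (lambda s: encode_ncp(s), oracles.oracle_ncp),
            "kmer": (lambda s: encode_kmer(s, 3), lambda s: oracles.oracle_kmer(s, 3)),
            "pseeiip": (encode_pseeiip, oracles.oracle_pseeiip),
            "psednc": (
                lambda s: encode_psednc(s, p6),
                lambda s: oracles.oracle_psednc(s, raw_di6, 2, 0.1),
            ),
            "pseknc": (
                lambda s: encode_pseknc(s, p6),
                lambda s: oracles.oracle_pseknc(s, raw_di6, 3, 2, 0.1),
            ),
            "pcpsednc": (
                lambda s: encode_pcpsednc(s, p38),
                lambda s: oracles.oracle_psednc(s, raw_di38, 2, 0.1),
            ),
            "pcpsetnc": (
                lambda s: encode_pcpsetnc(s, ptri),
                lambda s: oracles.oracle_pcpsetnc(s, raw_tri6, 2, 0.1),
            ),
            "dacc": (
                lambda s: encode_dacc(s, p6),
                lambda s: oracles.oracle_dacc(s, raw_di6, 2),
            ),
            "moran": (
                lambda s: encode_moran(s, p6),
                lambda s: oracles.oracle_moran(s, raw_di6, 2),
            ),
        }
        assert set(pairs) == set(ENCODERS)
        for name, (impl, oracle) in pairs.items():
            for seq in seqs:
                got = np.asarray(impl(seq), dtype=float)
                want = np.asarray(oracle(seq), dtype=float)
                np.testing.assert_allclose(
                    got, want, atol=1e-9, err_msg=f"scheme {name}, seq {seq}"
                )
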