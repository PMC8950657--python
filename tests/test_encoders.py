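"""Golden encoding vectors, dimension formulas, and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dhupred as dp
from dhupred import encoders as enc

rna = st.text(alphabet="ACGU", min_size=1, max_size=60)


def brute_kmer(seq: str, k: int, denom_mode: str) -> np.ndarray:
    """Independent oracle: explicit substring counting per lexicographic k-mer."""
    mers = ["".join(p) for p in itertools.product("ACGU", repeat=k)]
    counts = np.array(
        [sum(seq[i : i + k] == m for i in range(len(seq) - k + 1)) for m in mers],
        dtype=float,
    )
    denom = len(seq) - k + 1 if denom_mode == "kmer_count" else len(seq)
    return counts / denom


class TestGoldenVectors:
    """Hand-derived expected vectors for the worked toy sequences."""

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A", [1, 1, 1]),
            ("U", [0, 0, 1]),
            ("C", [0, 1, 0]),
            ("G", [1, 0, 0]),
            ("GAGACU", [1, 0, 0, 1, 1, 1, 1, 0, 0, 1, 1, 1, 0, 1, 0, 0, 0, 1]),
        ],
    )
    def test_ncp(self, seq, expected):
        assert enc.encode_ncp(seq).tolist() == expected

    def test_binary_gagacu_prefix_and_suffix(self):
        v = enc.encode_binary("GAGACU")
        # the worked example: starts 01001000 (G,A) and ends 0001 (U)
        assert v[:8].tolist() == [0, 1, 0, 0, 1, 0, 0, 0]
        assert v[-4:].tolist() == [0, 0, 0, 1]
        assert enc.encode_binary("C").tolist() == [0, 0, 1, 0]
        assert enc.encode_binary("U").tolist() == [0, 0, 0, 1]

    def test_enac(self):
        assert enc.encode_enac("AAAAA", w=5).tolist() == [1, 0, 0, 0]
        assert enc.encode_enac("GAGAC", w=5).tolist() == pytest.approx(
            [0.4, 0.2, 0.4, 0.0]
        )

    def test_kmer_modes(self):
        v = enc.encode_kmer("AAAA", k=2, denom_mode="kmer_count")
        assert v[0] == 1.0 and v[1:].sum() == 0.0
        v = enc.encode_kmer("AAAA", k=2, denom_mode="seq_length")
        assert v[0] == pytest.approx(0.75)
        nac = enc.encode_nac("GAGACU")
        assert nac.tolist() == pytest.approx([1 / 3, 1 / 6, 1 / 3, 1 / 6])

    def test_anf(self):
        assert enc.encode_anf("AAAA").tolist() == [1, 1, 1, 1]
        assert enc.encode_anf("GAGACU").tolist() == pytest.approx(
            [1, 1 / 2, 2 / 3, 1 / 2, 1 / 5, 1 / 6]
        )

    def test_eiip(self):
        assert enc.encode_eiip("AAAA").tolist() == [0.1260] * 4
        assert enc.encode_eiip("GA").tolist() == [0.0806, 0.1260]

    def test_pseeiip(self):
        v = enc.encode_pseeiip("AAAA")
        assert v[0] == pytest.approx(3 * 0.1260)
        assert v[1:].sum() == 0.0
        v = enc.encode_pseeiip("ACG")
        nonzero = np.flatnonzero(v)
        acg_index = ["".join(p) for p in itertools.product("ACGU", repeat=3)].index(
            "ACG"
        )
        assert nonzero.tolist() == [acg_index]
        assert v[acg_index] == pytest.approx(0.1260 + 0.1340 + 0.0806)

    @pytest.mark.parametrize(
        "kmer,canonical",
        [("UU", "AA"), ("AU", "AU"), ("GA", "GA"), ("ACG", "ACG"), ("CGU", "ACG")],
    )
    def test_canonical_kmer(self, kmer, canonical):
        assert enc.canonical_kmer(kmer) == canonical

    def test_rckmer_pools_reverse_complements(self):
        v = enc.encode_rckmer("UUUU", k=2)
        classes = enc.canonical_kmer_classes(2)
        assert v[classes.index("AA")] == 1.0
        assert v.sum() == pytest.approx(1.0)


class TestDimensions:
    DIMS_41 = {
        "NCP": 123,
        "BINARY": 164,
        "ENAC": 148,
        "NAC": 4,
        "DNC": 16,
        "TNC": 64,
        "ANF": 41,
        "EIIP": 41,
        "PseEIIP": 64,
    }

    @pytest.mark.parametrize("name,dim", sorted(DIMS_41.items()))
    def test_formula_and_actual_dimension_41nt(self, name, dim):
        seq = "GACU" * 10 + "U"
        spec = enc.EncoderSpec(name)
        assert enc.feature_dimension(spec, 41) == dim
        assert enc.encode_sequence(seq, spec).shape == (dim,)

    @pytest.mark.parametrize(
        "name,params,dim", [("Kmer", {"k": 3}, 64), ("RCKmer", {"k": 2}, 10),
                            ("RCKmer", {"k": 3}, 32)]
    )
    def test_kmer_family_dimensions(self, name, params, dim):
        spec = enc.EncoderSpec(name, params)
        assert enc.feature_dimension(spec, 41) == dim
        assert enc.encode_sequence("GACU" * 10 + "U", spec).shape == (dim,)

    def test_canonical_class_counts_partition_all_kmers(self):
        # 4 self-complementary 2-mers + 6 pairs = 10; no odd-length
        # self-complements exist, so 64/2 = 32 classes for k=3.
        assert len(enc.canonical_kmer_classes(2)) == 10
        assert len(enc.canonical_kmer_classes(3)) == 32
        for k in (2, 3):
            mapped = {enc.canonical_kmer("".join(p))
                      for p in itertools.product("ACGU", repeat=k)}
            assert mapped == set(enc.canonical_kmer_classes(k))


class TestOracles:
    def test_kmer_family_matches_brute_force_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            length = int(rng.integers(10, 61))
            seq = "".join(rng.choice(list("ACGU"), size=length))
            for k in (1, 2, 3):
                for mode in ("kmer_count", "seq_length"):
                    np.testing.assert_allclose(
                        enc.encode_kmer(seq, k=k, denom_mode=mode),
                        brute_kmer(seq, k, mode),
                        atol=0,
                    )

    def test_fixed_k_wrappers_agree_with_kmer(self):
        seq = "GAGACUGAUCCGUA"
        np.testing.assert_array_equal(enc.encode_nac(seq), enc.encode_kmer(seq, 1))
        np.testing.assert_array_equal(enc.encode_dnc(seq), enc.encode_kmer(seq, 2))
        np.testing.assert_array_equal(enc.encode_tnc(seq), enc.encode_kmer(seq, 3))


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(rna)
    def test_binary_one_hot_blocks_and_ncp_codes(self, seq):
        b = enc.encode_binary(seq).reshape(-1, 4)
        assert (b.sum(axis=1) == 1).all()
        n = enc.encode_ncp(seq).reshape(-1, 3)
        valid = {tuple(v) for v in enc.NCP_CODES.values()}
        assert {tuple(row) for row in n} <= valid

    @settings(max_examples=60, deadline=None)
    @given(rna.filter(lambda s: len(s) >= 3))
    def test_rckmer_strand_collapse_symmetry(self, seq):
        rc = enc.reverse_complement(seq)
        for k in (2, 3):
            np.testing.assert_allclose(
                enc.encode_rckmer(seq, k=k), enc.encode_rckmer(rc, k=k), atol=1e-15
            )

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=2, max_size=3))
    def test_canonical_kmer_idempotent(self, m):
        assert enc.canonical_kmer(enc.canonical_kmer(m)) == enc.canonical_kmer(m)

    @settings(max_examples=40, deadline=None)
    @given(rna.filter(lambda s: len(s) >= 5))
    def test_composition_normalisation_and_anf_range(self, seq):
        for k in (1, 2, 3):
            assert enc.encode_kmer(seq, k).sum() == pytest.approx(1.0)
        e = enc.encode_enac(seq, w=5).reshape(-1, 4)
        np.testing.assert_allclose(e.sum(axis=1), 1.0)
        a = enc.encode_anf(seq)
        assert a[0] == 1.0 and (a > 0).all() and (a <= 1).all()

    def test_encoders_are_pure(self):
        seq = "GAGACUGAUCCGUAGGACU"
        for name in dp.ENCODER_NAMES:
            spec = enc.EncoderSpec(name)
            np.testing.assert_array_equal(
                enc.encode_sequence(seq, spec), enc.encode_sequence(seq, spec)
            )


class TestErrorsAndBatch:
    def test_invalid_character_reports_position(self):
        with pytest.raises(enc.EncodingError, match="position 3"):
            enc.encode_ncp("ACNU")

    def test_parameter_guards(self):
        with pytest.raises(enc.EncodingError):
            enc.encode_enac("ACG", w=5)
        with pytest.raises(enc.EncodingError):
            enc.encode_kmer("AC", k=3)
        with pytest.raises(enc.EncodingError):
            enc.encode_pseeiip("AC")
        with pytest.raises(ValueError, match="unknown encoder"):
            enc.EncoderSpec("SSC")

    def test_encode_dataset_shapes_and_order(self, default_dataset):
        fm = dp.encode_dataset(default_dataset, enc.EncoderSpec("NCP"))
        assert fm.values.shape == (550, 123)
        assert fm.sample_ids == default_dataset.ids
        fm = dp.encode_dataset(default_dataset, enc.EncoderSpec("BINARY"))
        assert fm.values.shape == (550, 164)

    def test_encode_dataset_empty_keeps_feature_names(self):
        fm = dp.encode_dataset(dp.Dataset((), 41), enc.EncoderSpec("NCP"))
        assert fm.values.shape == (0, 123)
        assert len(fm.feature_names) == 123

    def test_encode_dataset_names_offending_record(self):
        d = dp.Dataset((dp.SequenceRecord("bad1", "E.coli", 0, "ACGU"),))
        object.__setattr__(d.records[0], "sequence", "ACNN")
        with pytest.raises(enc.EncodingError, match="bad1"):
            dp.encode_dataset(d, enc.EncoderSpec("NCP"))

    def test_feature_matrix_tsv_roundtrip(self, tmp_path, tiny_dataset):
        import pandas as pd

        fm = dp.encode_dataset(tiny_dataset, enc.EncoderSpec("NAC"))
        p = fm.to_tsv(tmp_path / "nac.tsv")
        df = pd.read_csv(p, sep="\t", index_col=0)
        np.testing.assert_allclose(df.values, fm.values)
        assert list(df.columns) == list(fm.feature_names)
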