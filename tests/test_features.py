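from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subgolgi import (
    EncoderConfig,
    KGapDipeptideEncoder,
    SplitCompositionEncoder,
    SyntheticSpec,
    encode_dataset,
    encode_kgap_dipeptide,
    encode_saac,
    generate,
    kgap_feature_names,
    saac_feature_names,
)
from subgolgi.features import EncodingError
from subgolgi.io import AMINO_ACIDS

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=200)


def kgap_oracle(seq: str, k: int) -> dict[str, float]:
    """Brute-force enumeration of all (i, i+k+1) residue pairs."""
    pairs = Counter(seq[i] + seq[i + k + 1] for i in range(len(seq) - k - 1))
    total = len(seq) - k - 1
    return {f"{p}.gap{k}": c / total for p, c in pairs.items()}


def saac_oracle(seq: str, xn: int, xc: int) -> dict[str, float]:
    """Independent per-segment letter-count oracle."""
    segments = {
        "Nterminal": seq[:xn],
        "InterTier": seq[xn : len(seq) - xc],
        "Cterminal": seq[len(seq) - xc :],
    }
    out = {}
    for seg_name, seg in segments.items():
        counts = Counter(seg)
        for aa in AMINO_ACIDS:
            out[f"{seg_name}_{aa}"] = counts.get(aa, 0) / len(seg)
    return out


class TestKGapDipeptide:
    def test_single_pair_sequence(self):
        v = encode_kgap_dipeptide("AAAA", k=2)
        names = kgap_feature_names(2)
        assert v[names.index("AA.gap2")] == 1.0
        assert v.sum() == 1.0
        assert np.count_nonzero(v) == 1

    def test_three_pair_sequence(self):
        v = encode_kgap_dipeptide("ACDEFG", k=2)
        names = kgap_feature_names(2)
        nonzero = {names[j]: v[j] for j in np.flatnonzero(v)}
        assert nonzero == pytest.approx(
            {"AE.gap2": 1 / 3, "CF.gap2": 1 / 3, "DG.gap2": 1 / 3}
        )

    def test_vector_length_is_400(self):
        assert encode_kgap_dipeptide("MKVLLAW", k=2).shape == (400,)
        assert len(kgap_feature_names(2)) == 400

    def test_too_short_sequence_names_L_and_k(self):
        with pytest.raises(EncodingError, match="length 3.*k=2"):
            encode_kgap_dipeptide("MKV", k=2)

    @pytest.mark.parametrize("k", [0, 1, 2, 4])
    def test_matches_brute_force_oracle(self, rng, k):
        names = kgap_feature_names(k)
        for _ in range(25):
            L = int(rng.integers(k + 2, 300))
            seq = "".join(rng.choice(list(AMINO_ACIDS), L))
            v = encode_kgap_dipeptide(seq, k)
            expected = kgap_oracle(seq, k)
            got = {names[j]: v[j] for j in np.flatnonzero(v)}
            assert got == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(seq=seq_strategy)
    def test_normalisation_sums_to_one(self, seq):
        assert encode_kgap_dipeptide(seq, k=2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_distance_convention(self):
        # distance k=2 pairs (i, i+2): "ACDE" -> AD, CE
        v = encode_kgap_dipeptide("ACDE", k=2, gap_convention="distance")
        names = kgap_feature_names(2)
        nonzero = {names[j]: v[j] for j in np.flatnonzero(v)}
        assert nonzero == pytest.approx({"AD.gap2": 0.5, "CE.gap2": 0.5})


class TestSaac:
    def test_forced_block_construction(self):
        seq = "A" * 30 + "CD" + "E" * 30
        v = encode_saac(seq, 30, 30)
        names = saac_feature_names()
        lookup = dict(zip(names, v))
        assert lookup["Nterminal_A"] == 1.0
        assert lookup["InterTier_C"] == 0.5
        assert lookup["InterTier_D"] == 0.5
        assert lookup["Cterminal_E"] == 1.0
        assert np.count_nonzero(v) == 4

    def test_vector_length_is_60(self):
        seq = "".join(np.random.default_rng(0).choice(list(AMINO_ACIDS), 100))
        assert encode_saac(seq).shape == (60,)

    def test_matches_counting_oracle(self, rng):
        names = saac_feature_names()
        for _ in range(25):
            L = int(rng.integers(61, 400))
            seq = "".join(rng.choice(list(AMINO_ACIDS), L))
            got = dict(zip(names, encode_saac(seq)))
            assert got == pytest.approx(saac_oracle(seq, 30, 30))

    def test_each_block_sums_to_one(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), 200))
        v = encode_saac(seq)
        for b in range(3):
            assert v[b * 20 : (b + 1) * 20].sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_short_names_lengths(self):
        with pytest.raises(EncodingError, match="length 60.*Xn=30.*Xc=30"):
            encode_saac("A" * 60, 30, 30)

    def test_prepending_changes_only_n_terminal_block(self, rng):
        """Shifting a window of dummy residues in changes the N block as the
        oracle predicts while the C-terminal block oracle still agrees."""
        seq = "".join(rng.choice(list(AMINO_ACIDS), 150))
        shifted = "W" * 30 + seq
        got = dict(zip(saac_feature_names(), encode_saac(shifted)))
        assert got == pytest.approx(saac_oracle(shifted, 30, 30))
        assert got["Nterminal_W"] == 1.0
        # C-terminal block unchanged by N-terminal padding
        base = dict(zip(saac_feature_names(), encode_saac(seq)))
        for aa in AMINO_ACIDS:
            assert got[f"Cterminal_{aa}"] == base[f"Cterminal_{aa}"]


class TestEncodeDataset:
    @pytest.mark.parametrize(
        "parts, expected_cols",
        [(("kgapdc", "saac"), 460), (("kgapdc",), 400), (("saac",), 60)],
    )
    def test_column_counts(self, parts, expected_cols):
        ds = generate(SyntheticSpec(n_cis=3, n_trans=4, seed=0))
        m = encode_dataset(ds, parts)
        assert m.n_features == expected_cols
        assert m.n_samples == 7
        assert m.labels is not None

    def test_empty_part_list_rejected(self):
        ds = generate(SyntheticSpec(n_cis=2, n_trans=2, seed=0))
        with pytest.raises(ValueError):
            encode_dataset(ds, ())

    def test_failing_record_named_in_error(self):
        from subgolgi import Dataset, ProteinRecord

        ds = Dataset([ProteinRecord(id="shorty", sequence="MKVLL", label="cis")])
        with pytest.raises(EncodingError, match="shorty"):
            encode_dataset(ds, ("saac",))

    def test_transformers_match_functions(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 120)) for _ in range(5)]
        np.testing.assert_array_equal(
            KGapDipeptideEncoder(k=2).fit(seqs).transform(seqs),
            np.vstack([encode_kgap_dipeptide(s, 2) for s in seqs]),
        )
        np.testing.assert_array_equal(
            SplitCompositionEncoder().fit(seqs).transform(seqs),
            np.vstack([encode_saac(s) for s in seqs]),
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EncoderConfig(k=-1)
        with pytest.raises(ValueError):
            EncoderConfig(xn=0)
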