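"""Encoder correctness: hand counts, formula oracles, and invariants.

The PseAAC and PSSM oracles below are literal transcriptions of the
defining formulas, written as plain loops sharing no code with the
package implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from succsite.aaindex import default_table
from succsite.encoders import (CKSAAPConfig, DEFAULT_LAYOUT, FeatureBlockLayout,
                               PseAACConfig, encode_cksaap, encode_disorder,
                               encode_pseaac, encode_pssm, encode_window, fuse,
                               read_feature_tsv, write_feature_tsv)
from succsite.windows import PeptideWindow, STANDARD_AA


def _window(residues, pads=(0, 0)):
    return PeptideWindow("P", 11, residues, n_pad_left=pads[0],
                         n_pad_right=pads[1], label=None)


# ---------------------------------------------------------------- oracles

def pseaac_oracle(seq, lam, w):
    """Literal transcription of the Type-1 pseudo-AA composition formulas
    for a window of standard residues only."""
    table = default_table()
    idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
    props = [table.h1, table.h2, table.m]
    L = len(seq)
    b = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            theta = 0.0
            for p in props:
                theta += (p[idx[seq[i]]] - p[idx[seq[i + j]]]) ** 2
            total += theta / 3.0
        b.append(total / (L - j))
    counts = [seq.count(aa) for aa in STANDARD_AA]
    f = [c / sum(counts) for c in counts]
    denom = sum(f) + w * sum(b)
    return np.array([fi / denom for fi in f] + [w * bj / denom for bj in b])


def pssm_oracle(matrix):
    """Flatten by position then per-column means, written out longhand."""
    L, n = matrix.shape
    flat = [matrix[i][j] for i in range(L) for j in range(n)]
    means = [sum(matrix[i][j] for i in range(L)) / L for j in range(n)]
    return np.array(flat + means)


# ---------------------------------------------------------------- CKSAAP

class TestCKSAAP:
    def test_hand_counted_adjacent_pairs(self):
        fv = encode_cksaap(_window("A" * 10 + "K" + "A" * 10), CKSAAPConfig(k_max=0))
        values = dict(zip(
            (a + b for a in STANDARD_AA for b in STANDARD_AA), fv.values))
        assert values["AA"] == pytest.approx(18 / 20)
        assert values["AK"] == pytest.approx(1 / 20)
        assert values["KA"] == pytest.approx(1 / 20)
        assert sum(v for k, v in values.items() if k not in ("AA", "AK", "KA")) == 0

    def test_all_pad_window_encodes_to_zero(self):
        w = PeptideWindow("P", 11, "X" * 10 + "K" + "X" * 10, 10, 0)
        fv = encode_cksaap(w)
        # only pads and the lone center: no standard-standard adjacent pairs
        # except none, since every neighbour of K is a pad
        assert fv.values.sum() == 0 or set(np.nonzero(fv.values)[0]) == set()

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet=STANDARD_AA, min_size=21, max_size=21))
    def test_per_k_block_sums_to_one_on_standard_windows(self, seq):
        fv = encode_cksaap(_window(seq), CKSAAPConfig(k_max=4))
        for k in range(5):
            block = fv.values[k * 400:(k + 1) * 400]
            assert block.sum() == pytest.approx(1.0)
            assert np.all((block >= 0) & (block <= 1))

    def test_denominator_unchanged_by_padding(self):
        # one left pad: 19 countable adjacent pairs over denominator 20
        w = PeptideWindow("P", 11, "X" + "A" * 20, 1, 0)
        fv = encode_cksaap(w, CKSAAPConfig(k_max=0))
        assert fv.values.sum() == pytest.approx(19 / 20)

    def test_window_too_short_for_kmax(self):
        with pytest.raises(ValueError, match="too short"):
            encode_cksaap(PeptideWindow("P", 2, "AKA"), CKSAAPConfig(k_max=4))


# ---------------------------------------------------------------- disorder

class TestDisorderEncoder:
    def test_identity_pass_through(self):
        scores = np.linspace(0.1, 0.9, 21)
        fv = encode_disorder(scores)
        np.testing.assert_array_equal(fv.values, scores)

    def test_out_of_range_scores_rejected(self):
        bad = np.full(21, 0.5)
        bad[3] = 1.2
        with pytest.raises(ValueError):
            encode_disorder(bad)


# ---------------------------------------------------------------- PseAAC

class TestPseAAC:
    def test_homopolymer_has_zero_correlation(self):
        fv = encode_pseaac(_window("A" * 21))
        assert fv.values[0] == pytest.approx(1.0)
        assert np.all(fv.values[1:] == 0)

    def test_output_length_is_20_plus_lambda(self):
        assert len(encode_pseaac(_window("ARNDCQEGHILKMFPSTWYVK"))) == 40
        cfg = PseAACConfig(lam=5)
        assert len(encode_pseaac(_window("ARNDCQEGHILKMFPSTWYVK"), cfg=cfg)) == 25

    @pytest.mark.parametrize("seq,lam", [
        ("ARNDCQEGHILKMFPSTWYVK", 2),
        ("ARNDCQEGHILKMFPSTWYVK", 20),
        ("KKKAAAEEEWWWLLLPPPRRR", 7),
    ])
    def test_matches_formula_oracle(self, seq, lam):
        cfg = PseAACConfig(lam=lam, w=0.05)
        fv = encode_pseaac(_window(seq), cfg=cfg)
        np.testing.assert_allclose(fv.values, pseaac_oracle(seq, lam, 0.05),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet=STANDARD_AA, min_size=21, max_size=21))
    def test_components_sum_to_one(self, seq):
        fv = encode_pseaac(_window(seq))
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_lambda_20_single_term_tail(self):
        # L=21, j=20 leaves exactly one (i=1) correlation term
        seq = "A" * 20 + "W"
        fv = encode_pseaac(_window(seq), cfg=PseAACConfig(lam=20))
        table = default_table()
        ia, iw = STANDARD_AA.index("A"), STANDARD_AA.index("W")
        expected_b20 = np.mean([
            (p[ia] - p[iw]) ** 2 for p in (table.h1, table.h2, table.m)
        ])
        # un-normalize the last component to recover b_20
        denom_ratio = fv.values[-1] / fv.values[:20].sum()  # w*b20 / Σf
        assert denom_ratio == pytest.approx(0.05 * expected_b20)

    def test_padded_terms_dropped_with_divisor_reduction(self):
        # pads contribute neither to composition nor to correlation terms
        w = PeptideWindow("P", 11, "X" * 10 + "K" + "A" * 10, 10, 0)
        fv = encode_pseaac(w, cfg=PseAACConfig(lam=2))
        counts = {"K": 1, "A": 10}
        assert fv.values[STANDARD_AA.index("K")] / fv.values[STANDARD_AA.index("A")] \
            == pytest.approx(counts["K"] / counts["A"])

    def test_all_pad_window_is_an_error(self):
        w = PeptideWindow("P", 11, "X" * 9 + "BKB" + "X" * 9, 9, 9)
        w2 = PeptideWindow("P", 11, "X" * 10 + "B" + "X" * 10, 10, 10)
        encode_pseaac(w)  # K present: fine
        with pytest.raises(ValueError, match="no standard residues"):
            encode_pseaac(w2)

    def test_property_table_standardized(self):
        t = default_table()
        for col in (t.h1, t.h2, t.m):
            assert abs(col.mean()) < 1e-9
            assert col.std() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- PSSM

class TestPSSMEncoder:
    def test_zero_matrix(self):
        fv = encode_pssm(np.zeros((21, 20)))
        assert len(fv) == 440 and np.all(fv.values == 0)

    def test_column_means_by_construction(self):
        m = np.tile(np.arange(1, 21, dtype=float), (21, 1))
        fv = encode_pssm(m)
        np.testing.assert_allclose(fv.values[-20:], np.arange(1, 21))

    def test_matches_formula_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            m = rng.integers(-10, 11, size=(21, 20)).astype(float)
            np.testing.assert_array_equal(encode_pssm(m).values, pssm_oracle(m))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="20"):
            encode_pssm(np.zeros((21, 19)))


# ---------------------------------------------------------------- fusion

class TestFusion:
    def test_layout_dimensionalities(self):
        layout = DEFAULT_LAYOUT
        assert dict(layout.blocks) == {
            "cksaap": 2000, "disorder": 21, "pseaac": 40, "pssm": 440}
        assert layout.total == 2501

    def test_fused_vector_and_names(self, rng):
        w = _window("ARNDCQEGHILKMFPSTWYVK")
        fv = encode_window(w, rng.integers(-5, 6, (21, 20)).astype(float),
                           np.full(21, 0.5))
        assert len(fv) == 2501
        names = DEFAULT_LAYOUT.feature_names()
        assert len(names) == len(set(names)) == 2501
        assert names[2000].startswith("disorder:0")
        assert DEFAULT_LAYOUT.block_of(2000) == ("disorder", 0)
        assert DEFAULT_LAYOUT.block_of(2061) == ("pssm", 0)

    def test_missing_block_is_an_error(self):
        w = _window("A" * 21)
        with pytest.raises(ValueError, match="missing feature block"):
            fuse({"cksaap": encode_cksaap(w)})

    def test_encoders_are_pure(self, rng):
        w = _window("ARNDCQEGHILKMFPSTWYVK")
        m = rng.normal(size=(21, 20))
        d = np.full(21, 0.3)
        a = encode_window(w, m, d).values
        b = encode_window(w, m, d).values
        np.testing.assert_array_equal(a, b)


def test_feature_tsv_round_trip(tmp_path, small_features):
    df = small_features.iloc[:8]
    path = tmp_path / "feats.tsv"
    write_feature_tsv(df, path)
    back = read_feature_tsv(path)
    assert list(back.columns) == list(df.columns)
    np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), rtol=1e-8)


def test_feature_sidecar_round_trip(tmp_path, small_features):
    df = small_features.iloc[:8]
    path = tmp_path / "feats.tsv"
    write_feature_tsv(df, path, sidecar=True)
    back = read_feature_tsv(path)  # prefers the binary sidecar
    np.testing.assert_array_equal(back.drop(columns="label").to_numpy(),
                                  df.drop(columns="label").to_numpy())
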