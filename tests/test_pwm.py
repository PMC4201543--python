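"""PWM computation and feature encoding, checked against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caspcleave.pwm import (
    BackgroundDistribution,
    PWMError,
    PositionWeightMatrix,
    compute_background,
    compute_pwm,
    encode_window,
    feature_vector_to_numeric,
    structure_context,
)
from caspcleave.seqio import AMINO_ACIDS, CleavageWindow, ProteinRecord

windows_strategy = st.lists(
    st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=8), min_size=1, max_size=40
)


def brute_force_pwm(window_strings, background, pseudocount):
    """Independent count-and-divide oracle over the residue table."""
    out = np.zeros((20, 8))
    for j in range(8):
        column = [w[j] for w in window_strings if w[j] != "X"]
        n = len(column)
        for i, aa in enumerate(AMINO_ACIDS):
            b = background.freq[aa]
            ratio = (column.count(aa) + pseudocount * b) / ((n + pseudocount) * b)
            out[i, j] = math.log2(ratio)
    return out


class TestBackground:
    def test_hand_counted_laplace_frequencies(self):
        bg = compute_background([ProteinRecord("p", "AAAA")])
        assert bg.freq["A"] == pytest.approx(5 / 24)
        assert bg.freq["W"] == pytest.approx(1 / 24)

    def test_uniform_proteome_is_uniform_within_smoothing(self):
        seq = AMINO_ACIDS * 50
        bg = compute_background([ProteinRecord("p", seq)])
        for aa in AMINO_ACIDS:
            assert bg.freq[aa] == pytest.approx(0.05, abs=1e-3)

    def test_empty_input_raises(self):
        with pytest.raises(PWMError):
            compute_background([])

    def test_zero_probability_rejected(self):
        freq = {aa: 0.05 for aa in AMINO_ACIDS}
        freq["W"] = 0.0
        freq["A"] = 0.10
        with pytest.raises(PWMError):
            BackgroundDistribution(freq)


class TestComputePwm:
    def test_matches_brute_force_oracle(self):
        strings = ["DEVDGAAA", "DEVDSTTT", "QEVDGHKL", "AAVDGQQQ"]
        wins = [CleavageWindow(s, 10) for s in strings]
        bg = BackgroundDistribution.uniform()
        pwm = compute_pwm(wins, bg, pseudocount=1.0)
        expected = brute_force_pwm(strings, bg, 1.0)
        assert np.allclose(pwm.log2_ratio, expected, atol=1e-12)

    def test_background_composition_gives_zero_log_ratio(self):
        # one window per residue at every position -> column == uniform bg
        wins = [CleavageWindow(aa * 8, 10) for aa in AMINO_ACIDS]
        pwm = compute_pwm(wins, BackgroundDistribution.uniform(), pseudocount=1.0)
        assert np.allclose(pwm.log2_ratio, 0.0, atol=1e-12)

    def test_absent_residue_more_negative_as_pseudocount_shrinks(self):
        wins = [CleavageWindow("DEVDGAAA", 10)] * 1  # W absent everywhere
        bg = BackgroundDistribution.uniform()
        big = compute_pwm(wins, bg, pseudocount=1.0).value("W", 0)
        small = compute_pwm(wins, bg, pseudocount=0.01).value("W", 0)
        assert small < big < 0

    def test_pads_excluded_from_counts(self):
        wins = [
            CleavageWindow("XXXXDAGK", 1, padded_left=4),
            CleavageWindow("MKVLDAGK", 9),
        ]
        pwm = compute_pwm(wins, BackgroundDistribution.uniform(), pseudocount=1.0)
        # position 0 saw only 'M' (1 observation), not 'X'
        expected = math.log2((1 + 0.05) / ((1 + 1) * 0.05))
        assert pwm.value("M", 0) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(strings=windows_strategy, pc=st.floats(0.1, 5.0))
    def test_mass_conservation_holds_for_every_matrix(self, strings, pc):
        """sum_i b(i) * 2**log2_ratio(i, j) == 1 at every position."""
        wins = [CleavageWindow(s, 10) for s in strings]
        bg = BackgroundDistribution.uniform()
        pwm = compute_pwm(wins, bg, pseudocount=pc)
        assert pwm.mass_conservation_error() < 1e-6

    @settings(max_examples=40, derandomize=True)
    @given(strings=windows_strategy)
    def test_pseudocount_shrinks_toward_zero(self, strings):
        """Smaller pseudocount -> weakly larger absolute entries."""
        wins = [CleavageWindow(s, 10) for s in strings]
        bg = BackgroundDistribution.uniform()
        sharp = compute_pwm(wins, bg, pseudocount=0.5).log2_ratio
        shrunk = compute_pwm(wins, bg, pseudocount=2.0).log2_ratio
        assert np.all(np.abs(sharp) >= np.abs(shrunk) - 1e-12)

    def test_serialization_round_trips_bit_exactly(self, tmp_path):
        wins = [CleavageWindow("DEVDGAAA", 10), CleavageWindow("QEVDSTKL", 12)]
        bg = BackgroundDistribution.uniform()
        pwm = compute_pwm(wins, bg, pseudocount=1.0)
        p = tmp_path / "pwm.tsv"
        pwm.to_tsv(p)
        back = PositionWeightMatrix.read_tsv(p)
        assert np.array_equal(back.log2_ratio, pwm.log2_ratio)
        assert back.background.freq == dict(pwm.background.freq)
        assert back.pseudocount == pwm.pseudocount
        assert back.n_sequences == pwm.n_sequences


class TestEncodeWindow:
    @pytest.fixture()
    def toy_pwm(self):
        wins = [CleavageWindow("DEVDGAAA", 10), CleavageWindow("DQVDSTKL", 12)]
        return compute_pwm(wins, BackgroundDistribution.uniform(), 1.0)

    def test_values_match_direct_matrix_lookup(self, toy_pwm):
        w = CleavageWindow("DQVDSTKL", 12)
        fv = encode_window(w, toy_pwm)
        for j, res in enumerate(w.residues):
            assert fv.pwm_values[j] == toy_pwm.value(res, j)

    def test_padded_positions_are_zero_with_default_labels(self, toy_pwm):
        w = CleavageWindow("DEVDGXXX", 6, padded_right=3)
        fv = encode_window(w, toy_pwm, ss="HHHHH___", disorder="*****...")
        assert np.all(fv.pwm_values[5:] == 0.0)
        assert fv.ss_labels[5:] == ("_", "_", "_")
        assert fv.disorder_labels[5:] == (".", ".", ".")

    def test_deterministic(self, toy_pwm):
        w = CleavageWindow("DEVDGAAA", 10)
        a = encode_window(w, toy_pwm, "HHEE____", "....****")
        b = encode_window(w, toy_pwm, "HHEE____", "....****")
        assert np.array_equal(a.pwm_values, b.pwm_values)
        assert a.ss_labels == b.ss_labels

    def test_unknown_residue_scores_zero_with_warning(self, toy_pwm, caplog):
        w = CleavageWindow("DEVDGXAA", 10)  # X at an unpadded position
        with caplog.at_level("WARNING"):
            fv = encode_window(w, toy_pwm)
        assert fv.pwm_values[5] == 0.0
        assert any("unknown residue" in r.message for r in caplog.records)

    def test_numeric_expansion_shape_and_one_hot(self, toy_pwm):
        w = CleavageWindow("DEVDGAAA", 10)
        fv = encode_window(w, toy_pwm, "HE______", "*.......")
        x = feature_vector_to_numeric(fv)
        assert x.shape == (40,)
        ss_block = x[8:32].reshape(8, 3)
        assert np.all(ss_block.sum(axis=1) == 1.0)  # exactly one state per position
        assert x[32] == 1.0 and np.all(x[33:] == 0.0)


def test_structure_context_slices_and_pads():
    ss = "HHHEEE___"
    dis = "...***..."
    # p1 = 2: window spans positions -2..5 -> 3 left pads
    s, d = structure_context(ss, dis, 2)
    assert s == "___HHHEE"
    assert d == "...." + "..**"[:4]


def test_positive_windows_outscore_background(small_model, ratio_records):
    """Summed PWM values separate planted from background windows (n=500)."""
    import numpy as np

    from caspcleave.seqio import extract_window
    from caspcleave.synth import SynthConfig, generate, sample_background_sites

    cfg = SynthConfig(n_proteins=120, length_range=(250, 400), n_sites=500, seed=17)
    recs, anns = generate(cfg)
    by_id = {r.id: r for r in recs}
    pos = [extract_window(by_id[a.protein_id], a.p1_position) for a in anns]
    decoys = sample_background_sites(recs, anns, 500, seed=18)
    neg = [extract_window(by_id[d.protein_id], d.p1_position) for d in decoys]
    pwm = small_model.pwm
    s_pos = [encode_window(w, pwm).pwm_values.sum() for w in pos]
    s_neg = [encode_window(w, pwm).pwm_values.sum() for w in neg]
    from scipy.stats import mannwhitneyu

    stat = mannwhitneyu(s_pos, s_neg, alternative="greater")
    assert stat.pvalue < 0.01
    assert np.mean(s_pos) > np.mean(s_neg)
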