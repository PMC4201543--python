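"""Independent brute-force oracles shared by the test suite."""

import math

import numpy as np

from caspcleave.seqio import AMINO_ACIDS


def brute_force_pwm_strings(window_strings, background, pseudocount):
    """Count-and-divide PWM oracle over raw 8-mer strings ('X' excluded)."""
    out = np.zeros((20, 8))
    for j in range(8):
        column = [w[j] for w in window_strings if w[j] != "X"]
        n = len(column)
        for i, aa in enumerate(AMINO_ACIDS):
            b = background.freq[aa]
            ratio = (column.count(aa) + pseudocount * b) / ((n + pseudocount) * b)
            out[i, j] = math.log2(ratio)
    return out
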