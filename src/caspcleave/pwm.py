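"""Position weight matrix and feature encoding.

The PWM is the per-position log2 ratio of motif frequency to background
frequency.  Aligned on the scissile bond, the positive windows give counts
``count(i, j)`` of amino acid *i* at position *j* (P5..P3'); with a
background distribution ``b(i)`` and a background-proportional pseudocount
of total weight ``c`` the stored value is::

    log2_ratio(i, j) = log2( (count(i, j) + c * b(i)) / ((n_j + c) * b(i)) )

where ``n_j`` is the number of unpadded residues observed at position *j*.
The background-proportional pseudocount keeps every entry finite while
preserving exact probability-mass conservation: for every position,
``sum_i b(i) * 2**log2_ratio(i, j) == 1``.

A candidate window is encoded as 8 numeric features (the matrix entry of the
observed residue at each position, 0 at pads) plus per-position secondary
structure (H/E/_) and disorder (./*) labels; the categorical labels are
one-hot expanded for classifiers that require numeric input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    AA_INDEX,
    AMINO_ACIDS,
    PAD,
    WINDOW_POSITIONS,
    WINDOW_SIZE,
    CleavageWindow,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

SS_STATES = ("H", "E", "_")
DISORDER_STATES = (".", "*")


class PWMError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundDistribution:
    """Amino-acid composition of the background sequence set (the b(i) term)."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.freq)
        if missing:
            raise PWMError(f"background missing residues {sorted(missing)}")
        vals = np.array([self.freq[aa] for aa in AMINO_ACIDS])
        if not np.all(vals > 0):
            raise PWMError("background probabilities must be strictly positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise PWMError(f"background must sum to 1 (got {vals.sum():.12f})")

    def as_array(self) -> np.ndarray:
        return np.array([self.freq[aa] for aa in AMINO_ACIDS])

    @classmethod
    def uniform(cls) -> "BackgroundDistribution":
        return cls({aa: 1.0 / 20.0 for aa in AMINO_ACIDS})

    @classmethod
    def from_mapping(cls, freq: Mapping[str, float]) -> "BackgroundDistribution":
        total = sum(freq[aa] for aa in AMINO_ACIDS)
        return cls({aa: freq[aa] / total for aa in AMINO_ACIDS})


def compute_background(records: Sequence[ProteinRecord]) -> BackgroundDistribution:
    """Amino-acid frequencies over all residues of the supplied proteins.

    'X' (unknown) residues are excluded; a Laplace +1 count per amino acid
    guarantees strictly positive frequencies.
    """
    if not records:
        raise PWMError("cannot compute a background from an empty record list")
    counts = {aa: 1 for aa in AMINO_ACIDS}
    n_standard = 0
    for rec in records:
        for c in rec.sequence:
            if c in counts:
                counts[c] += 1
                n_standard += 1
    if n_standard == 0:
        raise PWMError("records contain no standard residues")
    total = n_standard + 20
    return BackgroundDistribution({aa: counts[aa] / total for aa in AMINO_ACIDS})


@dataclass(frozen=True)
class PositionWeightMatrix:
    """20 x 8 matrix of log2(observed/background) values over P5..P3'."""

    log2_ratio: np.ndarray  # shape (20, 8), row order AMINO_ACIDS
    background: BackgroundDistribution
    pseudocount: float
    n_sequences: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.log2_ratio, dtype=float)
        if arr.shape != (20, WINDOW_SIZE):
            raise PWMError(f"PWM must be 20x{WINDOW_SIZE}, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise PWMError("PWM entries must be finite")
        object.__setattr__(self, "log2_ratio", arr)

    def value(self, residue: str, position: int) -> float:
        """Matrix entry for ``residue`` at window position index ``position``."""
        return float(self.log2_ratio[AA_INDEX[residue], position])

    def mass_conservation_error(self) -> float:
        """Max over positions of |sum_i b(i) * 2**log2_ratio(i,j) - 1|."""
        b = self.background.as_array()[:, None]
        mass = (b * np.exp2(self.log2_ratio)).sum(axis=0)
        return float(np.max(np.abs(mass - 1.0)))

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a tab-delimited 20x8 table plus a metadata block.

        Floats are written with repr precision so the file round-trips
        bit-exactly through :meth:`read_tsv`.
        """
        with open(path, "w") as fh:
            fh.write(f"#pseudocount\t{self.pseudocount!r}\n")
            fh.write(f"#n_sequences\t{self.n_sequences}\n")
            bg = "\t".join(f"{aa}={self.background.freq[aa]!r}" for aa in AMINO_ACIDS)
            fh.write(f"#background\t{bg}\n")
            fh.write("aa\t" + "\t".join(WINDOW_POSITIONS) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                row = "\t".join(repr(float(v)) for v in self.log2_ratio[i])
                fh.write(f"{aa}\t{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PositionWeightMatrix":
        pseudocount = None
        n_sequences = None
        background = None
        rows: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#pseudocount"):
                    pseudocount = float(line.split("\t")[1])
                elif line.startswith("#n_sequences"):
                    n_sequences = int(line.split("\t")[1])
                elif line.startswith("#background"):
                    pairs = line.split("\t")[1:]
                    background = BackgroundDistribution(
                        {p.split("=")[0]: float(p.split("=")[1]) for p in pairs}
                    )
                elif not line or line.startswith("aa\t") or line.startswith("#"):
                    continue
                else:
                    parts = line.split("\t")
                    rows[parts[0]] = [float(v) for v in parts[1:]]
        if pseudocount is None or n_sequences is None or background is None or len(rows) != 20:
            raise PWMError(f"{path}: incomplete PWM file")
        arr = np.array([rows[aa] for aa in AMINO_ACIDS])
        return cls(arr, background, pseudocount, n_sequences)


def compute_pwm(
    positives: Sequence[CleavageWindow],
    background: BackgroundDistribution,
    pseudocount: float = 1.0,
) -> PositionWeightMatrix:
    """Build the background-normalized log2 PWM from aligned positive windows.

    Pad symbols ('X') are excluded from the per-position counts; the
    pseudocount is distributed proportionally to the background so the
    probability-mass-conservation invariant holds exactly.
    """
    if not positives:
        raise PWMError("need at least one positive window")
    if pseudocount <= 0:
        raise PWMError("pseudocount must be positive")
    counts = np.zeros((20, WINDOW_SIZE))
    for w in positives:
        for j, res in enumerate(w.residues):
            if res != PAD:
                counts[AA_INDEX[res], j] += 1
    n_j = counts.sum(axis=0)  # unpadded observations per position
    if np.any(n_j == 0):
        raise PWMError("a window position has no unpadded observations")
    b = background.as_array()[:, None]
    ratio = (counts + pseudocount * b) / ((n_j[None, :] + pseudocount) * b)
    return PositionWeightMatrix(
        log2_ratio=np.log2(ratio),
        background=background,
        pseudocount=pseudocount,
        n_sequences=len(positives),
    )


@dataclass(frozen=True)
class FeatureVector:
    """Per-window classifier input: 8 PWM values + 8 ss + 8 disorder labels."""

    pwm_values: np.ndarray
    ss_labels: tuple[str, ...]
    disorder_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.pwm_values, dtype=float)
        if arr.shape != (WINDOW_SIZE,):
            raise PWMError(f"pwm_values must have shape ({WINDOW_SIZE},)")
        if not np.all(np.isfinite(arr)):
            raise PWMError("pwm_values must be finite")
        if len(self.ss_labels) != WINDOW_SIZE or len(self.disorder_labels) != WINDOW_SIZE:
            raise PWMError("structure labels must cover all 8 window positions")
        for s in self.ss_labels:
            if s not in SS_STATES:
                raise PWMError(f"bad secondary-structure label {s!r}")
        for d in self.disorder_labels:
            if d not in DISORDER_STATES:
                raise PWMError(f"bad disorder label {d!r}")
        object.__setattr__(self, "pwm_values", arr)


def encode_window(
    window: CleavageWindow,
    pwm: PositionWeightMatrix,
    ss: str | Sequence[str] = "_" * WINDOW_SIZE,
    disorder: str | Sequence[str] = "." * WINDOW_SIZE,
) -> FeatureVector:
    """Encode one window against a PWM with its structural context.

    Pad positions carry PWM value 0, ss '_' and disorder '.'; an 'X' at an
    unpadded position also scores 0, with a warning (unknown residue).
    """
    if len(ss) != WINDOW_SIZE or len(disorder) != WINDOW_SIZE:
        raise PWMError("ss/disorder context must have length 8")
    values = np.zeros(WINDOW_SIZE)
    ss_out = []
    dis_out = []
    for j, res in enumerate(window.residues):
        left_pad = j < window.padded_left
        right_pad = j >= WINDOW_SIZE - window.padded_right
        if left_pad or right_pad:
            ss_out.append("_")
            dis_out.append(".")
            continue
        if res == PAD:
            logger.warning(
                "window %s: unknown residue at %s scored 0", window.residues, WINDOW_POSITIONS[j]
            )
        else:
            values[j] = pwm.value(res, j)
        ss_out.append(ss[j])
        dis_out.append(disorder[j])
    return FeatureVector(values, tuple(ss_out), tuple(dis_out))


# --- numeric expansion for sklearn-style classifiers ----------------------

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"pwm_{p}" for p in WINDOW_POSITIONS]
    + [f"ss_{p}_{s}" for p in WINDOW_POSITIONS for s in SS_STATES]
    + [f"disorder_{p}" for p in WINDOW_POSITIONS]
)


def feature_vector_to_numeric(fv: FeatureVector) -> np.ndarray:
    """One-hot expand the categorical labels: 8 + 8*3 + 8 = 40 numerics."""
    ss_onehot = np.zeros((WINDOW_SIZE, len(SS_STATES)))
    for j, s in enumerate(fv.ss_labels):
        ss_onehot[j, SS_STATES.index(s)] = 1.0
    dis = np.array([1.0 if d == "*" else 0.0 for d in fv.disorder_labels])
    return np.concatenate([fv.pwm_values, ss_onehot.ravel(), dis])


def structure_context(
    ann_ss: str, ann_disorder: str, p1_position: int
) -> tuple[str, str]:
    """Slice full-protein structure strings to the window's P5..P3' span.

    Positions outside the protein get the defaults '_' and '.'.
    """
    n = len(ann_ss)
    ss_out, dis_out = [], []
    for pos in range(p1_position - 4, p1_position + 4):
        if 1 <= pos <= n:
            ss_out.append(ann_ss[pos - 1])
            dis_out.append(ann_disorder[pos - 1])
        else:
            ss_out.append("_")
            dis_out.append(".")
    return "".join(ss_out), "".join(dis_out)
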