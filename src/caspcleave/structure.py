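"""Per-residue secondary-structure and disorder labels.

Cleavage accessibility correlates with local structure: caspase sites sit
preferentially in loops and disordered segments rather than buried regular
structure, so the classifier consumes per-residue secondary-structure
(helix 'H', sheet 'E', loop '_') and disorder (ordered '.', disordered '*')
labels alongside the PWM values.

Two sources are supported behind one interface: a bundled deterministic
baseline predictor (single-sequence propensity scales, below), and a file
adapter for labels computed by any external predictor.  The baseline is a
self-contained propensity method, not a neural-network-grade predictor —
swapping in externally computed labels changes feature values but never
feature-vector shape.

Baseline method: Chou-Fasman helix/sheet propensities averaged over a
7-residue window, argmax against a loop threshold (ties -> loop); disorder
by a FoldIndex-style balance of mean Kyte-Doolittle hydrophobicity against
mean absolute net charge over a 9-residue window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .pwm import DISORDER_STATES, SS_STATES
from .seqio import ProteinRecord, _open_text

# Chou-Fasman conformational propensities (helix Pa, sheet Pb).
HELIX_PROPENSITY = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
    "X": 1.00,
}
SHEET_PROPENSITY = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
    "X": 1.00,
}
# Kyte-Doolittle hydropathy, rescaled to [0, 1] for the disorder index.
KD_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    "X": 0.0,
}
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

SS_WINDOW = 7
DISORDER_WINDOW = 9
#: minimum mean propensity for a non-loop call
PROPENSITY_THRESHOLD = 1.03


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class StructuralAnnotation:
    """Full-length secondary-structure and disorder strings for one protein."""

    protein_id: str
    ss: str
    disorder: str

    def __post_init__(self) -> None:
        if len(self.ss) != len(self.disorder):
            raise StructureError(
                f"{self.protein_id}: ss and disorder strings differ in length"
            )
        bad_ss = set(self.ss) - set(SS_STATES)
        if bad_ss:
            raise StructureError(
                f"{self.protein_id}: secondary-structure labels must be H/E/_, got {sorted(bad_ss)}"
            )
        bad_dis = set(self.disorder) - set(DISORDER_STATES)
        if bad_dis:
            raise StructureError(
                f"{self.protein_id}: disorder labels must be . or *, got {sorted(bad_dis)}"
            )


def _smoothed(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the termini."""
    n = len(values)
    half = width // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def predict_structure_baseline(record: ProteinRecord) -> StructuralAnnotation:
    """Deterministic propensity-scale structure and disorder prediction.

    Structure is predicted on the full protein and later sliced per window,
    so every window sees its real sequence context.
    """
    seq = record.sequence
    helix = _smoothed(np.array([HELIX_PROPENSITY[c] for c in seq]), SS_WINDOW)
    sheet = _smoothed(np.array([SHEET_PROPENSITY[c] for c in seq]), SS_WINDOW)
    ss = []
    for h, e in zip(helix, sheet):
        if h > e and h >= PROPENSITY_THRESHOLD:
            ss.append("H")
        elif e > h and e >= PROPENSITY_THRESHOLD:
            ss.append("E")
        else:
            ss.append("_")  # ties and low propensity default to loop

    # FoldIndex-style: I = 2.785 * <H01> - |<q>| - 1.151; I < 0 -> disordered
    hyd01 = np.array([(KD_HYDROPATHY[c] + 4.5) / 9.0 for c in seq])
    charge = np.array([CHARGE.get(c, 0.0) for c in seq])
    mean_h = _smoothed(hyd01, DISORDER_WINDOW)
    mean_q = _smoothed(charge, DISORDER_WINDOW)
    fold_index = 2.785 * mean_h - np.abs(mean_q) - 1.151
    disorder = "".join("*" if fi < 0 else "." for fi in fold_index)
    return StructuralAnnotation(record.id, "".join(ss), disorder)


def predict_structures(
    records: Sequence[ProteinRecord],
) -> dict[str, StructuralAnnotation]:
    return {r.id: predict_structure_baseline(r) for r in records}


def load_structure_file(
    path: str | Path, records: Sequence[ProteinRecord] | None = None
) -> list[StructuralAnnotation]:
    """Read externally computed labels: three lines per protein (id, ss, disorder).

    Blank lines and '#' comments are ignored; gzip input is accepted.  When a
    FASTA record set is supplied, string lengths are validated against it.
    """
    by_id = {r.id: r for r in records} if records is not None else None
    lines: list[str] = []
    with _open_text(path) as fh:
        for raw in fh:
            s = raw.strip()
            if s and not s.startswith("#"):
                lines.append(s)
    if len(lines) % 3 != 0:
        raise StructureError(f"{path}: expected id/ss/disorder line triplets")
    anns: list[StructuralAnnotation] = []
    for i in range(0, len(lines), 3):
        ann = StructuralAnnotation(lines[i], lines[i + 1], lines[i + 2])
        if by_id is not None:
            rec = by_id.get(ann.protein_id)
            if rec is None:
                raise StructureError(f"{path}: unknown protein {ann.protein_id!r}")
            if len(ann.ss) != len(rec):
                raise StructureError(
                    f"{path}: {ann.protein_id} labels length {len(ann.ss)} != "
                    f"sequence length {len(rec)}"
                )
        anns.append(ann)
    return anns


def write_structure_file(
    anns: Sequence[StructuralAnnotation], path: str | Path
) -> None:
    with _open_text(path, "wt") as fh:
        for a in anns:
            fh.write(f"{a.protein_id}\n{a.ss}\n{a.disorder}\n")
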