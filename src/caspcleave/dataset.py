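"""Training-set construction.

Positives are the P5..P3' windows of experimentally annotated cleavage
sites.  Negatives come from a sliding-window scheme: the two residues
upstream (P3, P2) and the two downstream (P1', P2') of each verified
scissile bond are tentatively treated as P1 positions, giving up to four
near-site non-cleavage windows per positive and an overall 1:4 class ratio.
All window strings within a training set are unique, and a negative
candidate identical to a positive window is discarded (the verified label
wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    AnnotationError,
    CleavageAnnotation,
    CleavageWindow,
    ProteinRecord,
    extract_window,
)

logger = logging.getLogger(__name__)

#: Pseudo-P1 offsets used to build near-site negatives.
NEGATIVE_OFFSETS = (-2, -1, 1, 2)

#: provenance record: (protein_id, annotated P1, offset of the pseudo-P1).
Provenance = tuple[str, int, int]


class DatasetError(ValueError):
    pass


@dataclass
class TrainingSet:
    """Positive and negative cleavage windows with their provenance.

    ``provenance`` maps each window's 8-mer string to the protein, the
    annotated P1 it derives from, and the pseudo-P1 offset (0 for positives,
    one of ±1/±2 for negatives).
    """

    positives: list[CleavageWindow]
    negatives: list[CleavageWindow]
    provenance: dict[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = {w.residues for w in self.positives}
        neg = {w.residues for w in self.negatives}
        if len(pos) != len(self.positives) or len(neg) != len(self.negatives):
            raise DatasetError("duplicate window strings within a class")
        if pos & neg:
            raise DatasetError(f"windows labelled both classes: {sorted(pos & neg)[:3]}")

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)

    def windows(self) -> list[CleavageWindow]:
        return self.positives + self.negatives

    def labels(self) -> np.ndarray:
        """1 for positives, 0 for negatives, aligned with :meth:`windows`."""
        return np.concatenate(
            [np.ones(self.n_positive, dtype=int), np.zeros(self.n_negative, dtype=int)]
        )

    def to_tsv(self, path: str | Path) -> None:
        """Two-column (window, label) TSV plus provenance columns."""
        with open(path, "w") as fh:
            fh.write("#window\tlabel\tprotein_id\tsource_p1\toffset\n")
            for w, lab in ((w, "positive") for w in self.positives):
                pid, p1, off = self.provenance[w.residues]
                fh.write(f"{w.residues}\t{lab}\t{pid}\t{p1}\t{off}\n")
            for w in self.negatives:
                pid, p1, off = self.provenance[w.residues]
                fh.write(f"{w.residues}\tnegative\t{pid}\t{p1}\t{off}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrainingSet":
        positives: list[CleavageWindow] = []
        negatives: list[CleavageWindow] = []
        prov: dict[str, Provenance] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                win, lab, pid, p1, off = line.split("\t")
                p1, off = int(p1), int(off)
                w = CleavageWindow(
                    residues=win,
                    p1_position=p1 + off,
                    padded_left=0,
                    padded_right=0,
                )
                (positives if lab == "positive" else negatives).append(w)
                prov[win] = (pid, p1, off)
        return cls(positives, negatives, prov)


def _index_records(records: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {r.id: r for r in records}


def build_positive_set(
    records: Sequence[ProteinRecord],
    annotations: Sequence[CleavageAnnotation],
    provenance: dict[str, Provenance] | None = None,
) -> list[CleavageWindow]:
    """One window per annotation, deduplicated on the 8-mer string."""
    by_id = _index_records(records)
    seen: dict[str, CleavageWindow] = {}
    dropped = 0
    for ann in annotations:
        rec = by_id.get(ann.protein_id)
        if rec is None:
            raise DatasetError(f"annotation references unknown protein {ann.protein_id!r}")
        win = extract_window(rec, ann.p1_position)
        if win.residues in seen:
            dropped += 1
            continue
        seen[win.residues] = win
        if provenance is not None:
            provenance[win.residues] = (ann.protein_id, ann.p1_position, 0)
    if dropped:
        logger.info("positive set: dropped %d duplicate windows", dropped)
    return list(seen.values())


def build_negative_set(
    records: Sequence[ProteinRecord],
    annotations: Sequence[CleavageAnnotation],
    positives: Sequence[CleavageWindow],
    provenance: dict[str, Provenance] | None = None,
) -> list[CleavageWindow]:
    """Sliding-window negatives at pseudo-P1 offsets -2, -1, +1, +2.

    Candidates duplicating another negative, or identical to a positive
    window, are removed (positives take precedence).  Candidates at protein
    termini are built with padding rather than dropped.
    """
    by_id = _index_records(records)
    positive_strings = {w.residues for w in positives}
    seen: dict[str, CleavageWindow] = {}
    dup = clash = 0
    for ann in annotations:
        rec = by_id.get(ann.protein_id)
        if rec is None:
            raise DatasetError(f"annotation references unknown protein {ann.protein_id!r}")
        for off in NEGATIVE_OFFSETS:
            win = extract_window(rec, ann.p1_position + off, allow_out_of_range=True)
            if win.residues in positive_strings:
                clash += 1
                continue
            if win.residues in seen:
                dup += 1
                continue
            seen[win.residues] = win
            if provenance is not None:
                provenance[win.residues] = (ann.protein_id, ann.p1_position, off)
    if dup or clash:
        logger.info(
            "negative set: removed %d duplicates and %d positive-window clashes", dup, clash
        )
    return list(seen.values())


def build_training_set(
    records: Sequence[ProteinRecord], annotations: Sequence[CleavageAnnotation]
) -> TrainingSet:
    """Full positive + sliding-window-negative training set with provenance."""
    prov: dict[str, Provenance] = {}
    positives = build_positive_set(records, annotations, prov)
    negatives = build_negative_set(records, annotations, positives, prov)
    return TrainingSet(positives, negatives, prov)


def split_train_test(
    ts: TrainingSet, test_fraction: float, seed: int
) -> tuple[TrainingSet, TrainingSet]:
    """Stratified random split preserving the class ratio in both halves.

    Deterministic for a fixed seed.  Refuses sets with fewer than 10 windows
    in either class, where a stratified fraction stops being meaningful.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DatasetError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if ts.n_positive < 10 or ts.n_negative < 10:
        raise DatasetError(
            f"refusing to split tiny classes ({ts.n_positive}+, {ts.n_negative}-): "
            "need at least 10 windows per class"
        )
    rng = np.random.default_rng(seed)

    def _split(wins: list[CleavageWindow]):
        idx = rng.permutation(len(wins))
        n_test = int(round(len(wins) * test_fraction))
        test_idx = set(idx[:n_test].tolist())
        train = [w for i, w in enumerate(wins) if i not in test_idx]
        test = [w for i, w in enumerate(wins) if i in test_idx]
        return train, test

    pos_tr, pos_te = _split(ts.positives)
    neg_tr, neg_te = _split(ts.negatives)

    def _sub(pos, neg):
        keys = {w.residues for w in pos} | {w.residues for w in neg}
        return TrainingSet(pos, neg, {k: v for k, v in ts.provenance.items() if k in keys})

    return _sub(pos_tr, neg_tr), _sub(pos_te, neg_te)
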