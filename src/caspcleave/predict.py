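"""Applying a trained model: proteome scanning, motif search, variant
re-scoring and ortholog conservation mapping.

Scanning scores every D (optionally also E) residue of a protein as a
putative P1 and reports the cleavage probability, the P5-P5' display window
with '-' at the scissile bond, and the yes/no call at the 0.5 threshold,
sorted by descending score.  Variant re-scoring recomputes the probability
after an amino-acid substitution inside the P5..P3' window (e.g. the
ATG16L1 T300A polymorphism next to the D299 site).  Conservation mapping
transfers annotated sites through a global pairwise alignment to an
ortholog and asks whether the acidic P1 and its context are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import SCORE_THRESHOLD, CleavageResults
from .pwm import structure_context
from .seqio import (
    PAD,
    CleavageWindow,
    ProteinRecord,
    display_window,
    extract_window,
)
from .structure import StructuralAnnotation, predict_structure_baseline

logger = logging.getLogger(__name__)

#: residues accepted at P1 when scanning (D by default; E optional)
DEFAULT_P1_RESIDUES = frozenset("D")
ALLOWED_P1_RESIDUES = frozenset("DE")

#: conservation accepts E at the aligned P1 as well as D, since E can
#: sporadically replace the canonical aspartate
CONSERVED_P1_RESIDUES = frozenset("DE")


class PredictError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionResult:
    """One scored candidate scissile bond."""

    protein_id: str
    p1_position: int
    window: str  # P5-P5' display string, '-' at the bond
    score: float
    predicted_class: str  # "yes" | "no"
    ss_context: str  # 8 labels over P5..P3'
    disorder_context: str


def _sort_results(results: list[PredictionResult]) -> list[PredictionResult]:
    return sorted(results, key=lambda r: (-r.score, r.p1_position))


def _resolve_structure(
    record: ProteinRecord, structure: Optional[StructuralAnnotation]
) -> StructuralAnnotation:
    if structure is None:
        return predict_structure_baseline(record)
    if len(structure.ss) != len(record):
        raise PredictError(
            f"{record.id}: structure length {len(structure.ss)} != "
            f"sequence length {len(record)}"
        )
    return structure


def scan_protein(
    results_model: CleavageResults,
    record: ProteinRecord,
    p1_residues: frozenset[str] | set[str] | str = DEFAULT_P1_RESIDUES,
    structure: Optional[StructuralAnnotation] = None,
) -> list[PredictionResult]:
    """Score every position whose residue is an allowed P1 (subset of {D, E}).

    Results are sorted by descending score, ties by ascending position.
    The structural context defaults to the bundled baseline predictor run on
    the full protein.
    """
    p1_set = frozenset(p1_residues)
    if not p1_set or not p1_set <= ALLOWED_P1_RESIDUES:
        raise PredictError(f"p1_residues must be a nonempty subset of {{D, E}}: {p1_set}")
    ann = _resolve_structure(record, structure)
    out: list[PredictionResult] = []
    windows, contexts, positions = [], [], []
    for pos in range(1, len(record) + 1):
        if record.sequence[pos - 1] in p1_set:
            windows.append(extract_window(record, pos))
            contexts.append(structure_context(ann.ss, ann.disorder, pos))
            positions.append(pos)
    if not windows:
        return []
    probs = results_model.score_windows(windows, contexts)
    for pos, (ss, dis), p in zip(positions, contexts, probs):
        out.append(
            PredictionResult(
                protein_id=record.id,
                p1_position=pos,
                window=display_window(record, pos),
                score=float(p),
                predicted_class="yes" if p >= SCORE_THRESHOLD else "no",
                ss_context=ss,
                disorder_context=dis,
            )
        )
    return _sort_results(out)


# ---------------------------------------------------------------------------
# motif search
# ---------------------------------------------------------------------------

#: window position offsets relative to P1 (offset 0); negative = N-terminal
MAX_MOTIF_SPAN = 5  # P5..P5'


@dataclass(frozen=True)
class MotifQuery:
    """Per-position allowed-residue sets, keyed by offset from P1.

    Offset 0 is P1, -1 is P2, ..., +1 is P1', matching the left-to-right
    motif grammar ``...P2 P1 - P1' P2'...``.
    """

    constraints: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.constraints:
            raise PredictError("motif constrains no position")
        if 0 not in self.constraints or not self.constraints[0]:
            raise PredictError("motif P1 set must be nonempty")
        for off in self.constraints:
            if not -MAX_MOTIF_SPAN < off <= MAX_MOTIF_SPAN:
                raise PredictError(f"motif offset {off} outside P5..P5'")


def parse_motif(text: str) -> MotifQuery:
    """Parse a motif such as ``DEVD-A/G/S/T``.

    Residues run left-to-right toward the bond, '-' marks the scissile bond,
    '/' separates alternatives at one position and 'X' is a wildcard
    (unconstrained).  Without a '-', P1 is assumed at the final residue and a
    warning is logged.
    """
    text = text.strip().upper()
    if not text:
        raise PredictError("empty motif")
    if "-" in text:
        if text.count("-") > 1:
            raise PredictError(f"motif {text!r}: more than one scissile-bond marker")
        left, right = text.split("-")
    else:
        logger.warning("motif %r has no '-': assuming P1 at the final residue", text)
        left, right = text, ""

    def _positions(part: str, label: str) -> list[frozenset[str]]:
        # split into single residues or A/B/C alternative groups
        sets: list[frozenset[str]] = []
        i = 0
        while i < len(part):
            group = [part[i]]
            i += 1
            while i + 1 <= len(part) and i < len(part) and part[i] == "/":
                if i + 1 >= len(part):
                    raise PredictError(f"motif {label} side: trailing '/' at position {i + 1}")
                group.append(part[i + 1])
                i += 2
            for c in group:
                if c not in "ACDEFGHIKLMNPQRSTVWYX":
                    raise PredictError(
                        f"motif {label} side: illegal character {c!r} at position {i}"
                    )
            sets.append(frozenset(group))
        return sets

    left_sets = _positions(left, "N-terminal")
    right_sets = _positions(right, "C-terminal")
    if not left_sets:
        raise PredictError(f"motif {text!r}: no residues before the scissile bond")
    if len(left_sets) > MAX_MOTIF_SPAN or len(right_sets) > MAX_MOTIF_SPAN:
        raise PredictError(f"motif {text!r} spans beyond P5..P5'")

    constraints: dict[int, frozenset[str]] = {}
    # rightmost residue on the left side is P1 (offset 0)
    for k, sset in enumerate(left_sets):
        off = -(len(left_sets) - 1 - k)
        if "X" not in sset:
            constraints[off] = sset
    for k, sset in enumerate(right_sets):
        if "X" not in sset:
            constraints[k + 1] = sset
    if 0 not in constraints:
        raise PredictError(f"motif {text!r}: P1 must be constrained (not a wildcard)")
    return MotifQuery(constraints)


def search_motif(
    records: Sequence[ProteinRecord],
    query: MotifQuery,
    results_model: Optional[CleavageResults] = None,
    structures: Optional[dict[str, StructuralAnnotation]] = None,
) -> list[PredictionResult]:
    """All positions matching every constrained set, across all records.

    When a model is supplied each hit carries the same score scanning would
    assign at that position; otherwise scores are reported as NaN with class
    left empty.
    """
    hits: list[PredictionResult] = []
    for rec in records:
        ann = None
        positions = []
        n = len(rec)
        for p1 in range(1, n + 1):
            ok = True
            for off, allowed in query.constraints.items():
                pos = p1 + off
                if not (1 <= pos <= n) or rec.sequence[pos - 1] not in allowed:
                    ok = False
                    break
            if ok:
                positions.append(p1)
        if not positions:
            continue
        if results_model is not None:
            if structures is not None and rec.id in structures:
                ann = structures[rec.id]
            ann = _resolve_structure(rec, ann)
            windows = [extract_window(rec, p) for p in positions]
            contexts = [structure_context(ann.ss, ann.disorder, p) for p in positions]
            probs = results_model.score_windows(windows, contexts)
        else:
            contexts = [("_" * 8, "." * 8)] * len(positions)
            probs = [float("nan")] * len(positions)
        for p1, (ss, dis), prob in zip(positions, contexts, probs):
            hits.append(
                PredictionResult(
                    protein_id=rec.id,
                    p1_position=p1,
                    window=display_window(rec, p1),
                    score=float(prob),
                    predicted_class=(
                        ("yes" if prob >= SCORE_THRESHOLD else "no")
                        if results_model is not None
                        else ""
                    ),
                    ss_context=ss,
                    disorder_context=dis,
                )
            )
    return _sort_results(hits) if results_model is not None else hits


# ---------------------------------------------------------------------------
# variant re-scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """A single amino-acid substitution, e.g. T300A on ATG16L1."""

    protein_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PredictError("variant position must be >= 1")
        for r in (self.ref, self.alt):
            if len(r) != 1 or r not in "ACDEFGHIKLMNPQRSTVWYX":
                raise PredictError(f"bad variant residue {r!r}")


def apply_variant(record: ProteinRecord, variant: VariantSpec) -> ProteinRecord:
    if variant.position > len(record):
        raise PredictError(
            f"{record.id}: variant position {variant.position} outside sequence"
        )
    observed = record.sequence[variant.position - 1]
    if observed != variant.ref:
        raise PredictError(
            f"{record.id}: variant ref {variant.ref} != sequence residue "
            f"{observed} at {variant.position}"
        )
    seq = (
        record.sequence[: variant.position - 1]
        + variant.alt
        + record.sequence[variant.position :]
    )
    return ProteinRecord(record.id, seq, record.name)


def rescore_variant(
    results_model: CleavageResults,
    record: ProteinRecord,
    variant: VariantSpec,
    p1_position: int,
    recompute_structure: bool = True,
    structure: Optional[StructuralAnnotation] = None,
) -> tuple[float, float]:
    """(wild-type score, variant score) at one site, from the same model.

    With ``recompute_structure`` (default) the baseline structure predictor
    is re-run on the mutated sequence, so a substitution can shift the
    structural context as well as the PWM features; with fixed file-derived
    labels only window residues inside P5..P3' can change the score.
    """
    wt_ann = _resolve_structure(record, structure)
    mutated = apply_variant(record, variant)
    if recompute_structure and structure is None:
        mut_ann = predict_structure_baseline(mutated)
    else:
        mut_ann = StructuralAnnotation(mutated.id, wt_ann.ss, wt_ann.disorder)
    wt_window = extract_window(record, p1_position)
    mut_window = extract_window(mutated, p1_position)
    wt_score = results_model.score_window(
        wt_window, *structure_context(wt_ann.ss, wt_ann.disorder, p1_position)
    )
    mut_score = results_model.score_window(
        mut_window, *structure_context(mut_ann.ss, mut_ann.disorder, p1_position)
    )
    return wt_score, mut_score


# ---------------------------------------------------------------------------
# ortholog conservation mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteConservation:
    """Where one annotated site lands in an ortholog after global alignment."""

    p1_position: int
    aligned_position: Optional[int]  # 1-based ortholog position, None if gap
    ortholog_residue: Optional[str]
    conserved: bool  # aligned residue in {D, E} and not a gap
    window_identity: float  # identity fraction over the aligned P5..P3'


def _global_alignment(a: str, b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner.align(a, b)[0]


def align_and_map(
    substrate: ProteinRecord,
    ortholog: ProteinRecord,
    sites: Sequence[int],
) -> list[SiteConservation]:
    """Map annotated cleavage positions onto an ortholog.

    Uses a BLOSUM62 global alignment with affine gaps (open 10, extend 0.5).
    A site is conserved when its P1 aligns to a D or E (no gap); window
    identity is the match fraction over the substrate's P5..P3' columns.
    """
    for s in sites:
        if not 1 <= s <= len(substrate):
            raise PredictError(f"site {s} outside {substrate.id}")
    aln = _global_alignment(substrate.sequence, ortholog.sequence)
    g_sub, g_ort = str(aln[0]), str(aln[1])
    # map substrate position (1-based) -> alignment column, and column ->
    # ortholog position (1-based) or None at gaps
    sub_col = {}
    ort_at_col: list[Optional[int]] = []
    i = j = 0
    for col, (ca, cb) in enumerate(zip(g_sub, g_ort)):
        if ca != "-":
            i += 1
            sub_col[i] = col
        if cb != "-":
            j += 1
            ort_at_col.append(j)
        else:
            ort_at_col.append(None)

    out = []
    for site in sites:
        col = sub_col[site]
        ort_pos = ort_at_col[col]
        ort_res = ortholog.sequence[ort_pos - 1] if ort_pos is not None else None
        conserved = ort_res is not None and ort_res in CONSERVED_P1_RESIDUES
        matches = 0
        total = 0
        for pos in range(site - 4, site + 4):
            if 1 <= pos <= len(substrate):
                total += 1
                c = sub_col[pos]
                if g_ort[c] != "-" and g_sub[c] == g_ort[c]:
                    matches += 1
        out.append(
            SiteConservation(
                p1_position=site,
                aligned_position=ort_pos,
                ortholog_residue=ort_res,
                conserved=conserved,
                window_identity=matches / total if total else 0.0,
            )
        )
    return out
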