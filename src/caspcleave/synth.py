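"""Synthetic proteins with planted caspase-like cleavage sites.

The generator emulates the structure of the curated training data: a few
hundred substrate proteins, each carrying one or two annotated scissile
bonds whose P5..P3' context is drawn from a known position-specific residue
distribution with aspartate fixed at P1, embedded in i.i.d. background
sequence with a human-proteome-like amino-acid composition.  Sliding-window
negatives built from these annotations then give the canonical 1:4 class
ratio.

The ``casp3-like`` preset encodes the executioner-caspase consensus
(DxxD-[AGST]): aspartate-rich P4, glutamate-rich P3, D fixed at P1, and the
small uncharged residues A/G/S/T (plus some N) favoured at P1'.  A single
``effect_size`` dial interpolates each position's distribution linearly in
probability space between the background (0) and the full preset (1); at 0
planted sites are indistinguishable from background except for the fixed
P1 = D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .pwm import BackgroundDistribution, PositionWeightMatrix
from .seqio import (
    AA_INDEX,
    AMINO_ACIDS,
    WINDOW_SIZE,
    CleavageAnnotation,
    ProteinRecord,
)


class SynthError(ValueError):
    pass


#: Swiss-Prot-like human amino-acid composition used as the generation
#: background (rounded to 4 places, renormalized on construction).
HUMAN_AA_FREQS = {
    "A": 0.0702, "C": 0.0230, "D": 0.0473, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0572, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0535, "V": 0.0597, "W": 0.0122, "Y": 0.0267,
}


def human_background() -> BackgroundDistribution:
    return BackgroundDistribution.from_mapping(HUMAN_AA_FREQS)


# Per-position preferred-residue mass for the casp3-like preset; residues
# not listed share the remaining mass in proportion to the background.
# P1 is degenerate: always D.
_CASP3_PREFS: dict[str, dict[str, float]] = {
    "P5": {},
    "P4": {"D": 0.55, "I": 0.05, "L": 0.05, "V": 0.04},
    "P3": {"E": 0.50, "D": 0.08},
    "P2": {"V": 0.15, "P": 0.10, "A": 0.08},
    "P1": {"D": 1.0},
    "P1'": {"A": 0.22, "G": 0.18, "S": 0.16, "T": 0.10, "N": 0.06},
    "P2'": {"G": 0.10, "S": 0.08, "A": 0.08},
    "P3'": {},
}

PRESET_NAMES = ("casp3-like",)
WINDOW_POSITION_NAMES = ("P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'")


def _preset_columns(
    prefs: Mapping[str, Mapping[str, float]], background: BackgroundDistribution
) -> np.ndarray:
    """20 x 8 column-stochastic probability matrix for a preset."""
    b = background.as_array()
    cols = np.empty((20, WINDOW_SIZE))
    for j, pname in enumerate(WINDOW_POSITION_NAMES):
        spec = prefs[pname]
        col = np.zeros(20)
        mass = sum(spec.values())
        if mass > 1.0 + 1e-9:
            raise SynthError(f"preset column {pname}: preferred mass {mass} > 1")
        pref_idx = [AA_INDEX[aa] for aa in spec]
        bg_pref = b[pref_idx].sum() if pref_idx else 0.0
        for aa, p in spec.items():
            col[AA_INDEX[aa]] = p
        rest = 1.0 - mass
        if rest > 0:
            scale = rest / (1.0 - bg_pref)
            for i in range(20):
                if i not in pref_idx:
                    col[i] = b[i] * scale
        cols[:, j] = col / col.sum()
    return cols


@dataclass(frozen=True)
class SynthConfig:
    """Generation settings.

    ``effect_size`` in [0, 1] scales the planted-site distributions toward
    background (0 = background everywhere except the fixed P1 = D).
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (200, 500)
    n_sites: int = 100
    preset: str = "casp3-like"
    effect_size: float = 1.0
    seed: int = 0
    min_site_separation: int = 10

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise SynthError(f"unknown preset {self.preset!r}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise SynthError("effect_size must be in [0, 1]")
        if self.n_proteins < 1 or self.n_sites < 0:
            raise SynthError("need at least one protein and nonnegative site count")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise SynthError("length_range must satisfy 20 <= lo <= hi")


def generator_columns(config: SynthConfig) -> np.ndarray:
    """Effective 20x8 per-position probabilities at the configured effect size.

    Linear interpolation in probability space, renormalized per position;
    the P1 column stays a point mass on D at every effect size.
    """
    bg = human_background()
    preset = _preset_columns(_CASP3_PREFS, bg)
    b = bg.as_array()[:, None]
    e = config.effect_size
    cols = (1.0 - e) * b + e * preset
    cols[:, 4] = 0.0
    cols[AA_INDEX["D"], 4] = 1.0
    return cols / cols.sum(axis=0, keepdims=True)


def generator_pwm(config: SynthConfig) -> PositionWeightMatrix:
    """The true log2(p/background) matrix of the generator.

    Residues with zero generating probability (the non-D rows of the P1
    column) get -inf; this matrix is the ground truth for parameter-recovery
    checks, not a fitted PWM, so the finiteness invariant is relaxed by
    clipping to a large negative value.
    """
    bg = human_background()
    cols = generator_columns(config)
    with np.errstate(divide="ignore"):
        log2 = np.log2(cols / bg.as_array()[:, None])
    return PositionWeightMatrix(
        np.clip(log2, -60.0, None), bg, pseudocount=1e-12, n_sequences=0
    )


def generate(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[CleavageAnnotation]]:
    """Generate proteins with planted cleavage sites; deterministic per seed.

    Background residues are i.i.d. from the human-like composition; at each
    planted site the P5..P3' residues are overwritten with draws from the
    effect-scaled preset columns.  Planted P1 positions are returned as
    positive annotations.
    """
    rng = np.random.default_rng(config.seed)
    bg = human_background().as_array()
    aa = np.array(list(AMINO_ACIDS))
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)

    # capacity check: each site occupies min_site_separation positions of
    # the usable interior [6, L-5]
    sep = max(config.min_site_separation, WINDOW_SIZE)
    capacity = sum(max(0, (L - 10) // sep) for L in lengths)
    if config.n_sites > capacity:
        raise SynthError(
            f"cannot place {config.n_sites} sites in {config.n_proteins} proteins "
            f"(capacity ~{capacity}); increase protein count or length"
        )

    seqs = [rng.choice(aa, size=L, p=bg) for L in lengths]
    # assign sites to proteins weighted by interior length, respecting capacity
    weights = np.array([max(0, L - 10) for L in lengths], dtype=float)
    placed: list[list[int]] = [[] for _ in range(config.n_proteins)]
    cols = generator_columns(config)
    annotations: list[CleavageAnnotation] = []
    for _ in range(config.n_sites):
        for _attempt in range(10_000):
            k = int(rng.choice(config.n_proteins, p=weights / weights.sum()))
            L = int(lengths[k])
            p1 = int(rng.integers(6, L - 4))  # window fully inside [1, L]
            if all(abs(p1 - q) >= sep for q in placed[k]):
                break
        else:  # pragma: no cover - capacity check above makes this unreachable
            raise SynthError("failed to place a site; proteins too crowded")
        placed[k].append(p1)
        for j in range(WINDOW_SIZE):
            res = rng.choice(aa, p=cols[:, j])
            seqs[k][p1 - 5 + j] = res
        annotations.append(CleavageAnnotation(f"SYN{k + 1:04d}", p1, "positive", "planted"))

    records = [
        ProteinRecord(f"SYN{k + 1:04d}", "".join(seqs[k]), f"synthetic protein {k + 1}")
        for k in range(config.n_proteins)
    ]
    annotations.sort(key=lambda a: (a.protein_id, a.p1_position))
    return records, annotations


def sample_background_sites(
    records: Sequence[ProteinRecord],
    annotations: Sequence[CleavageAnnotation],
    n: int,
    seed: int,
    p1_residue: str = "D",
    exclusion: int = 4,
) -> list[CleavageAnnotation]:
    """Sample decoy (negative) annotations at background D residues.

    Positions within ``exclusion`` residues of a planted P1 are excluded, so
    decoy windows share no planted context.  These D-centred decoys are the
    fair null comparison set: at effect size 0 a planted window and a decoy
    window are exchangeable by construction.
    """
    planted: dict[str, set[int]] = {}
    for a in annotations:
        planted.setdefault(a.protein_id, set()).add(a.p1_position)
    pool: list[tuple[str, int]] = []
    for rec in records:
        taken = planted.get(rec.id, set())
        for pos in range(5, len(rec) - 3):  # keep windows fully in-sequence
            if rec.sequence[pos - 1] == p1_residue and all(
                abs(pos - q) > exclusion for q in taken
            ):
                pool.append((rec.id, pos))
    if n > len(pool):
        raise SynthError(f"requested {n} decoys but only {len(pool)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [
        CleavageAnnotation(pool[i][0], pool[i][1], "negative", "decoy")
        for i in sorted(idx.tolist())
    ]


def build_decoy_training_set(
    records: Sequence[ProteinRecord],
    annotations: Sequence[CleavageAnnotation],
    n_decoys: int,
    seed: int,
):
    """Planted positives against D-centred background decoys.

    This is the matched-null construction: every window, positive or
    negative, has D at P1, so at effect size 0 the two classes are
    exchangeable and a classifier's cross-validated AUC tends to 0.5.
    Contrast with the sliding-window negatives of the dataset module, which
    reproduce the published training-set construction.
    """
    from .dataset import TrainingSet, build_positive_set
    from .seqio import extract_window

    prov: dict[str, tuple[str, int, int]] = {}
    positives = build_positive_set(records, annotations, prov)
    by_id = {r.id: r for r in records}
    decoys = sample_background_sites(records, annotations, n_decoys, seed)
    seen = {w.residues for w in positives}
    negatives = []
    for d in decoys:
        w = extract_window(by_id[d.protein_id], d.p1_position)
        if w.residues in seen:
            continue
        seen.add(w.residues)
        negatives.append(w)
        prov[w.residues] = (d.protein_id, d.p1_position, 0)
    return TrainingSet(positives, negatives, prov)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A small generated dataset with its expected bookkeeping counts."""

    name: str
    records: tuple[ProteinRecord, ...]
    annotations: tuple[CleavageAnnotation, ...]
    expected_positives: int
    expected_candidate_negatives: int  # before dedup (4 per positive)


_FIXTURE_CONFIGS: dict[str, SynthConfig] = {
    # 10 proteins, 20 sites: smallest set exercising every module
    "tiny": SynthConfig(n_proteins=10, length_range=(80, 150), n_sites=20, seed=101),
    # keeps the 1:4 ratio visible after dedup at a moderate size
    "ratio": SynthConfig(n_proteins=40, length_range=(200, 400), n_sites=150, seed=202),
}


def training_scale_config(seed: int = 0, effect_size: float = 1.0) -> SynthConfig:
    """The training-set-scale condition: 520 substrate proteins carrying 661
    cleavage sites (so sliding-window negatives approach the 1:4 ratio)."""
    return SynthConfig(
        n_proteins=520,
        length_range=(300, 700),
        n_sites=661,
        effect_size=effect_size,
        seed=seed,
    )


def make_fixture(name: str) -> Fixture:
    """Return a bundled preset dataset; identical across runs."""
    cfg = _FIXTURE_CONFIGS.get(name)
    if cfg is None:
        raise SynthError(f"unknown fixture preset {name!r}; know {sorted(_FIXTURE_CONFIGS)}")
    records, annotations = generate(cfg)
    return Fixture(
        name=name,
        records=tuple(records),
        annotations=tuple(annotations),
        expected_positives=cfg.n_sites,
        expected_candidate_negatives=4 * cfg.n_sites,
    )
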