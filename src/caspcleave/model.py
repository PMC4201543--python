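"""Classifier training, cross-validation and evaluation metrics.

The modelling surface follows the Model/Results convention: a
:class:`CleavageModel` is constructed from a training set (windows, labels,
structural context) and ``fit()`` returns a :class:`CleavageResults` that
carries the fitted classifier together with the PWM and configuration
needed to reproduce its features, so scoring is fully self-contained.

The production classifier is a random forest (1500 trees, unlimited depth);
naive-Bayes, single-decision-tree and RBF-kernel SVM analogs are available
behind the same interface for comparison.  Evaluation reports confusion
counts at the 0.5 probability threshold plus Cohen's kappa, AUC, accuracy,
precision, specificity, MCC and a configurable misclassification cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import __version__
from .dataset import TrainingSet
from .pwm import (
    FEATURE_NAMES,
    BackgroundDistribution,
    PositionWeightMatrix,
    compute_background,
    compute_pwm,
    encode_window,
    feature_vector_to_numeric,
    structure_context,
)
from .seqio import CleavageWindow, ProteinRecord
from .structure import StructuralAnnotation, predict_structures

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("random_forest", "naive_bayes", "decision_tree", "svm")

#: probability threshold for the "yes" cleavage call
SCORE_THRESHOLD = 0.5

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Classifier settings; defaults are the optimized random-forest values
    (1500 trees, unlimited depth) with 10-fold cross-validation."""

    classifier_kind: str = "random_forest"
    n_trees: int = 1500
    max_depth: Optional[int] = None
    seed: int = 0
    folds: int = 10
    cost_fp: float = 1.0
    cost_fn: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise ModelError(f"unknown classifier kind {self.classifier_kind!r}")
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")
        if self.folds < 2:
            raise ModelError("folds must be >= 2")
        if self.cost_fp < 0 or self.cost_fn < 0:
            raise ModelError("costs must be nonnegative")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived metrics.

    Rate metrics (acc/prc/spc) are percentages; kappa and MCC are on [-1, 1].
    A metric whose closed form divides by zero is ``None`` (undefined), never
    silently 0.  ``auc`` is ``None`` when no scores were provided.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    kappa: Optional[float]
    auc: Optional[float]
    acc_percent: Optional[float]
    prc_percent: Optional[float]
    spc_percent: Optional[float]
    mcc: Optional[float]
    cost: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "kappa": self.kappa, "auc": self.auc, "acc_percent": self.acc_percent,
            "prc_percent": self.prc_percent, "spc_percent": self.spc_percent,
            "mcc": self.mcc, "cost": self.cost,
        }

    def summary(self) -> str:
        def f(v, nd=3):
            return "undefined" if v is None else f"{v:.{nd}f}"

        lines = [
            "Cleavage classifier evaluation",
            "------------------------------",
            f"TP {self.tp}   FN {self.fn}   FP {self.fp}   TN {self.tn}",
            f"Accuracy     {f(self.acc_percent, 2)} %",
            f"Precision    {f(self.prc_percent, 2)} %",
            f"Specificity  {f(self.spc_percent, 2)} %",
            f"Kappa        {f(self.kappa)}",
            f"MCC          {f(self.mcc)}",
            f"AUC          {f(self.auc)}",
            f"Cost         {self.cost:.1f}",
        ]
        return "\n".join(lines)


def auc_from_scores(scores: Sequence[tuple[float, int]]) -> Optional[float]:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling."""
    s = np.array([x[0] for x in scores], dtype=float)
    y = np.array([x[1] for x in scores], dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return None
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # midrank, 1-based
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(
    tp: int,
    fn: int,
    fp: int,
    tn: int,
    scores: Optional[Sequence[tuple[float, int]]] = None,
    cost_fp: float = 1.0,
    cost_fn: float = 1.0,
) -> EvaluationReport:
    """Derive every report metric from a 2x2 confusion matrix.

    ACC = (tp+tn)/N x100, PRC = tp/(tp+fp) x100, SPC = tn/(tn+fp) x100;
    kappa and MCC by their standard closed forms; AUC from (score, label)
    pairs when given; cost = cost_fp*fp + cost_fn*fn.
    """
    for v in (tp, fn, fp, tn):
        if v < 0:
            raise ModelError("confusion counts must be nonnegative")
    n = tp + fn + fp + tn
    if n == 0:
        raise ModelError("confusion matrix is all zeros")

    acc = 100.0 * (tp + tn) / n
    prc = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    spc = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None

    # Cohen's kappa: (p_o - p_e) / (1 - p_e)
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else None

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None

    auc = auc_from_scores(scores) if scores is not None else None
    cost = cost_fp * fp + cost_fn * fn
    return EvaluationReport(tp, fn, fp, tn, kappa, auc, acc, prc, spc, mcc, cost)


def confusion_from_scores(
    scores: Sequence[tuple[float, int]], threshold: float = SCORE_THRESHOLD
) -> tuple[int, int, int, int]:
    tp = fn = fp = tn = 0
    for s, y in scores:
        if y == 1:
            if s >= threshold:
                tp += 1
            else:
                fn += 1
        else:
            if s >= threshold:
                fp += 1
            else:
                tn += 1
    return tp, fn, fp, tn


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def _make_estimator(cfg: ModelConfig):
    if cfg.classifier_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            random_state=cfg.seed,
            n_jobs=1,
        )
    if cfg.classifier_kind == "naive_bayes":
        return GaussianNB()
    if cfg.classifier_kind == "decision_tree":
        return DecisionTreeClassifier(max_depth=cfg.max_depth, random_state=cfg.seed)
    # RBF-kernel SVM with the published settings: gamma 0.01, complexity 1,
    # inputs normalized
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", gamma=0.01, C=1.0, probability=True, random_state=cfg.seed),
    )


class CleavageModel:
    """Cleavage-site classifier specification bound to its training data.

    Parameters
    ----------
    training_set
        Positive and sliding-window-negative cleavage windows.
    structures
        Mapping protein id -> :class:`StructuralAnnotation` covering every
        protein referenced by the training set's provenance.
    config
        Classifier settings (default: random forest, 1500 trees).
    background
        Amino-acid background for the PWM; defaults must be supplied via
        :meth:`from_training_data`, which computes it from the substrate
        proteins themselves.
    pwm
        Optional precomputed matrix; computed from the training positives
        otherwise.
    """

    def __init__(
        self,
        training_set: TrainingSet,
        structures: Mapping[str, StructuralAnnotation],
        config: ModelConfig | None = None,
        background: BackgroundDistribution | None = None,
        pwm: PositionWeightMatrix | None = None,
    ):
        if training_set.n_positive == 0 or training_set.n_negative == 0:
            raise ModelError("training set must contain both classes")
        self.training_set = training_set
        self.structures = dict(structures)
        self.config = config or ModelConfig()
        if pwm is not None:
            self.pwm = pwm
        else:
            if background is None:
                raise ModelError("need either a background distribution or a PWM")
            self.pwm = compute_pwm(
                training_set.positives, background, self.config.pseudocount
            )

    @classmethod
    def from_training_data(
        cls,
        records: Sequence[ProteinRecord],
        training_set: TrainingSet,
        config: ModelConfig | None = None,
        structures: Mapping[str, StructuralAnnotation] | None = None,
        background: BackgroundDistribution | None = None,
    ) -> "CleavageModel":
        """Build a model from substrate proteins and a prepared training set.

        The background defaults to the amino-acid composition of the full
        substrate sequences; structures default to the bundled baseline
        predictor run on each protein.
        """
        if background is None:
            background = compute_background(records)
        if structures is None:
            structures = predict_structures(records)
        return cls(training_set, structures, config, background)

    # -- feature assembly --------------------------------------------------

    def _window_context(self, window: CleavageWindow) -> tuple[str, str]:
        pid, src_p1, off = self.training_set.provenance[window.residues]
        ann = self.structures.get(pid)
        if ann is None:
            raise ModelError(f"no structural annotation for protein {pid!r}")
        return structure_context(ann.ss, ann.disorder, src_p1 + off)

    def design_matrix(
        self, pwm: PositionWeightMatrix | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Numeric feature matrix and 0/1 labels for the full training set."""
        pwm = pwm or self.pwm
        rows = []
        for w in self.training_set.windows():
            ss, dis = self._window_context(w)
            rows.append(feature_vector_to_numeric(encode_window(w, pwm, ss, dis)))
        return np.vstack(rows), self.training_set.labels()

    # -- fitting and validation --------------------------------------------

    def fit(self) -> "CleavageResults":
        """Fit the configured classifier; deterministic for a fixed seed."""
        X, y = self.design_matrix()
        est = _make_estimator(self.config)
        est.fit(X, y)
        return CleavageResults(
            model=self,
            estimator=est,
            pwm=self.pwm,
            config=self.config,
            feature_names=FEATURE_NAMES,
            n_positive=self.training_set.n_positive,
            n_negative=self.training_set.n_negative,
        )

    def cross_validate(self) -> EvaluationReport:
        """Stratified k-fold CV; confusion counts pooled over out-of-fold
        predictions at the 0.5 threshold, AUC from pooled scores.

        The PWM is recomputed inside each fold from that fold's training
        positives only, so held-out windows never contribute to the matrix
        they are scored against.
        """
        cfg = self.config
        n_min = min(self.training_set.n_positive, self.training_set.n_negative)
        if cfg.folds > n_min:
            raise ModelError(
                f"folds ({cfg.folds}) exceeds smallest class size ({n_min})"
            )
        windows = self.training_set.windows()
        y = self.training_set.labels()
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        scores = np.empty(len(y))
        dummy = np.zeros((len(y), 1))
        for train_idx, test_idx in skf.split(dummy, y):
            fold_positives = [windows[i] for i in train_idx if y[i] == 1]
            fold_pwm = compute_pwm(
                fold_positives, self.pwm.background, self.config.pseudocount
            )
            X, _ = self.design_matrix(fold_pwm)
            est = _make_estimator(cfg)
            est.fit(X[train_idx], y[train_idx])
            pos_col = list(est.classes_).index(1)
            scores[test_idx] = est.predict_proba(X[test_idx])[:, pos_col]
        paired = list(zip(scores.tolist(), y.tolist()))
        tp, fn, fp, tn = confusion_from_scores(paired)
        return compute_metrics(tp, fn, fp, tn, paired, cfg.cost_fp, cfg.cost_fn)


@dataclass
class CleavageResults:
    """A fitted cleavage classifier plus everything needed to score windows.

    Self-contained: carries the PWM (with its background and pseudocount) and
    the feature layout, so prediction needs only a sequence window and its
    structural context.
    """

    model: Optional[CleavageModel]
    estimator: object
    pwm: PositionWeightMatrix
    config: ModelConfig
    feature_names: tuple[str, ...]
    n_positive: int
    n_negative: int

    def score_window(
        self, window: CleavageWindow, ss: str = "_" * 8, disorder: str = "." * 8
    ) -> float:
        """Positive-class probability for one window in [0, 1]."""
        fv = feature_vector_to_numeric(encode_window(window, self.pwm, ss, disorder))
        pos_col = list(self.estimator.classes_).index(1)
        return float(self.estimator.predict_proba(fv[None, :])[0, pos_col])

    def score_windows(
        self, windows: Sequence[CleavageWindow], contexts: Sequence[tuple[str, str]]
    ) -> np.ndarray:
        rows = [
            feature_vector_to_numeric(encode_window(w, self.pwm, ss, dis))
            for w, (ss, dis) in zip(windows, contexts)
        ]
        pos_col = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(np.vstack(rows))[:, pos_col]

    def evaluate(
        self,
        test_set: TrainingSet,
        structures: Mapping[str, StructuralAnnotation],
    ) -> EvaluationReport:
        """Score a held-out set and report all metrics at the 0.5 threshold."""
        windows = test_set.windows()
        contexts = []
        for w in windows:
            pid, src_p1, off = test_set.provenance[w.residues]
            ann = structures[pid]
            contexts.append(structure_context(ann.ss, ann.disorder, src_p1 + off))
        probs = self.score_windows(windows, contexts)
        paired = list(zip(probs.tolist(), test_set.labels().tolist()))
        tp, fn, fp, tn = confusion_from_scores(paired)
        return compute_metrics(
            tp, fn, fp, tn, paired, self.config.cost_fp, self.config.cost_fn
        )

    def summary(self) -> str:
        cfg = self.config
        depth = "unlimited" if cfg.max_depth is None else str(cfg.max_depth)
        lines = [
            "Caspase cleavage classifier",
            "---------------------------",
            f"Classifier        {cfg.classifier_kind}",
            f"Trees / depth     {cfg.n_trees} / {depth}",
            f"Training windows  {self.n_positive} positive, {self.n_negative} negative",
            f"PWM               {self.pwm.n_sequences} aligned sites, "
            f"pseudocount {self.pwm.pseudocount:g}",
            f"Features          {len(self.feature_names)} "
            "(8 PWM + 24 secondary-structure + 8 disorder)",
            f"Decision rule     cleavage 'yes' if P(cleaved) >= {SCORE_THRESHOLD}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "package_version": __version__,
            "estimator": self.estimator,
            "pwm_log2": self.pwm.log2_ratio,
            "pwm_background": dict(self.pwm.background.freq),
            "pwm_pseudocount": self.pwm.pseudocount,
            "pwm_n": self.pwm.n_sequences,
            "config": self.config,
            "feature_names": self.feature_names,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        joblib.dump(payload, path)


def load_model(path: str | Path) -> CleavageResults:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt or not a joblib file
        raise ModelError(f"{path}: cannot load model ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"{path}: not a caspcleave model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"{path}: model format {payload['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    pwm = PositionWeightMatrix(
        payload["pwm_log2"],
        BackgroundDistribution(payload["pwm_background"]),
        payload["pwm_pseudocount"],
        payload["pwm_n"],
    )
    return CleavageResults(
        model=None,
        estimator=payload["estimator"],
        pwm=pwm,
        config=payload["config"],
        feature_names=tuple(payload["feature_names"]),
        n_positive=payload["n_positive"],
        n_negative=payload["n_negative"],
    )
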