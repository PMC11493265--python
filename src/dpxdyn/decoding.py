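"""Per-timepoint linear decoding and generalisation across time (GAT).

A linear support-vector classifier is trained independently at every time
sample on the channel vector of that sample (standardised with training-fold
statistics), under 5-fold stratified cross-validation with class weights
inversely proportional to class frequency (baseline C = 1). Each trained
classifier is then scored at every other time sample, giving a train-time x
test-time matrix of fold-averaged ROC-AUC values; 0.5 is chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .data import SubjectEpochs, TimeAxis, WindowError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecoderSpec:
    """Linear decoder settings.

    ``scorer='decision'`` ranks the classifier's continuous decision values
    when computing the AUC; ``'prediction'`` ranks the hard class labels
    instead (kept for comparison — graded AUC values require the former).
    """

    C: float = 1.0
    n_folds: int = 5
    seed: int = 0
    scorer: str = "decision"

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.scorer not in ("decision", "prediction"):
            raise ValueError("scorer must be 'decision' or 'prediction'")


@dataclass
class GATResult:
    """Per-subject and group train-time x test-time AUC matrices."""

    per_subject_auc: np.ndarray   # (n_subjects, n_train, n_test)
    timeaxis: TimeAxis
    contrast: str = ""
    chance: float = 0.5
    diag_mask: np.ndarray | None = None
    matrix_mask: np.ndarray | None = None

    @property
    def group_mean_auc(self) -> np.ndarray:
        return self.per_subject_auc.mean(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        """(n_subjects, n_times) AUC of classifiers tested where trained."""
        return np.einsum("stt->st", self.per_subject_auc)


def select_contrast(trials, contrast: str):
    """Trial mask and binary labels for a contrast like ``"AX vs BX"``.

    The right-hand condition is the positive class.
    """
    try:
        neg, pos = [c.strip() for c in contrast.split("vs")]
    except ValueError as e:
        raise ValueError(f"cannot parse contrast {contrast!r}") from e
    pairs = trials["pair"]
    keep = pairs.isin([neg, pos]).to_numpy()
    y = (pairs[keep] == pos).to_numpy(dtype=int)
    return keep, y


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based ROC AUC per column of a (trials x cells) score matrix."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(scores, axis=0)
    return (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def fit_and_score_gat(
    epochs: SubjectEpochs, labels: np.ndarray, spec: DecoderSpec | None = None
) -> np.ndarray:
    """One subject's GAT matrix of fold-averaged ROC-AUC values.

    Folds are stratified by label and shuffled once per subject, and shared
    across training times so all matrix cells are comparable. Features are
    the raw channel vector at the training time, standardised with
    training-fold statistics; the same affine transform (training-time
    statistics) is applied when the classifier is scored at other times.
    """
    spec = spec or DecoderSpec()
    y = np.asarray(labels, dtype=int)
    data = epochs.data
    n_tr, n_ch, n_t = data.shape
    if y.shape != (n_tr,):
        raise ValueError("labels must have one entry per trial")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < spec.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} trials; need >= n_folds={spec.n_folds}"
        )
    skf = StratifiedKFold(
        n_splits=spec.n_folds, shuffle=True, random_state=spec.seed % (2**31)
    )
    auc = np.zeros((n_t, n_t))
    for train_idx, test_idx in skf.split(np.zeros(n_tr), y):
        Xtr, ytr = data[train_idx], y[train_idx]
        Xte, yte = data[test_idx], y[test_idx]
        fold_scores = np.empty((n_t, len(test_idx), n_t))
        for t in range(n_t):
            mu = Xtr[:, :, t].mean(axis=0)
            sd = Xtr[:, :, t].std(axis=0)
            sd[sd < 1e-12] = 1.0
            clf = LinearSVC(
                C=spec.C, class_weight="balanced", dual=False, max_iter=5000
            )
            clf.fit((Xtr[:, :, t] - mu) / sd, ytr)
            w = clf.coef_[0] / sd
            b = clf.intercept_[0] - float((clf.coef_[0] * mu / sd).sum())
            fold_scores[t] = np.einsum("c,ict->it", w, Xte) + b
        if spec.scorer == "prediction":
            fold_scores = (fold_scores > 0).astype(float)
        for t in range(n_t):
            auc[t] += _rank_auc(fold_scores[t], yte)
    return auc / spec.n_folds


def gat_for_subjects(
    subjects: list[SubjectEpochs], contrast: str, spec: DecoderSpec | None = None
) -> GATResult:
    """Fit per-subject GAT matrices for a pairwise trial-type contrast."""
    spec = spec or DecoderSpec()
    mats = []
    for i, ep in enumerate(subjects):
        keep, y = select_contrast(ep.trials, contrast)
        sub_spec = DecoderSpec(
            C=spec.C, n_folds=spec.n_folds,
            seed=(spec.seed + 7919 * i) % (2**31), scorer=spec.scorer,
        )
        sub = SubjectEpochs(
            subject_id=ep.subject_id, data=ep.data[keep], channels=ep.channels,
            timeaxis=ep.timeaxis, trials=ep.trials.loc[keep], lock_event=ep.lock_event,
        )
        mats.append(fit_and_score_gat(sub, y, sub_spec))
    return GATResult(
        per_subject_auc=np.stack(mats), timeaxis=subjects[0].timeaxis,
        contrast=contrast,
    )


def diagonal_performance(gat: GATResult) -> np.ndarray:
    """Exact per-subject diagonal of the GAT matrix (no recomputation)."""
    return gat.diagonal


def window_generalisation(
    gat: GATResult, train_window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Average test-time curves of classifiers trained inside a closed window.

    Returns ``(per_subject, group_mean)`` with shapes (S, n_test) and
    (n_test,).
    """
    t = gat.timeaxis.times
    rows = (t >= train_window[0]) & (t <= train_window[1])
    if not rows.any():
        raise WindowError(f"no training times inside {train_window}")
    per_subject = gat.per_subject_auc[:, rows, :].mean(axis=1)
    return per_subject, per_subject.mean(axis=0)


def group_significance(
    scores: np.ndarray, chance: float = 0.5, alpha: float = 0.01
) -> np.ndarray:
    """Two-sided one-sample t vs chance, Bonferroni over all tested cells.

    ``scores`` is (n_subjects, ...); the mask marks cells whose
    Bonferroni-adjusted p-value is below alpha. Zero-variance cells are
    non-significant unless every subject deviates from chance identically in
    the same direction (then flagged significant and logged).
    """
    scores = np.asarray(scores, dtype=float)
    S = scores.shape[0]
    if S < 3:
        raise ValueError("need >= 3 subjects")
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    n_cells = int(np.prod(mean.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - chance) / (sd / np.sqrt(S))
    p = 2.0 * stats.t.sf(np.abs(t), df=S - 1)
    degenerate = sd == 0
    if degenerate.any():
        same_dir = degenerate & (mean != chance)
        p = np.where(same_dir, 0.0, p)
        p = np.where(degenerate & (mean == chance), 1.0, p)
        if same_dir.any():
            logger.warning(
                "group significance: %d zero-variance cells off chance "
                "flagged significant", int(same_dir.sum()),
            )
    return np.minimum(p * n_cells, 1.0) < alpha
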