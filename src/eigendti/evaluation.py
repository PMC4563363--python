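"""Experimental harness: pair-level CV, metrics, bootstrap, and ranking.

Evaluation is pair-level: the known interactions (Y entries equal to 1) and
the unknown pairs (entries equal to 0) are *each* split into folds of nearly
equal size.  Masking a fold sets its known entries to 0 in the training
matrix; the held-out known pairs (positives) together with the held-out
unknown pairs (negatives) form the test set whose labels the predictor must
recover.

Hyperparameter selection is nested: the outer loop estimates generalization,
an inner loop over the outer-training pairs picks the eigenvalue exponent
alpha from a grid by the combined score Q = w1*AUC + w2*AUPR.  Running the
harness with the degenerate grid {1.0} reproduces a plain CV of the original
algorithm, so the harness itself cannot advantage the transformation.

Statistical significance of transformed-vs-original is assessed with a paired
bootstrap over the test pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import InteractionMatrix, ScoreMatrix
from .kernel_prep import KernelMatrix
from .predictors import PredictorSpec, predict
from .spectral import SpectralDecomposition, decompose

DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(21))  # 0.0 .. 2.0
DEFAULT_WEIGHTS = (0.5, 0.5)


# ---------------------------------------------------------------------------
# metrics


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann-Whitney statistic); ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))

def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall step curve (average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricSet:
    """AUC, AUPR and their convex combination Q = w1*AUC + w2*AUPR."""

    auc: float
    aupr: float
    w1: float = DEFAULT_WEIGHTS[0]
    w2: float = DEFAULT_WEIGHTS[1]

    def __post_init__(self):
        _check_weights(self.w1, self.w2)

    @property
    def q(self) -> float:
        return self.w1 * self.auc + self.w2 * self.aupr


def _check_weights(w1: float, w2: float) -> None:
    if not math.isclose(w1 + w2, 1.0, abs_tol=1e-12):
        raise ValueError("combined-score weights must sum to 1")
    if w1 < 0 or w2 < w1:
        raise ValueError("combined-score weights need w2 >= w1 >= 0 "
                         "(AUPR is the more informative metric for rare positives)")


def combined_q(auc_value: float, aupr_value: float,
               weights: tuple[float, float] = DEFAULT_WEIGHTS) -> float:
    _check_weights(*weights)
    return weights[0] * auc_value + weights[1] * aupr_value


def metric_set(scores: np.ndarray, labels: np.ndarray,
               weights: tuple[float, float] = DEFAULT_WEIGHTS) -> MetricSet:
    return MetricSet(auc=auc(scores, labels), aupr=aupr(scores, labels),
                     w1=weights[0], w2=weights[1])


# ---------------------------------------------------------------------------
# folds and masking


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified pair-level fold labels for known and unknown pairs.

    ``known_pairs``/``unknown_pairs`` are (row, col) index arrays into Y;
    ``known_fold``/``unknown_fold`` give each pair's fold id.
    """

    n_folds: int
    known_pairs: np.ndarray  # (n_known, 2) int
    unknown_pairs: np.ndarray  # (n_unknown, 2) int
    known_fold: np.ndarray  # (n_known,) int
    unknown_fold: np.ndarray  # (n_unknown,) int
    seed: int


def make_folds(Y: InteractionMatrix, n_folds: int, seed: int) -> FoldAssignment:
    """Randomly partition known and unknown pairs each into n_folds groups.

    Group sizes within each stratum differ by at most one; the assignment is
    a pure function of (Y, n_folds, seed).
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    known = np.argwhere(Y.values == 1)
    unknown = np.argwhere(Y.values == 0)
    if len(known) < n_folds or len(unknown) < n_folds:
        raise ValueError(
            f"need >= {n_folds} known and unknown pairs "
            f"(have {len(known)} known, {len(unknown)} unknown)"
        )
    rng = np.random.default_rng(seed)
    known_fold = rng.permutation(np.arange(len(known)) % n_folds)
    unknown_fold = rng.permutation(np.arange(len(unknown)) % n_folds)
    return FoldAssignment(
        n_folds=n_folds,
        known_pairs=known,
        unknown_pairs=unknown,
        known_fold=known_fold,
        unknown_fold=unknown_fold,
        seed=seed,
    )


@dataclass(frozen=True)
class TestIndex:
    """Held-out pairs of one fold with their true labels."""

    pairs: np.ndarray  # (m, 2) int, rows then labels aligned
    labels: np.ndarray  # (m,) 0/1

    def scores_at(self, F: ScoreMatrix) -> np.ndarray:
        return F.values[self.pairs[:, 0], self.pairs[:, 1]]


def mask_fold(Y: InteractionMatrix, folds: FoldAssignment,
              fold_id: int) -> tuple[InteractionMatrix, TestIndex]:
    """Zero out one fold's known pairs; earmark that fold's pairs for testing."""
    if not 0 <= fold_id < folds.n_folds:
        raise ValueError(f"fold_id {fold_id} out of range")
    held_known = folds.known_pairs[folds.known_fold == fold_id]
    held_unknown = folds.unknown_pairs[folds.unknown_fold == fold_id]
    Y_train_vals = Y.values.copy()
    Y_train_vals[held_known[:, 0], held_known[:, 1]] = 0.0
    Y_train = InteractionMatrix(Y.drug_ids, Y.target_ids, Y_train_vals)
    pairs = np.vstack([held_known, held_unknown])
    labels = np.concatenate(
        [np.ones(len(held_known), dtype=int), np.zeros(len(held_unknown), dtype=int)]
    )
    return Y_train, TestIndex(pairs=pairs, labels=labels)


# ---------------------------------------------------------------------------
# nested cross-validation


def grid_search_alpha(
    spec_template: PredictorSpec,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y_train: InteractionMatrix,
    n_inner: int,
    alpha_grid: tuple[float, ...],
    weights: tuple[float, float],
    seed: int,
    *,
    drug_eigen: SpectralDecomposition | None = None,
    target_eigen: SpectralDecomposition | None = None,
) -> tuple[float, dict[float, float]]:
    """Inner-CV selection of the eigenvalue exponent.

    Returns the alpha maximizing mean inner-test Q and the per-alpha mean Q
    table.  Ties break toward the alpha closest to 1 (the original
    algorithm), then toward the smaller alpha.
    """
    if not alpha_grid:
        raise ValueError("alpha grid must be nonempty")
    if drug_eigen is None:
        drug_eigen = decompose(K_d)
    if target_eigen is None:
        target_eigen = decompose(K_t)
    inner_folds = make_folds(Y_train, n_inner, seed)
    q_sums = {a: 0.0 for a in alpha_grid}
    for fold_id in range(n_inner):
        Y_inner, test_index = mask_fold(Y_train, inner_folds, fold_id)
        for a in alpha_grid:
            F = predict(
                spec_template.with_alpha(a), K_d, K_t, Y_inner,
                drug_eigen=drug_eigen, target_eigen=target_eigen,
            )
            s = test_index.scores_at(F)
            q_sums[a] += combined_q(auc(s, test_index.labels),
                                    aupr(s, test_index.labels), weights)
    mean_q = {a: q_sums[a] / n_inner for a in alpha_grid}
    best = min(mean_q, key=lambda a: (-mean_q[a], abs(a - 1.0), a))
    return best, mean_q


@dataclass(frozen=True)
class FoldResult:
    fold_id: int
    train: MetricSet
    test: MetricSet
    chosen_alpha: float
    p_value: float | None = None


@dataclass(frozen=True)
class CVReport:
    """Per-outer-fold metrics plus aggregates; fully seed-determined."""

    folds: tuple[FoldResult, ...]
    weights: tuple[float, float]
    seed: int

    def mean(self, attr: str, split: str = "test") -> float:
        return float(np.mean([getattr(getattr(f, split), attr) for f in self.folds]))

    def chosen_alphas(self) -> list[float]:
        return [f.chosen_alpha for f in self.folds]


def nested_cv(
    spec_template: PredictorSpec,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y: InteractionMatrix,
    n_outer: int = 10,
    n_inner: int = 10,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    seed: int = 0,
    *,
    baseline_alpha: float | None = None,
    n_boot: int = 1000,
) -> CVReport:
    """Double CV: outer folds estimate performance, inner folds pick alpha.

    When ``baseline_alpha`` is given, each outer fold also fits the predictor
    at that fixed exponent on the same training matrix and reports a paired
    bootstrap p-value for "tuned model outperforms baseline" on the fold's
    test pairs.
    """
    _check_weights(*weights)
    drug_eigen = decompose(K_d)
    target_eigen = decompose(K_t)
    outer_folds = make_folds(Y, n_outer, seed)
    ss = np.random.SeedSequence(seed)
    inner_seeds, boot_seeds = _spawn_seeds(ss, n_outer)
    results = []
    for fold_id in range(n_outer):
        Y_train, test_index = mask_fold(Y, outer_folds, fold_id)
        best_alpha, _ = grid_search_alpha(
            spec_template, K_d, K_t, Y_train, n_inner, alpha_grid, weights,
            inner_seeds[fold_id], drug_eigen=drug_eigen, target_eigen=target_eigen,
        )
        F = predict(
            spec_template.with_alpha(best_alpha), K_d, K_t, Y_train,
            drug_eigen=drug_eigen, target_eigen=target_eigen,
        )
        test_scores = test_index.scores_at(F)
        test_metrics = metric_set(test_scores, test_index.labels, weights)
        train_pairs, train_labels = _training_pairs(Y, outer_folds, fold_id)
        train_scores = F.values[train_pairs[:, 0], train_pairs[:, 1]]
        train_metrics = metric_set(train_scores, train_labels, weights)
        p_value = None
        if baseline_alpha is not None:
            F_base = predict(
                spec_template.with_alpha(baseline_alpha), K_d, K_t, Y_train,
                drug_eigen=drug_eigen, target_eigen=target_eigen,
            )
            p_value = bootstrap_compare(
                test_scores,
                test_index.scores_at(F_base),
                test_index.labels,
                n_boot=n_boot,
                weights=weights,
                seed=boot_seeds[fold_id],
            )
        results.append(
            FoldResult(fold_id, train_metrics, test_metrics, best_alpha, p_value)
        )
    return CVReport(folds=tuple(results), weights=weights, seed=seed)


def _spawn_seeds(ss: np.random.SeedSequence, n: int) -> tuple[list[int], list[int]]:
    children = ss.spawn(2)
    inner = [int(s.generate_state(1)[0] % (2 ** 31)) for s in children[0].spawn(n)]
    boot = [int(s.generate_state(1)[0] % (2 ** 31)) for s in children[1].spawn(n)]
    return inner, boot


def _training_pairs(Y: InteractionMatrix, folds: FoldAssignment,
                    fold_id: int) -> tuple[np.ndarray, np.ndarray]:
    keep_known = folds.known_pairs[folds.known_fold != fold_id]
    keep_unknown = folds.unknown_pairs[folds.unknown_fold != fold_id]
    pairs = np.vstack([keep_known, keep_unknown])
    labels = np.concatenate(
        [np.ones(len(keep_known), dtype=int), np.zeros(len(keep_unknown), dtype=int)]
    )
    return pairs, labels


# ---------------------------------------------------------------------------
# bootstrap significance


def bootstrap_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    seed: int = 0,
    max_redraws: int = 10000,
) -> float:
    """Paired bootstrap p-value for "model a outperforms model b" in Q.

    Test pairs are resampled with replacement; replicates whose labels are
    degenerate (one class only) are redrawn.  The add-one estimator
    ``p = (1 + #{Q_a <= Q_b}) / (n_boot + 1)`` avoids p = 0.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score vectors and labels must share one test set")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(labels)
    losses = 0
    redraws = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        q_a = combined_q(auc(scores_a[idx], lab), aupr(scores_a[idx], lab), weights)
        q_b = combined_q(auc(scores_b[idx], lab), aupr(scores_b[idx], lab), weights)
        if q_a <= q_b:
            losses += 1
        done += 1
    return (1 + losses) / (n_boot + 1)


# ---------------------------------------------------------------------------
# new-interaction ranking


def rank_new_interactions(scores: ScoreMatrix, Y: InteractionMatrix,
                          top_n: int = 15) -> list[tuple[int, str, str, float]]:
    """Rank non-interacting pairs by descending score; Table-of-predictions shape.

    Ties break lexically by (drug_id, target_id).  Returns up to ``top_n``
    rows of (rank, drug_id, target_id, score).
    """
    if scores.drug_ids != Y.drug_ids or scores.target_ids != Y.target_ids:
        raise ValueError("score and interaction matrices are not aligned")
    zero = np.argwhere(Y.values == 0)
    rows = [
        (scores.drug_ids[i], scores.target_ids[j], float(scores.values[i, j]))
        for i, j in zero
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return [(k + 1, d, t, s) for k, (d, t, s) in enumerate(rows[:top_n])]
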