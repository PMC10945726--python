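"""Nested k-fold cross-validation comparing PWM and APFA on one sample.

Both models train on positive sequences only; non-positive sequences
enter at scoring time.  One 7-fold partition (of positives and, in
parallel, of non-positives) serves both loops:

* inner loop (hyperparameter and threshold calibration): in iteration
  i the test fold i is untouched, fold i+1 calibrates, and the
  remaining five folds train.  Each APFA hyperparameter combination is
  scored by its Average Precision on the calibration fold plus the
  matching non-positive fold, averaged over the seven iterations; the
  classification thresholds are the averages of the per-iteration
  F1-optimal score cuts.
* outer loop (performance estimation): in iteration i both models
  train on the six non-test folds and are scored on test fold i plus
  non-positive fold i, giving seven AP values per model.

The comparison is summarised by Cohen's D, the standardised difference
of the two models' mean AP with pooled standard deviation; D >= 0.4
labels the sample APFA-preferred, otherwise the simpler PWM is
recommended.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .apfa import LearnApfaHyperparams, default_grid, learn_apfa, score_apfa_many
from .negatives import DEFAULT_SEED, NonPositiveSample
from .pwm import score_pwm_many, train_pwm
from .sequence_io import NullModel, TFBSSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 7
    seed: int = DEFAULT_SEED
    apfa_grid: tuple[LearnApfaHyperparams, ...] = field(default_factory=default_grid)
    selector_folds: int = 10

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.apfa_grid:
            raise ValueError("hyperparameter grid must be nonempty")


@dataclass(frozen=True)
class ModelComparison:
    ap_pwm: tuple[float, ...]
    ap_apfa: tuple[float, ...]
    mean_ap_pwm: float
    mean_ap_apfa: float
    d: float
    preferred: str  # "APFA" or "PWM"
    best_hp: LearnApfaHyperparams
    threshold_pwm: float
    threshold_apfa: float

    def to_dict(self) -> dict:
        return {
            "ap_pwm": list(self.ap_pwm),
            "ap_apfa": list(self.ap_apfa),
            "mean_ap_pwm": self.mean_ap_pwm,
            "mean_ap_apfa": self.mean_ap_apfa,
            "cohens_d": self.d,
            "preferred": self.preferred,
            "best_hp": {
                "mu": self.best_hp.mu,
                "m0": self.best_hp.m0,
                "gamma": self.best_hp.gamma,
            },
            "threshold_pwm": self.threshold_pwm,
            "threshold_apfa": self.threshold_apfa,
        }


def split_folds(items, k: int, seed: int) -> list[list]:
    """Partition items into k folds of near-equal size (differ by <= 1).

    A seeded permutation assigns items; the partition is deterministic
    given the seed.
    """
    items = list(items)
    if len(items) < k:
        raise ValueError(f"cannot split {len(items)} items into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    sizes = np.full(k, len(items) // k)
    sizes[: len(items) % k] += 1
    folds, start = [], 0
    for sz in sizes:
        folds.append([items[i] for i in perm[start : start + sz]])
        start += sz
    return folds


def average_precision(pos_scores, neg_scores) -> float:
    """Area under the precision-recall curve via the AP summation.

    AP = sum_k (R_k - R_{k-1}) P_k over the descending sweep of
    distinct score thresholds; tied scores are grouped at a single
    threshold, so no ordering credit is granted within a tie.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score collections must be nonempty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # indices where a block of tied scores ends
    block_end = np.nonzero(np.diff(scores))[0]
    block_end = np.append(block_end, scores.size - 1)
    tp = np.cumsum(labels)[block_end]
    total = block_end + 1.0
    precision = tp / total
    recall = tp / pos.size
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def calibrate_threshold(pos_scores, neg_scores) -> float:
    """Score cut maximising F1, classifying score >= cut as positive.

    Candidate cuts are the midpoints between adjacent distinct pooled
    scores; among equally good cuts the smallest is returned.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score collections must be nonempty")
    distinct = np.unique(np.concatenate([pos, neg]))
    if distinct.size == 1:
        warnings.warn("all scores identical; threshold degenerate", stacklevel=2)
        return float(distinct[0])
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    best_cut, best_f1 = cuts[0], -1.0
    for cut in cuts:
        tp = np.count_nonzero(pos >= cut)
        fp = np.count_nonzero(neg >= cut)
        fn = pos.size - tp
        f1 = 2.0 * tp / (2.0 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1:
            best_f1, best_cut = f1, cut
    return float(best_cut)


def cohens_d(ap_apfa, ap_pwm) -> float:
    """Standardised mean AP difference; positive values favor the APFA.

    Pooled standard deviation with equal group sizes n:
    s = sqrt(((n-1) s1^2 + (n-1) s2^2) / (2n - 2)).  When s = 0 the
    value is 0 for equal means and +/-inf otherwise, preserving the
    preference semantics.
    """
    a = np.asarray(ap_apfa, dtype=float)
    p = np.asarray(ap_pwm, dtype=float)
    if a.size != p.size or a.size < 2:
        raise ValueError("need two equal-length collections of >= 2 AP values")
    n = a.size
    s = np.sqrt(((n - 1) * a.var(ddof=1) + (n - 1) * p.var(ddof=1)) / (2 * n - 2))
    diff = a.mean() - p.mean()
    if s <= 1e-12:  # degenerate pooled variance
        return 0.0 if abs(diff) <= 1e-12 else float(np.sign(diff)) * float("inf")
    return float(diff / s)


#: Effect-size threshold above which the APFA is preferred.
D_THRESHOLD = 0.4


def label_preference(d: float) -> str:
    """"APFA" iff Cohen's D >= 0.4, else "PWM" (the simpler model)."""
    return "APFA" if d >= D_THRESHOLD else "PWM"


def _train_indices(k: int, test: int, cal: int | None):
    return [f for f in range(k) if f != test and f != cal]


def inner_cv(
    pos_folds: list[np.ndarray],
    neg_folds: list[np.ndarray],
    grid,
    null: NullModel,
    sample: TFBSSample,
) -> tuple[LearnApfaHyperparams, float, float]:
    """Calibrate APFA hyperparameters and both classification thresholds.

    Folds are index arrays into the sample / negatives matrices; see the
    module docstring for the iteration layout.  Ties in mean calibration
    AP prefer the more aggressively merged, more smoothed model (larger
    mu, then m0, then gamma).
    """
    k = len(pos_folds)
    mat = sample.matrix()
    grid = list(grid)
    ap_by_hp = np.zeros((len(grid), k))
    pwm_cuts, iter_models = [], []
    for i in range(k):
        cal = (i + 1) % k
        train_idx = np.concatenate([pos_folds[f] for f in _train_indices(k, i, cal)])
        train_sample = sample.subset(train_idx)
        cal_pos = mat[pos_folds[cal]]
        cal_neg = neg_folds[cal]
        pwm = train_pwm(train_sample, null)
        pos_s = score_pwm_many(pwm, cal_pos)
        neg_s = score_pwm_many(pwm, cal_neg)
        pwm_cuts.append(calibrate_threshold(pos_s, neg_s))
        for g, hp in enumerate(grid):
            a = learn_apfa(train_sample, hp)
            ap_by_hp[g, i] = average_precision(
                score_apfa_many(a, cal_pos, null), score_apfa_many(a, cal_neg, null)
            )
        iter_models.append((train_sample, cal_pos, cal_neg))
    mean_ap = ap_by_hp.mean(axis=1)
    for g, hp in enumerate(grid):
        logger.info(
            "grid point mu=%.3g m0=%.3g gamma=%.3g mean calibration AP=%.4f",
            hp.mu, hp.m0, hp.gamma, mean_ap[g],
        )
    best = max(
        range(len(grid)),
        key=lambda g: (mean_ap[g], grid[g].mu, grid[g].m0, grid[g].gamma),
    )
    best_hp = grid[best]
    apfa_cuts = []
    for train_sample, cal_pos, cal_neg in iter_models:
        a = learn_apfa(train_sample, best_hp)
        apfa_cuts.append(
            calibrate_threshold(
                score_apfa_many(a, cal_pos, null), score_apfa_many(a, cal_neg, null)
            )
        )
    return best_hp, float(np.mean(pwm_cuts)), float(np.mean(apfa_cuts))


def outer_cv(
    sample: TFBSSample,
    negatives: NonPositiveSample,
    cfg: CVConfig,
    null: NullModel,
) -> ModelComparison:
    """Estimate and compare PWM and APFA performance on one sample."""
    k = cfg.k_folds
    if sample.n < 2 * k:
        raise ValueError(
            f"sample of {sample.n} sequences is too small for {k}-fold nested CV"
        )
    if negatives.l != sample.l:
        raise ValueError("negatives and sample have different sequence lengths")
    pos_folds = [np.array(f, dtype=np.intp) for f in split_folds(range(sample.n), k, cfg.seed)]
    neg_mat = negatives.matrix()
    neg_folds = [
        neg_mat[np.array(f, dtype=np.intp)]
        for f in split_folds(range(len(neg_mat)), k, cfg.seed)
    ]
    best_hp, thr_pwm, thr_apfa = inner_cv(
        pos_folds, neg_folds, cfg.apfa_grid, null, sample
    )
    mat = sample.matrix()
    ap_pwm, ap_apfa = [], []
    for i in range(k):
        train_idx = np.concatenate([pos_folds[f] for f in _train_indices(k, i, None)])
        train_sample = sample.subset(train_idx)
        test_pos = mat[pos_folds[i]]
        test_neg = neg_folds[i]
        pwm = train_pwm(train_sample, null)
        ap_pwm.append(
            average_precision(
                score_pwm_many(pwm, test_pos), score_pwm_many(pwm, test_neg)
            )
        )
        a = learn_apfa(train_sample, best_hp)
        ap_apfa.append(
            average_precision(
                score_apfa_many(a, test_pos, null), score_apfa_many(a, test_neg, null)
            )
        )
        logger.debug("outer fold %d: AP_pwm=%.4f AP_apfa=%.4f", i, ap_pwm[-1], ap_apfa[-1])
    d = cohens_d(ap_apfa, ap_pwm)
    return ModelComparison(
        ap_pwm=tuple(ap_pwm),
        ap_apfa=tuple(ap_apfa),
        mean_ap_pwm=float(np.mean(ap_pwm)),
        mean_ap_apfa=float(np.mean(ap_apfa)),
        d=d,
        preferred=label_preference(d),
        best_hp=best_hp,
        threshold_pwm=thr_pwm,
        threshold_apfa=thr_apfa,
    )
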