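"""Inter-position dependency measures and the per-sample feature vector.

For a pair of motif positions (j, h) the smoothed joint distribution is

    P(b_j, b_h) = (N(b_j, b_h) + 1/n) / (n + 16/n)

where N counts joint occurrences over the n sequences; the 1/n
pseudocount keeps every one of the 16 cells positive and the marginals
are the row/column sums.  On this table we compute

* Cramér's V: sqrt(chi2 / (min(c-1, r-1) * n)) with c = r = 4, a
  chi-square-derived association measure in [0, 1];
* symmetric Theil's U: 2 I / (H_j + H_h), mutual information
  normalised by the mean entropy, also in [0, 1] and base-invariant
  (entropies and I are computed in nats).

A sample's feature vector collects the mean and max of each measure
over all l(l-1)/2 unordered position pairs, plus the sample size n and
the mean information content (mIC) of a PWM trained on the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import PWM, train_pwm
from .sequence_io import NullModel, TFBSSample

#: Column order used whenever features are laid out as a plain vector.
FEATURE_NAMES = (
    "n_sequences",
    "mic",
    "mean_cramers_v",
    "max_cramers_v",
    "mean_theils_u",
    "max_theils_u",
)


@dataclass(frozen=True)
class PairTable:
    """Smoothed joint distribution of nucleotides at two positions."""

    j: int  # 1-based position index
    h: int
    P: np.ndarray  # (4, 4); axis 0 = position j, axis 1 = position h
    n: int

    @property
    def marginal_j(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def marginal_h(self) -> np.ndarray:
        return self.P.sum(axis=0)


@dataclass(frozen=True)
class FeatureVector:
    n_sequences: int
    mic: float
    mean_cramers_v: float
    max_cramers_v: float
    mean_theils_u: float
    max_theils_u: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def _check_pair(sample: TFBSSample, j: int, h: int) -> None:
    if j == h:
        raise ValueError("positions j and h must differ")
    if not (1 <= j <= sample.l and 1 <= h <= sample.l):
        raise ValueError(f"positions must be in [1, {sample.l}], got ({j}, {h})")


def joint_table(sample: TFBSSample, j: int, h: int) -> PairTable:
    """Pseudocount-smoothed joint distribution of positions j and h (1-based)."""
    _check_pair(sample, j, h)
    mat = sample.matrix()
    n = sample.n
    N = np.zeros((4, 4), dtype=float)
    np.add.at(N, (mat[:, j - 1], mat[:, h - 1]), 1.0)
    P = (N + 1.0 / n) / (n + 16.0 / n)
    return PairTable(j=j, h=h, P=P, n=n)


def cramers_v_from_table(t: PairTable) -> float:
    expected = np.outer(t.marginal_j, t.marginal_h)
    chi2 = t.n * ((t.P - expected) ** 2 / expected).sum()
    return float(np.sqrt(chi2 / (3.0 * t.n)))


def theils_u_from_table(t: PairTable) -> float:
    pj, ph = t.marginal_j, t.marginal_h
    mi = float((t.P * np.log(t.P / np.outer(pj, ph))).sum())
    hj = float(-(pj * np.log(pj)).sum())
    hh = float(-(ph * np.log(ph)).sum())
    assert hj + hh > 0.0, "entropies cannot both vanish on a smoothed table"
    return 2.0 * mi / (hj + hh)


def cramers_v(sample: TFBSSample, j: int, h: int) -> float:
    """Cramér's V between positions j and h, in [0, 1]."""
    return cramers_v_from_table(joint_table(sample, j, h))


def theils_u(sample: TFBSSample, j: int, h: int) -> float:
    """Symmetric Theil's U between positions j and h, in [0, 1]."""
    return theils_u_from_table(joint_table(sample, j, h))


def information_content(pwm: PWM) -> float:
    """Total information content in bits: sum of p_hat * W over all cells.

    Cells with p_hat = 0 contribute 0 (the 0 * log 0 convention), so the
    IC is finite even when the score matrix contains -inf entries.
    """
    with np.errstate(invalid="ignore"):
        contrib = np.where(pwm.probs > 0, pwm.probs * pwm.scores, 0.0)
    return float(contrib.sum())


def mean_ic(pwm: PWM) -> float:
    """Information content per position (bits/position)."""
    return information_content(pwm) / pwm.l


def pairwise_matrices(sample: TFBSSample) -> tuple[np.ndarray, np.ndarray]:
    """Full l x l matrices of Cramér's V and Theil's U (diagonal = nan)."""
    l = sample.l
    V = np.full((l, l), np.nan)
    U = np.full((l, l), np.nan)
    for j in range(1, l + 1):
        for h in range(j + 1, l + 1):
            t = joint_table(sample, j, h)
            V[j - 1, h - 1] = V[h - 1, j - 1] = cramers_v_from_table(t)
            U[j - 1, h - 1] = U[h - 1, j - 1] = theils_u_from_table(t)
    return V, U


def extract_features(sample: TFBSSample, null: NullModel) -> FeatureVector:
    """Six summary features of a TFBS sample.

    Dependency measures are aggregated over all unordered position pairs
    (both are symmetric in (j, h)); mIC comes from a PWM trained on the
    full sample against ``null``.
    """
    if sample.l < 2:
        raise ValueError("feature extraction needs motif length >= 2")
    vs, us = [], []
    for j in range(1, sample.l + 1):
        for h in range(j + 1, sample.l + 1):
            t = joint_table(sample, j, h)
            vs.append(cramers_v_from_table(t))
            us.append(theils_u_from_table(t))
    pwm = train_pwm(sample, null)
    return FeatureVector(
        n_sequences=sample.n,
        mic=mean_ic(pwm),
        mean_cramers_v=float(np.mean(vs)),
        max_cramers_v=float(np.max(vs)),
        mean_theils_u=float(np.mean(us)),
        max_theils_u=float(np.max(us)),
    )
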