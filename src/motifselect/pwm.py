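"""Position weight matrices: training, scoring, serialization.

The probability estimate for nucleotide b_i at motif position j is

    p_hat[i, j] = (n_ij + psi_i) / (n + sum_i psi_i)

where n_ij is the count of b_i at position j, n the sample size, and
psi_i = alpha * f_i a pseudocount proportional to f_i, the count of b_i
anywhere in the sample, with alpha = 1/(10 n) by default.  The score
matrix is the log-odds W[i, j] = log2(p_hat[i, j] / q(b_i)) against a
background model q, and a sequence scores the sum of its per-position
entries.  Note psi_i is exactly zero for a nucleotide that never occurs
in the sample, so p_hat cells can be exactly zero; such cells score
-inf, which propagates through sums and sorts below any finite
threshold.  Pass ``min_prob`` to floor probabilities instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequence_io import ALPHABET, NullModel, TFBSSample, encode_sequences


@dataclass(frozen=True)
class PWM:
    probs: np.ndarray  # (4, l) column-stochastic probability matrix
    scores: np.ndarray  # (4, l) log2 odds in bits; -inf where probs == 0
    null: NullModel
    alpha: float
    threshold: float | None = None

    @property
    def l(self) -> int:  # noqa: E743
        return self.probs.shape[1]

    def with_threshold(self, threshold: float) -> "PWM":
        return replace(self, threshold=threshold)


def train_pwm(
    sample: TFBSSample,
    null: NullModel,
    alpha_override: float | None = None,
    min_prob: float = 0.0,
) -> PWM:
    """Train a PWM from a sample of aligned binding sites.

    ``alpha_override`` replaces the default pseudocount scale 1/(10 n);
    ``min_prob`` (default off) floors each probability cell before
    renormalising, eliminating -inf scores.
    """
    if alpha_override is not None and alpha_override <= 0:
        raise ValueError("alpha_override must be positive")
    mat = sample.matrix()
    n, l = mat.shape
    counts = np.zeros((4, l), dtype=float)
    for j in range(l):
        counts[:, j] = np.bincount(mat[:, j], minlength=4)
    alpha = alpha_override if alpha_override is not None else 1.0 / (10.0 * n)
    f = counts.sum(axis=1)  # whole-sample nucleotide counts
    psi = alpha * f
    probs = (counts + psi[:, None]) / (n + psi.sum())
    if min_prob > 0.0:
        probs = np.maximum(probs, min_prob)
        probs /= probs.sum(axis=0, keepdims=True)
    q = null.as_array()
    with np.errstate(divide="ignore"):
        scores = np.log2(probs / q[:, None])
    return PWM(probs=probs, scores=scores, null=null, alpha=alpha)


def score_pwm(pwm: PWM, s: str) -> float:
    """Log-odds score of one sequence in bits; -inf if any cell is zero."""
    if len(s) != pwm.l:
        raise ValueError(f"sequence length {len(s)} != motif length {pwm.l}")
    mat = encode_sequences([s])
    return float(score_pwm_many(pwm, mat)[0])


def score_pwm_many(pwm: PWM, mat: np.ndarray) -> np.ndarray:
    """Vectorised scores for an (n, l) encoded sequence matrix."""
    if mat.shape[1] != pwm.l:
        raise ValueError(f"matrix width {mat.shape[1]} != motif length {pwm.l}")
    return pwm.scores[mat, np.arange(pwm.l)].sum(axis=1)


def save_pwm(pwm: PWM, path) -> None:
    """Plain-text serialization: header line, then the 4 x l score matrix.

    Header carries l, alpha, background frequencies and threshold; rows
    of both matrices are in fixed A,C,G,T order.
    """
    q = pwm.null.as_array()
    thr = "nan" if pwm.threshold is None else repr(pwm.threshold)
    with open(path, "w") as fh:
        fh.write(
            f"#pwm l={pwm.l} alpha={float(pwm.alpha)!r} "
            f"null={','.join(repr(float(x)) for x in q)} threshold={thr}\n"
        )
        fh.write("#probs rows A,C,G,T\n")
        for row in pwm.probs:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def load_pwm(path) -> PWM:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(tok.split("=", 1) for tok in header.lstrip("#pwm ").split())
        fh.readline()  # probs comment line
        probs = np.array(
            [[float(x) for x in fh.readline().split("\t")] for _ in range(4)]
        )
    alpha = float(fields["alpha"])
    q = [float(x) for x in fields["null"].split(",")]
    null = NullModel(dict(zip(ALPHABET, q)))
    thr = float(fields["threshold"])
    with np.errstate(divide="ignore"):
        scores = np.log2(probs / null.as_array()[:, None])
    return PWM(
        probs=probs,
        scores=scores,
        null=null,
        alpha=alpha,
        threshold=None if np.isnan(thr) else thr,
    )
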