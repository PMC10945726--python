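"""Synthetic TFBS samples, genomes and labeled corpora.

The generator produces fixed-length samples with controllable
inter-position dependence: uncoupled positions are drawn independently
from per-position marginals, and a coupling (j -> h, strength rho,
bijective nucleotide mapping) overwrites position h with
mapping(symbol at j) with probability rho, leaving the marginal draw
otherwise.  rho = 0 gives fully independent positions, rho = 1 a
deterministic functional dependence of the kind a PWM cannot represent
but an APFA can.  Couplings are applied in list order, so chaining them
(the target of one is the source of another) builds higher-order
dependence.

Default marginals are Dirichlet-perturbed uniform (concentration 10),
giving mildly informative columns so trained PWMs have nonzero
information content without saturating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import ALPHABET, NullModel, TFBSSample, decode_matrix

#: Dirichlet concentration of the default randomised marginals.
MARGINAL_CONCENTRATION = 10.0


@dataclass(frozen=True)
class Coupling:
    source: int  # 1-based position
    target: int
    rho: float
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("coupling source and target must differ")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("coupling strength rho must be in [0, 1]")
        if sorted(self.mapping) != list(ALPHABET) or sorted(
            self.mapping.values()
        ) != list(ALPHABET):
            raise ValueError("mapping must be a bijection on {A, C, G, T}")

    def mapping_array(self) -> np.ndarray:
        code = {c: i for i, c in enumerate(ALPHABET)}
        return np.array([code[self.mapping[c]] for c in ALPHABET], dtype=np.uint8)


@dataclass(frozen=True)
class DependencySpec:
    """Marginals plus a list of pairwise couplings for one sample."""

    marginals: np.ndarray  # (l, 4), each row sums to 1
    couplings: tuple[Coupling, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.marginals, dtype=float)
        object.__setattr__(self, "marginals", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("marginals must be an (l, 4) array")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each marginal row must be a probability vector")
        l = m.shape[0]
        for c in self.couplings:
            if not (1 <= c.source <= l and 1 <= c.target <= l):
                raise ValueError(f"coupling positions out of range [1, {l}]")

    @property
    def l(self) -> int:  # noqa: E743
        return self.marginals.shape[0]


IDENTITY_MAPPING = {c: c for c in ALPHABET}


def uniform_spec(l: int, couplings: tuple[Coupling, ...] = ()) -> DependencySpec:  # noqa: E741
    return DependencySpec(np.full((l, 4), 0.25), couplings)


def dirichlet_marginals(
    l: int,  # noqa: E741
    rng: np.random.Generator,
    concentration: float = MARGINAL_CONCENTRATION,
) -> np.ndarray:
    """Per-position marginals drawn from Dirichlet(concentration * uniform)."""
    return rng.dirichlet(np.full(4, concentration * 0.25), size=l)


def generate_sample(
    l: int,  # noqa: E741
    n: int,
    spec: DependencySpec,
    seed: int,
    tf_name: str = "synthetic",
) -> TFBSSample:
    """Draw a sample of n sequences of length l under ``spec``."""
    if spec.l != l:
        raise ValueError(f"spec is for length {spec.l}, requested {l}")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, l))
    cum = np.cumsum(spec.marginals, axis=1)
    mat = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)
    np.clip(mat, 0, 3, out=mat)
    for c in spec.couplings:
        mask = rng.random(n) < c.rho
        mat[mask, c.target - 1] = c.mapping_array()[mat[mask, c.source - 1]]
    return TFBSSample(
        tuple(decode_matrix(mat)), tf_name=tf_name, source="synthetic"
    )


def generate_genome(length: int, composition: NullModel, seed: int) -> str:
    """An i.i.d. genome string of the given length and composition."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=composition.as_array()).astype(np.uint8)
    return decode_matrix(codes[None, :])[0]


def random_bijection(rng: np.random.Generator) -> dict[str, str]:
    perm = rng.permutation(4)
    return {ALPHABET[i]: ALPHABET[perm[i]] for i in range(4)}


def generate_corpus(
    n_samples: int,
    frac_dependent: float,
    l: int,  # noqa: E741
    n: int,
    seed: int,
    rho: float = 1.0,
) -> list[tuple[TFBSSample, str]]:
    """A mixed corpus of coupled and independent samples with ground truth.

    The first round(frac_dependent * n_samples) samples carry one
    coupling of strength ``rho`` between an early position pair (source
    in 1..3, target = source + 1, random bijection); the rest are fully
    independent.  Marginals are Dirichlet-perturbed per sample.  Returns
    (sample, tag) pairs with tag in {"dependent", "independent"}.
    """
    if n_samples < 2:
        raise ValueError("corpus needs at least 2 samples")
    rng = np.random.default_rng(seed)
    n_dep = round(frac_dependent * n_samples)
    out = []
    for i in range(n_samples):
        marginals = dirichlet_marginals(l, rng)
        if i < n_dep:
            src = int(rng.integers(1, min(4, l)))
            coupling = Coupling(src, src + 1, rho, random_bijection(rng))
            spec = DependencySpec(marginals, (coupling,))
            tag = "dependent"
        else:
            spec = DependencySpec(marginals)
            tag = "independent"
        sub_seed = int(rng.integers(2**31 - 1))
        out.append(
            (generate_sample(l, n, spec, sub_seed, tf_name=f"synthetic_{i}"), tag)
        )
    return out
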