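"""Non-positive test sequences from shuffled genome fragments.

Models are trained on positive binding sites only, so test-time
negatives are manufactured from the background genome: random fragments
are drawn, each fragment is shuffled character-wise (destroying any
local motif or dinucleotide structure while conserving composition),
sliced into non-overlapping windows of the motif length, and the pooled
windows are subsampled.  These are called *non-positive* rather than
negative because a shuffled window is not certified to miss the motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import sequence_io
from .sequence_io import decode_matrix, read_genome

#: Hard cap on the number of non-positive sequences.
MAX_NONPOSITIVE = 500_000
#: Non-positives per positive sequence below the cap.
NONPOSITIVE_RATIO = 100
#: Default seed for every randomised task in the package.
DEFAULT_SEED = 11


def nonpositive_size(n_positive: int) -> int:
    """Size of the non-positive sample: min(500,000; 100 * n_positive)."""
    return min(MAX_NONPOSITIVE, NONPOSITIVE_RATIO * n_positive)


@dataclass(frozen=True)
class NonPositiveSample:
    sequences: tuple[str, ...]
    source_genome_id: str
    seed: int

    @property
    def size(self) -> int:
        return len(self.sequences)

    @property
    def l(self) -> int:  # noqa: E743
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        return sequence_io.encode_sequences(self.sequences)


def generate_nonpositive(
    genome,
    l: int,  # noqa: E741
    n_positive: int,
    n_fragments: int = 16_000,
    fragment_len: int = 1_000,
    seed: int = DEFAULT_SEED,
    genome_id: str = "",
) -> NonPositiveSample:
    """Build a non-positive sample of min(500,000; 100 * n_positive) windows.

    ``genome`` may be a sequence string, a list of record strings, or a
    FASTA path; fragments never span record boundaries.  Fragments
    containing non-ACGT characters are redrawn, up to a 10x oversampling
    budget.  Deterministic given ``seed``.
    """
    if isinstance(genome, str) and ("/" in genome or genome.lower().endswith((".fa", ".fasta", ".fna"))):
        records = read_genome(genome)
        genome_id = genome_id or str(genome)
    elif isinstance(genome, str):
        records = [genome.upper()]
    else:
        records = [str(r).upper() for r in genome]
    if l > fragment_len:
        raise ValueError(f"motif length {l} exceeds fragment length {fragment_len}")
    starts_per_record = [len(r) - fragment_len + 1 for r in records]
    if max(starts_per_record, default=0) < 1:
        raise ValueError(
            f"no genome record is at least fragment_len={fragment_len} nt long"
        )
    usable = [(rec, ns) for rec, ns in zip(records, starts_per_record) if ns >= 1]
    offsets = np.cumsum([0] + [ns for _, ns in usable])
    total_starts = int(offsets[-1])

    rng = np.random.default_rng(seed)
    lut = sequence_io._LUT
    windows_per_fragment = fragment_len // l
    fragments = np.empty((n_fragments, fragment_len), dtype=np.uint8)
    drawn = 0
    attempts = 0
    max_attempts = 10 * n_fragments
    while drawn < n_fragments:
        if attempts >= max_attempts:
            raise ValueError(
                "could not draw enough ACGT-only fragments within the "
                "10x oversampling budget"
            )
        attempts += 1
        g = int(rng.integers(total_starts))
        rec_idx = int(np.searchsorted(offsets, g, side="right")) - 1
        start = g - int(offsets[rec_idx])
        frag = usable[rec_idx][0][start : start + fragment_len]
        codes = lut[np.frombuffer(frag.encode("ascii"), dtype=np.uint8)]
        if np.any(codes == 255):
            continue
        fragments[drawn] = codes
        drawn += 1

    shuffled = rng.permuted(fragments, axis=1)
    pool = shuffled[:, : windows_per_fragment * l].reshape(-1, l)
    pool = pool[rng.permutation(len(pool))]
    size = nonpositive_size(n_positive)
    if len(pool) < size:
        warnings.warn(
            f"window pool ({len(pool)}) smaller than requested non-positive "
            f"size ({size}); returning the whole pool",
            stacklevel=2,
        )
        size = len(pool)
    return NonPositiveSample(
        sequences=tuple(decode_matrix(pool[:size])),
        source_genome_id=genome_id or "inline",
        seed=seed,
    )
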