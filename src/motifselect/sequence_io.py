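"""Reading, writing and validating TFBS samples and background genomes.

Binding-site samples are collections of equal-length DNA sequences over
{A, C, G, T}.  Two FASTA dialects are supported: ``plain`` (the record
sequence *is* the site) and ``jaspar`` (the site is the single contiguous
uppercase run embedded in lowercase flanking sequence).  Sequences are
stored uppercase internally; case is purely a dialect concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_VALID = frozenset(ALPHABET)

# uint8 lookup table: ASCII byte -> nucleotide code, 255 for invalid
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


class SampleError(ValueError):
    """Base class for malformed TFBS samples."""


class LengthMismatchError(SampleError):
    pass


class AlphabetError(SampleError):
    pass


class DialectError(SampleError):
    pass


class EmptySampleError(SampleError):
    pass


@dataclass(frozen=True)
class TFBSSample:
    """A fixed-length sample of binding-site sequences.

    ``n`` (sample size) and ``l`` (motif length) are derived from
    ``sequences`` and validated on construction.
    """

    sequences: tuple[str, ...]
    tf_name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise EmptySampleError("a TFBS sample must contain at least one sequence")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        l = len(self.sequences[0])
        for idx, s in enumerate(self.sequences):
            if len(s) != l:
                raise LengthMismatchError(
                    f"sequence {idx} has length {len(s)}, expected {l}"
                )
            bad = set(s) - _VALID
            if bad:
                raise AlphabetError(
                    f"sequence {idx} contains non-ACGT characters: {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def l(self) -> int:  # noqa: E743 - domain name for motif length
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Encode as an (n, l) uint8 matrix with A,C,G,T -> 0,1,2,3."""
        return encode_sequences(self.sequences)

    def subset(self, indices) -> "TFBSSample":
        return TFBSSample(
            tuple(self.sequences[i] for i in indices),
            tf_name=self.tf_name,
            source=self.source,
        )


@dataclass(frozen=True)
class NullModel:
    """Background nucleotide distribution q used in log-odds denominators."""

    q: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.q) != _VALID:
            raise ValueError(f"null model must have exactly the keys {ALPHABET}")
        vals = np.array([self.q[c] for c in ALPHABET], dtype=float)
        if np.any(vals <= 0):
            raise ValueError("null model probabilities must be strictly positive")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"null model probabilities sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        """Probabilities in A,C,G,T order."""
        return np.array([self.q[c] for c in ALPHABET], dtype=float)


def encode_sequences(sequences) -> np.ndarray:
    """Encode equal-length DNA strings as an (n, l) uint8 code matrix."""
    raw = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    mat = _LUT[raw].reshape(len(sequences), -1)
    if np.any(mat == 255):
        raise AlphabetError("non-ACGT character in sequence batch")
    return mat


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    letters = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return [bytes(letters[row]).decode("ascii") for row in np.asarray(mat, dtype=np.intp)]


_UPPER_RUN = re.compile(r"[A-Z]+")


def _trim_jaspar(seq: str, record_id: str, keep_longest_run: bool) -> str:
    runs = _UPPER_RUN.findall(seq)
    if not runs:
        raise DialectError(f"record {record_id!r} has no uppercase run")
    if len(runs) > 1:
        if not keep_longest_run:
            raise DialectError(
                f"record {record_id!r} has {len(runs)} disjoint uppercase runs; "
                "pass keep_longest_run=True to keep the longest"
            )
        runs.sort(key=len, reverse=True)
    return runs[0]


def read_fasta_sample(
    path,
    dialect: str = "plain",
    keep_longest_run: bool = False,
    tf_name: str = "",
    source: str = "",
) -> TFBSSample:
    """Read a TFBS sample from FASTA.

    Parameters
    ----------
    dialect
        ``"plain"``: each record sequence is a complete site.
        ``"jaspar"``: the site is the single contiguous uppercase run;
        lowercase flanks are trimmed away.
    keep_longest_run
        In the jaspar dialect, keep the longest uppercase run instead of
        rejecting records with several disjoint runs.
    """
    if dialect not in ("plain", "jaspar"):
        raise ValueError(f"unknown dialect {dialect!r}")
    seqs: list[str] = []
    ids: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        s = str(record.seq)
        if dialect == "jaspar":
            s = _trim_jaspar(s, record.id, keep_longest_run)
        bad = set(s.upper()) - _VALID
        if bad:
            raise AlphabetError(
                f"record {record.id!r} contains non-ACGT characters: {sorted(bad)}"
            )
        seqs.append(s.upper())
        ids.append(record.id)
    if not seqs:
        raise EmptySampleError(f"no FASTA records in {path}")
    l = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != l:
            raise LengthMismatchError(
                f"record {rid!r} has length {len(s)} after processing, expected {l}"
            )
    if not source:
        source = dialect
    return TFBSSample(tuple(seqs), tf_name=tf_name, source=source)


def write_fasta(sample_or_sequences, path, id_prefix: str = "seq") -> None:
    """Write sequences to FASTA, one unwrapped line per record.

    Accepts a :class:`TFBSSample` or any iterable of strings; record order
    is preserved so a read/write round trip is the identity.
    """
    seqs = getattr(sample_or_sequences, "sequences", sample_or_sequences)
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{id_prefix}{i}\n{s}\n")


#: Floor applied to zero background frequencies so log-odds denominators
#: never divide by zero; the vector is renormalised afterwards.
NULL_ZERO_FLOOR = 1e-6


def uniform_null() -> NullModel:
    """The uniform background: q(b) = 1/4 for every nucleotide."""
    return NullModel({c: 0.25 for c in ALPHABET})


def null_from_genome(genome: str) -> NullModel:
    """Background model from mononucleotide frequencies of a genome string.

    Characters outside {A,C,G,T} (either case) are ignored.  A nucleotide
    absent from the genome receives the floor ``NULL_ZERO_FLOOR`` and the
    vector is renormalised, keeping every entry strictly positive.
    """
    raw = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    codes = codes[codes != 255]
    if codes.size == 0:
        raise ValueError("genome contains no usable A/C/G/T characters")
    counts = np.bincount(codes, minlength=4).astype(float)
    freqs = counts / counts.sum()
    freqs[freqs == 0.0] = NULL_ZERO_FLOOR
    freqs /= freqs.sum()
    return NullModel(dict(zip(ALPHABET, freqs)))


def read_genome(path) -> list[str]:
    """Read a (possibly multi-record) genome FASTA as a list of record strings."""
    records = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptySampleError(f"no FASTA records in {path}")
    return records
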