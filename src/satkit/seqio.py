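"""Paired-end FASTQ IO, quality filtering and reproducible read sampling.

The quality filter mirrors Trimmomatic semantics (LEADING / TRAILING /
SLIDINGWINDOW / MINLEN) but keeps only pairs that the trimmer would leave
untouched at full length in both mates: surviving reads therefore have
every nucleotide above the quality criteria, which is the retention rule
the downstream clustering assumes (uniform read length, no clipped ends).
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
_MAX_PHRED33_CHAR = 75  # Q42 in offset-33; higher ordinals indicate offset-64 data


class FastqFormatError(ValueError):
    pass


@dataclass
class ReadPair:
    """One read pair: sequences plus per-base Phred qualities (integers)."""

    id: str
    seq1: str
    seq2: str
    qual1: Sequence[int] = field(default_factory=tuple)
    qual2: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self):
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if qual and len(seq) != len(qual):
                raise FastqFormatError(
                    f"read {self.id}/{mate}: sequence and quality lengths differ")
            if set(seq) - set("ACGTN"):
                raise FastqFormatError(
                    f"read {self.id}/{mate}: alphabet restricted to ACGTN")


@dataclass
class QCParams:
    """Trimmomatic-style quality-filter parameters (Phred scale)."""

    window: int = 4
    min_mean_q: float = 20.0
    min_len: int = 100
    leading_q: int = 3
    trailing_q: int = 3

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < self.window:
            raise ValueError("min_len must be >= window")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_quals(qual_str: str, record_id: str) -> tuple:
    if any(ord(c) > _MAX_PHRED33_CHAR for c in qual_str):
        raise FastqFormatError(
            f"read {record_id}: quality characters above Q42 suggest Phred+64 "
            "encoding; only offset-33 FASTQ is supported")
    if any(ord(c) < PHRED_OFFSET for c in qual_str):
        raise FastqFormatError(f"read {record_id}: invalid quality character")
    return tuple(ord(c) - PHRED_OFFSET for c in qual_str)


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (gzip accepted)."""
    with _open(path1) as h1, _open(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            rid = t1.split()[0]
            rid2 = t2.split()[0]
            base = rid[:-2] if rid.endswith(("/1", "/2")) else rid
            base2 = rid2[:-2] if rid2.endswith(("/1", "/2")) else rid2
            if base != base2:
                raise FastqFormatError(
                    f"unpaired records: {rid!r} vs {rid2!r}")
            yield ReadPair(base, s1.upper(), s2.upper(),
                           _decode_quals(q1, rid), _decode_quals(q2, rid2))


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    with _open(path1, "wt") as h1, _open(path2, "wt") as h2:
        for p in pairs:
            q1 = "".join(chr(q + PHRED_OFFSET) for q in p.qual1)
            q2 = "".join(chr(q + PHRED_OFFSET) for q in p.qual2)
            h1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            h2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


def read_fasta(path) -> dict:
    """Load a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO
    with _open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with _open(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def _survives_unmodified(qual: Sequence[int], params: QCParams) -> bool:
    """Would Trimmomatic leave this read untouched at full length?"""
    n = len(qual)
    if n < params.min_len:
        return False
    if qual[0] < params.leading_q or qual[-1] < params.trailing_q:
        return False
    w = params.window
    if n >= w:
        threshold = params.min_mean_q * w
        running = sum(qual[:w])
        if running < threshold:
            return False
        for i in range(w, n):
            running += qual[i] - qual[i - w]
            if running < threshold:
                return False
    return True


def trim_and_filter_pairs(pairs: Iterable[ReadPair],
                          params: QCParams | None = None) -> Iterator[ReadPair]:
    """Keep only pairs whose two mates pass quality trimming unmodified.

    A pair survives iff leading/trailing base qualities and every sliding
    window of ``params.window`` bases meet the thresholds in both mates,
    i.e. a Trimmomatic run with the same options would remove no bases.
    """
    params = params or QCParams()
    for pair in pairs:
        if (_survives_unmodified(pair.qual1, params)
                and _survives_unmodified(pair.qual2, params)):
            yield pair


def sample_pairs(pairs: Sequence[ReadPair], n: int, seed: int) -> list:
    """Uniform sample of ``n`` pairs without replacement, deterministic per seed."""
    pairs = list(pairs)
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} pairs from a population of {len(pairs)}")
    return random.Random(seed).sample(pairs, n)
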