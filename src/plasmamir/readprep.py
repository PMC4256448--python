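"""Small-RNA read preparation: 3' adapter removal, quality trimming,
19-24 nt length selection and redundancy collapsing.

Single-end, 3'-ligated libraries are assumed: the insert (a ~22 nt mature
miRNA) is followed by the sequencing adapter, so everything from the best
adapter occurrence to the 3' end is removed.  Low-quality 3' tails are
clipped first with the standard running-sum algorithm (default Q20).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "CollapsedRead",
    "quality_trim_index",
    "trim_read",
    "select_and_collapse",
    "read_fastq",
    "trim_fastq",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
]

DEFAULT_MIN_LEN = 19
DEFAULT_MAX_LEN = 24


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with the multiplicity of identical raw reads."""

    sequence: str
    count: int


def _phred(quality: str) -> list[int]:
    return [ord(c) - 33 for c in quality]


def quality_trim_index(quality: str, cutoff: int) -> int:
    """3' cut position under the running-sum (BWA-style) rule.

    Walking from the 3' end, accumulate ``cutoff - q``; the read is cut at
    the position where the partial sum is maximal (and positive).
    """
    qs = _phred(quality)
    best, cum, cut = 0, 0, len(qs)
    for i in range(len(qs) - 1, -1, -1):
        cum += cutoff - qs[i]
        if cum < 0:
            break
        if cum > best:
            best, cut = cum, i
    return cut


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_error_rate: float):
    """Best adapter occurrence: lowest mismatch fraction, then longest
    overlap, then leftmost.  3'-terminal partial overlaps are allowed."""
    best = None  # (rate, -overlap, pos)
    n, m = len(seq), len(adapter)
    for pos in range(n):
        overlap = min(m, n - pos)
        if overlap < min_overlap:
            break
        mm = sum(1 for a, b in zip(seq[pos:pos + overlap], adapter[:overlap]) if a != b)
        rate = mm / overlap
        if rate <= max_error_rate:
            key = (rate, -overlap, pos)
            if best is None or key < best:
                best = key
    return None if best is None else best[2]


def trim_read(
    sequence: str,
    quality: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    quality_cutoff: int = 20,
) -> str:
    """Quality-trim then adapter-trim a single read; may return ''."""
    if len(sequence) != len(quality):
        raise ValueError(
            f"read length {len(sequence)} != quality length {len(quality)}"
        )
    if not adapter:
        raise ValueError("adapter must be non-empty")
    sequence = sequence.strip().upper()
    cut = quality_trim_index(quality, quality_cutoff)
    seq = sequence[:cut]
    pos = _find_adapter(seq, adapter.upper(), min_overlap, max_error_rate)
    return seq if pos is None else seq[:pos]


def select_and_collapse(
    sequences: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Keep min_len..max_len sequences, merge identical ones with summed
    counts, and tally discards.

    Returns reads sorted by (-count, sequence) and the tally
    ``{"too_short", "too_long", "empty_after_trim"}``.  Conservation:
    input size == sum of kept counts + all tally entries.
    """
    counts: dict[str, int] = {}
    tally = {"too_short": 0, "too_long": 0, "empty_after_trim": 0}
    for seq in sequences:
        n = len(seq)
        if n == 0:
            tally["empty_after_trim"] += 1
        elif n < min_len:
            tally["too_short"] += 1
        elif n > max_len:
            tally["too_long"] += 1
        else:
            counts[seq] = counts.get(seq, 0) + 1
    reads = [CollapsedRead(s, c) for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.sequence))
    return reads, tally


# ---------------------------------------------------------------------------
# IO


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """(id, sequence, quality) triples from a plain or gzipped FASTQ."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq), qual


def trim_fastq(
    path,
    adapter: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    quality_cutoff: int = 20,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Full per-library preparation: trim every read, select and collapse."""
    trimmed = (
        trim_read(seq, qual, adapter, min_overlap, max_error_rate, quality_cutoff)
        for _, seq, qual in read_fastq(path)
    )
    return select_and_collapse(trimmed, min_len, max_len)


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path) -> None:
    """Collapsed-FASTA dialect: headers ``>r<i>_<count>``."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">r{i}_{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    reads = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line
            else:
                count = int(header.rsplit("_", 1)[1])
                reads.append(CollapsedRead(line.upper().replace("T", "U"), count))
                header = None
    return reads
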