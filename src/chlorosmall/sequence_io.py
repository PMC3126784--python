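"""Small-RNA library I/O: FASTQ reading, 3' adapter trimming, read collapsing.

Raw libraries arrive as 36-cycle single-end FASTQ with the 3' sequencing
adapter read through for inserts shorter than the cycle length.  Analysis
operates on *collapsed* reads: unique insert sequences with per-library
abundance counts, restricted to the 9-36 nt window in which exact genomic
placement is meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "RawRead",
    "CollapsedRead",
    "Library",
    "FastqParseError",
    "CollapsedFastaError",
    "read_fastq",
    "trim_adapter",
    "collapse_reads",
    "write_collapsed",
    "read_collapsed",
    "MIN_LEN",
    "MAX_LEN",
]

MIN_LEN = 9
MAX_LEN = 36


class FastqParseError(ValueError):
    """Malformed FASTQ record; message carries the 1-based line number."""


class CollapsedFastaError(ValueError):
    """Collapsed-FASTA header does not follow the ``>seq{i}_x{count}`` dialect."""


@dataclass(frozen=True)
class RawRead:
    """One sequencer read: identifier, base sequence, optional quality string."""

    identifier: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.identifier!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class CollapsedRead:
    """A unique insert sequence with abundance counts keyed by library id."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class Library:
    """Bookkeeping for one sequencing library.

    ``total_reads`` is the pre-filter depth (every raw read, including those
    dropped for length, Ns, or missing adapter) and is the denominator used
    for reads-per-million normalization downstream.
    """

    library_id: str
    total_reads: int
    passed_reads: int = 0
    dropped_no_adapter: int = 0
    dropped_length: int = 0
    dropped_n: int = 0


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Yield :class:`RawRead` from a 4-line-record FASTQ file, in file order.

    N-containing sequences are retained here; they are filtered at the
    collapsing stage so that library depth still counts them.

    Raises :class:`FastqParseError` naming the offending line for truncated
    records, bad headers, or quality/sequence length mismatches.
    """
    path = Path(path)
    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}:{lineno}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(
                    f"{path}:{lineno}: truncated record for {header[:30]!r}"
                )
            lineno += 3
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"{path}:{lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield RawRead(header[1:].split()[0], seq.upper(), qual)


def trim_adapter(
    sequence: str, adapter: str, min_overlap: int = 5
) -> Optional[str]:
    """Return the insert 5' of the leftmost adapter occurrence, or ``None``.

    Evidence for the adapter is either a full exact occurrence anywhere in
    the read, or a prefix of the adapter (length >= ``min_overlap``) sitting
    at the very 3' end of the read.  The leftmost such occurrence wins, and
    trimming is repeated until the insert carries no residual evidence (a
    cut can expose a new terminal adapter prefix), so re-trimming an insert
    never removes anything further.  ``None`` means no adapter evidence was
    found in the first place, or the trimmed insert is empty; the caller
    decides whether untrimmed reads are kept.
    """
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require 1 <= min_overlap <= len(adapter)")

    def cut_at(seq: str) -> int:
        pos = seq.find(adapter)
        if pos != -1:
            return pos
        limit = min(len(adapter) - 1, len(seq))
        for k in range(limit, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                return len(seq) - k
        return -1

    pos = cut_at(sequence)
    if pos == -1:
        return None
    insert = sequence[:pos]
    while insert:
        pos = cut_at(insert)
        if pos == -1:
            break
        insert = insert[:pos]
    return insert or None


def collapse_reads(
    sequences: Iterable[Optional[str]],
    library_id: str,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[dict[str, CollapsedRead], Library]:
    """Collapse adapter-free sequences into unique reads with counts.

    ``sequences`` may contain ``None`` entries (reads with no detected
    adapter); they count toward library depth but never toward a collapsed
    read.  Sequences outside ``[min_len, max_len]`` or containing non-ACGT
    characters are likewise dropped but depth-counted, so that
    ``sum(counts) + dropped == total_reads`` always holds.
    """
    collapsed: dict[str, CollapsedRead] = {}
    lib = Library(library_id=library_id, total_reads=0)
    valid = re.compile(r"^[ACGT]+$")
    for seq in sequences:
        lib.total_reads += 1
        if seq is None:
            lib.dropped_no_adapter += 1
            continue
        if not min_len <= len(seq) <= max_len:
            lib.dropped_length += 1
            continue
        if not valid.match(seq):
            lib.dropped_n += 1
            continue
        lib.passed_reads += 1
        rec = collapsed.get(seq)
        if rec is None:
            rec = collapsed[seq] = CollapsedRead(seq, {library_id: 0})
        rec.counts[library_id] = rec.counts.get(library_id, 0) + 1
    return collapsed, lib


_HEADER_RE = re.compile(r"^>(\S+)_x(\d+)$")


def write_collapsed(
    collapsed: dict[str, CollapsedRead], path: str | Path, library_id: str | None = None
) -> None:
    """Write collapsed reads as FASTA with ``>seq{i}_x{count}`` headers.

    Records are sorted by descending count then sequence, which keeps output
    deterministic across input orderings.  With multiple libraries present,
    ``library_id`` selects which count to export (default: total).
    """
    def key(rec: CollapsedRead) -> int:
        if library_id is not None:
            return rec.counts.get(library_id, 0)
        return rec.total()

    ordered = sorted(collapsed.values(), key=lambda r: (-key(r), r.sequence))
    with Path(path).open("w") as fh:
        for i, rec in enumerate(ordered, start=1):
            fh.write(f">seq{i}_x{key(rec)}\n{rec.sequence}\n")


def read_collapsed(
    path: str | Path, library_id: str = "lib"
) -> dict[str, CollapsedRead]:
    """Read a collapsed FASTA file written by :func:`write_collapsed`.

    Counts are filed under ``library_id``.  A header without the ``_x{count}``
    suffix raises :class:`CollapsedFastaError`.
    """
    collapsed: dict[str, CollapsedRead] = {}
    header: Optional[str] = None
    count = 0
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(seq_parts)
        if not seq:
            raise CollapsedFastaError(f"{path}: record {header!r} has no sequence")
        rec = collapsed.get(seq)
        if rec is None:
            collapsed[seq] = CollapsedRead(seq, {library_id: count})
        else:
            rec.counts[library_id] = rec.counts.get(library_id, 0) + count

    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                m = _HEADER_RE.match(line)
                if m is None:
                    raise CollapsedFastaError(
                        f"{path}: header {line!r} does not match '>name_x<count>'"
                    )
                header, count = m.group(1), int(m.group(2))
                seq_parts = []
            else:
                seq_parts.append(line.upper())
        flush()
    return collapsed
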