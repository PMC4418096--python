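"""Small-RNA read handling: FASTA/FASTQ I/O, adapter trimming, length
filtering, read collapsing and size distributions.

Sequences are canonicalized to the DNA alphabet internally (U -> T);
writers can emit RNA on request.  A :class:`ReadLibrary` holds either raw
reads (one record per sequenced read) or collapsed reads (unique sequence
plus count); ``total_reads`` always refers to the underlying read count,
so collapsing conserves totals.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

VALID_BASES = set("ACGTUN")
STAGE_LABELS = ("LM", "LF", "PM", "PF", "AM", "AF")


class ParseError(ValueError):
    """Malformed sequence file; carries the index of the offending record."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


def canonical(seq: str) -> str:
    """Uppercase and canonicalize to DNA (U -> T); validates the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad or not s:
        raise ValueError(f"invalid sequence {seq!r}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class RawRead:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        self.sequence = canonical(self.sequence)
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"quality length mismatch for {self.read_id}")


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", canonical(self.sequence))
        if self.count < 0:
            raise ValueError("negative count")


@dataclass
class ReadLibrary:
    stage_label: str
    reads: list = field(default_factory=list)

    @property
    def collapsed(self) -> bool:
        return bool(self.reads) and isinstance(self.reads[0], CollapsedRead)

    @property
    def total_reads(self) -> int:
        if self.collapsed:
            return sum(r.count for r in self.reads)
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# --------------------------------------------------------------------------
# parsing / writing
# --------------------------------------------------------------------------

def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fasta(handle) -> Iterator[tuple[str, str]]:
    name, chunks, idx = None, [], -1
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                yield name, "".join(chunks)
            name, chunks = line[1:].split()[0] if line[1:] else "", []
            idx += 1
        else:
            if name is None:
                raise ParseError("sequence before first FASTA header", 0)
            chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def _iter_fastq(handle) -> Iterator[tuple[str, str, str]]:
    idx = 0
    while True:
        head = handle.readline()
        if not head:
            return
        head = head.rstrip("\n")
        if not head:
            continue
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not head.startswith("@"):
            raise ParseError("expected '@' header", idx)
        if not plus.startswith("+") or not qual or not seq:
            raise ParseError("truncated FASTQ record", idx)
        if len(qual) != len(seq):
            raise ParseError("quality/sequence length mismatch", idx)
        yield head[1:].split()[0], seq, qual
        idx += 1


def read_sequences(path, fmt: str | None = None, stage_label: str = "") -> ReadLibrary:
    """Read a FASTA or FASTQ file (gzip-transparent) into a ReadLibrary.

    Collapsed-style FASTA headers of the form ``name;count=N`` are restored
    as :class:`CollapsedRead` entries, which makes write/read a faithful
    round trip for collapsed libraries.
    """
    path = Path(path)
    if fmt is None:
        suffixes = path.name.lower()
        if any(s in suffixes for s in (".fastq", ".fq")):
            fmt = "fastq"
        elif any(s in suffixes for s in (".fasta", ".fa", ".fna")):
            fmt = "fasta"
        else:
            raise ValueError(f"cannot infer format of {path.name}; pass fmt=")
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    lib = ReadLibrary(stage_label=stage_label or path.stem)
    with _open(path) as fh:
        if fmt == "fasta":
            records = list(_iter_fasta(fh))
            if records and all(";count=" in n for n, _ in records):
                for name, seq in records:
                    lib.reads.append(
                        CollapsedRead(seq, int(name.rsplit(";count=", 1)[1])))
            else:
                for i, (name, seq) in enumerate(records):
                    try:
                        lib.reads.append(RawRead(name, seq))
                    except ValueError as exc:
                        raise ParseError(str(exc), i) from None
        else:
            for i, (name, seq, qual) in enumerate(_iter_fastq(fh)):
                try:
                    lib.reads.append(RawRead(name, seq, qual))
                except ValueError as exc:
                    raise ParseError(str(exc), i) from None
    return lib


def write_sequences(lib: ReadLibrary, path, fmt: str | None = None,
                    rna: bool = False) -> None:
    """Write a library as FASTA (collapsed or raw) or FASTQ (raw only)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if ".fastq" in path.name or ".fq" in path.name else "fasta"
    conv = to_rna if rna else (lambda s: s)
    with _open(path, "wt") as fh:
        if fmt == "fasta":
            if lib.collapsed:
                for r in lib.reads:
                    fh.write(f">{r.sequence};count={r.count}\n{conv(r.sequence)}\n")
            else:
                for r in lib.reads:
                    fh.write(f">{r.read_id}\n{conv(r.sequence)}\n")
        elif fmt == "fastq":
            for r in lib.reads:
                if isinstance(r, CollapsedRead):
                    raise ValueError("cannot write collapsed reads as FASTQ")
                q = r.quality or "I" * len(r.sequence)
                fh.write(f"@{r.read_id}\n{conv(r.sequence)}\n+\n{q}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 5,
                 max_mismatch_rate: float = 0.1) -> RawRead:
    """Remove the 3' adapter from one read.

    The longest 3'-terminal suffix of the read matching a prefix of the
    adapter (overlap >= ``min_overlap``, mismatch fraction <=
    ``max_mismatch_rate``) is removed; the quality string is trimmed in
    step.  A read with no qualifying match is returned unchanged; a read
    that is adapter from its first base (empty insert) returns ``None``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ad = canonical(adapter)
    seq = read.sequence
    n = len(seq)
    for start in range(0, n - min_overlap + 1):  # longest suffix first
        ov = min(n - start, len(ad))
        mism = sum(1 for a, b in zip(seq[start:start + ov], ad[:ov]) if a != b)
        if mism <= max_mismatch_rate * ov:
            if start == 0:
                return None
            return RawRead(read.read_id, seq[:start],
                           read.quality[:start] if read.quality else None)
    return read


def filter_by_length(lib: ReadLibrary, min_len: int = 18, max_len: int = 30) -> ReadLibrary:
    """Keep reads with min_len <= length <= max_len (inclusive window)."""
    if min_len > max_len:
        raise ValueError(f"inverted length bounds [{min_len}, {max_len}]")
    keep = [r for r in lib.reads if min_len <= len(r.sequence) <= max_len]
    return ReadLibrary(stage_label=lib.stage_label, reads=keep)


def collapse(lib: ReadLibrary) -> list[CollapsedRead]:
    """Collapse to unique sequences; counts sum to the input read total."""
    counts: Counter = Counter()
    if lib.collapsed:
        for r in lib.reads:
            counts[r.sequence] += r.count
    else:
        for r in lib.reads:
            counts[r.sequence] += 1
    return [CollapsedRead(s, c) for s, c in sorted(counts.items())]


def collapsed_library(lib: ReadLibrary) -> ReadLibrary:
    return ReadLibrary(stage_label=lib.stage_label, reads=collapse(lib))


def size_histogram(lib: ReadLibrary) -> Counter:
    """Read count per sequence length; missing lengths read as 0."""
    hist: Counter = Counter()
    if lib.collapsed:
        for r in lib.reads:
            hist[len(r.sequence)] += r.count
    else:
        for r in lib.reads:
            hist[len(r.sequence)] += 1
    return hist
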