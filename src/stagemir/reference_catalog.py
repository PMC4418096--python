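"""Reference catalogs and hierarchical zero-mismatch read assignment.

Reads are assigned to the first catalog they match in a fixed priority
order (known miRNA, then ncRNA, then CDS, then genome), mirroring the
disjoint per-class accounting of a small-RNA profiling run.  Matching is
exact (zero mismatches): a hash/substring index replaces an external
zero-mismatch aligner, which is equivalent for this purpose.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .io_small_rna import CollapsedRead, canonical, _iter_fasta, _open

log = logging.getLogger(__name__)

CATALOG_CLASSES = ("known_mirna", "ncrna", "cds", "genome")
UNASSIGNED = "unassigned"

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SequenceCatalog:
    catalog_class: str
    entries: dict[str, str] = field(default_factory=dict)
    source_species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.catalog_class not in CATALOG_CLASSES:
            raise ValueError(f"unknown catalog class {self.catalog_class!r}")
        self.entries = {n: canonical(s) for n, s in self.entries.items()}

    @classmethod
    def from_fasta(cls, path, catalog_class: str) -> "SequenceCatalog":
        entries = {}
        with _open(Path(path)) as fh:
            for name, seq in _iter_fasta(fh):
                if name in entries:
                    raise ValueError(f"duplicate catalog name {name!r}")
                entries[name] = seq
        return cls(catalog_class, entries)

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class AssignmentResult:
    sequence: str
    assigned_class: str
    feature_name: str | None

    def __post_init__(self):
        if (self.feature_name is None) != (self.assigned_class == UNASSIGNED):
            raise ValueError("feature_name present iff assigned")


@dataclass
class CountTable:
    """Feature x stage integer counts plus per-stage library totals."""
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    library_totals: dict[str, int] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return sorted(self.counts)

    @property
    def stages(self) -> list[str]:
        return sorted(self.library_totals)

    def get(self, feature: str, stage: str) -> int:
        return self.counts.get(feature, {}).get(stage, 0)

    def set(self, feature: str, stage: str, value: int) -> None:
        if value < 0:
            raise ValueError("negative count")
        self.counts.setdefault(feature, {})[stage] = value

    def to_tsv(self, path) -> None:
        stages = self.stages
        with open(path, "w") as fh:
            fh.write("feature\t" + "\t".join(stages) + "\n")
            fh.write("__library_total__\t" +
                     "\t".join(str(self.library_totals[s]) for s in stages) + "\n")
            for f in self.features:
                fh.write(f + "\t" + "\t".join(str(self.get(f, s)) for s in stages) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        tab = cls()
        with open(path) as fh:
            stages = fh.readline().rstrip("\n").split("\t")[1:]
            totals = fh.readline().rstrip("\n").split("\t")
            if totals[0] != "__library_total__":
                raise ValueError("missing __library_total__ row")
            tab.library_totals = {s: int(v) for s, v in zip(stages, totals[1:])}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                for s, v in zip(stages, parts[1:]):
                    if int(v):
                        tab.set(parts[0], s, int(v))
        return tab


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

class _MatureIndex:
    """Exact / isomiR matcher against mature miRNA catalogs.

    A read matches a mature if it is identical, a substring of it, or
    contains it with at most ``flank_tolerance`` extra bases in total
    (isomiR ends); zero mismatches in the matched span.
    """

    def __init__(self, catalog: SequenceCatalog, flank_tolerance: int = 3):
        if catalog.catalog_class != "known_mirna":
            raise ValueError("mature index requires a known_mirna catalog")
        self.flank_tolerance = flank_tolerance
        self.exact: dict[str, str] = {}
        for name in sorted(catalog.entries):
            seq = catalog.entries[name]
            self.exact.setdefault(seq, name)
        self._matures = sorted((s, n) for s, n in self.exact.items())

    def match(self, read_seq: str) -> str | None:
        seq = canonical(read_seq)
        if seq in self.exact:
            return self.exact[seq]
        hits = []
        for mat, name in self._matures:
            if len(seq) < len(mat):
                if seq in mat:
                    hits.append(name)
            elif self.flank_tolerance and len(seq) - len(mat) <= self.flank_tolerance:
                if mat in seq:
                    hits.append(name)
        if not hits:
            return None
        if len(hits) > 1:
            log.warning("read matches %d matures; keeping %s", len(hits), min(hits))
        return min(hits)


def match_known_mirna(sequence: str, catalog: SequenceCatalog,
                      flank_tolerance: int = 3) -> str | None:
    """Zero-mismatch mature-miRNA match with isomiR end tolerance."""
    return _MatureIndex(catalog, flank_tolerance).match(sequence)


def dedupe_mature(catalog: SequenceCatalog) -> SequenceCatalog:
    """Merge entries with identical sequences (lexicographically smallest
    name wins), as in collapsing a multi-species mature catalog."""
    if catalog.catalog_class != "known_mirna":
        raise ValueError("dedupe_mature requires a known_mirna catalog")
    by_seq: dict[str, str] = {}
    for name in sorted(catalog.entries):
        by_seq.setdefault(catalog.entries[name], name)
    return SequenceCatalog("known_mirna", {n: s for s, n in by_seq.items()})


class _SubstringIndex:
    """Sense-strand (and optionally both-strand) exact substring lookup."""

    def __init__(self, catalog: SequenceCatalog, both_strands: bool, k: int = 12):
        self.k = k
        self.catalog = catalog
        self.both_strands = both_strands
        self.seeds: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for name in sorted(catalog.entries):
            seq = catalog.entries[name]
            self._index(name, seq, "+")
            if both_strands:
                self._index(name, reverse_complement(seq), "-")

    def _index(self, name: str, seq: str, strand: str):
        for off in range(0, max(1, len(seq) - self.k + 1)):
            self.seeds[seq[off:off + self.k]].append((name, off, strand))
        # keep full sequence for short entries
        if len(seq) < self.k:
            self.seeds[seq].append((name, 0, strand))

    def find(self, read_seq: str):
        """Return (feature, position, strand) of the first exact hit."""
        seq = canonical(read_seq)
        probe = seq[: self.k]
        hits = []
        for name, off, strand in self.seeds.get(probe, ()):  # seed then verify
            ref = self.catalog.entries[name]
            refseq = ref if strand == "+" else reverse_complement(ref)
            if refseq[off:off + len(seq)] == seq:
                pos = off if strand == "+" else len(ref) - off - len(seq)
                hits.append((name, pos, strand))
        if len(seq) < self.k:
            for key, lst in self.seeds.items():
                if seq in key:
                    for name, off, strand in lst:
                        hits.append((name, off, strand))
        if not hits:
            return None
        if len({h[0] for h in hits}) > 1:
            log.warning("read maps to %d features; keeping %s",
                        len({h[0] for h in hits}), min(hits)[0])
        return min(hits)


def assign_hierarchical(reads, catalogs, flank_tolerance: int = 3):
    """Assign each read to the first matching catalog in priority order.

    ``catalogs`` must be ordered (known_mirna, ncrna, cds, genome); any
    subset may be supplied but the relative order is enforced.  Genome
    matching considers both strands; transcript-like catalogs are
    sense-strand only.  Returns one :class:`AssignmentResult` per read,
    in input order.
    """
    order = [c.catalog_class for c in catalogs]
    if order != sorted(order, key=CATALOG_CLASSES.index):
        raise ValueError(f"catalogs out of priority order: {order}")
    indexes = []
    for cat in catalogs:
        if cat.catalog_class == "known_mirna":
            indexes.append(("known_mirna", _MatureIndex(cat, flank_tolerance)))
        else:
            indexes.append((cat.catalog_class,
                            _SubstringIndex(cat, cat.catalog_class == "genome")))
    results = []
    for r in reads:
        seq = r.sequence if isinstance(r, (CollapsedRead,)) or hasattr(r, "sequence") else str(r)
        assigned = AssignmentResult(seq, UNASSIGNED, None)
        for cls, idx in indexes:
            if cls == "known_mirna":
                name = idx.match(seq)
                if name:
                    assigned = AssignmentResult(seq, cls, name)
                    break
            else:
                hit = idx.find(seq)
                if hit:
                    assigned = AssignmentResult(seq, cls, hit[0])
                    break
        results.append(assigned)
    return results


def locate_in_genome(sequence: str, genome: SequenceCatalog):
    """Return (contig, start, end, strand) of an exact genome hit (0-based,
    half-open) or None."""
    idx = _SubstringIndex(genome, both_strands=True)
    hit = idx.find(sequence)
    if hit is None:
        return None
    name, pos, strand = hit
    return name, pos, pos + len(canonical(sequence)), strand


def count_features(assignments, reads, stage: str,
                   table: CountTable | None = None) -> CountTable:
    """Accumulate collapsed counts per assigned feature into one stage
    column; the grand total over classes + unassigned equals the library
    total."""
    if len(assignments) != len(reads):
        raise ValueError("assignments must cover the reads")
    table = table if table is not None else CountTable()
    total = 0
    per_feature: dict[str, int] = defaultdict(int)
    for a, r in zip(assignments, reads):
        n = r.count if isinstance(r, CollapsedRead) else 1
        total += n
        if a.assigned_class == "known_mirna":
            per_feature[a.feature_name] += n
    for f, c in per_feature.items():
        table.set(f, stage, table.get(f, stage) + c)
    table.library_totals[stage] = table.library_totals.get(stage, 0) + total
    return table


def class_totals(assignments, reads) -> dict[str, int]:
    """Read totals per assigned class (the per-library accounting row)."""
    out: dict[str, int] = defaultdict(int)
    for a, r in zip(assignments, reads):
        n = r.count if isinstance(r, CollapsedRead) else 1
        out[a.assigned_class] += n
    return dict(out)
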