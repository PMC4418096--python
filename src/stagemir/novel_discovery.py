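"""Novel miRNA discovery: flank extraction, MFE hairpin folding, topology
and arm classification, naming, and known-miRNA similarity screening.

A candidate locus (a genome-mapped read with no catalog hit) is extended
by 75 nt on each side, folded, and accepted as a novel miRNA when

* the window's minimum free energy is below the threshold (default
  -20 kcal/mol),
* the structure is a single hairpin: exactly one *major* terminal loop,
  where side branches containing at most ``prune`` base pairs are ignored
  as minor decorations, and
* the mature read sits on one arm of that hairpin: at least ``arm_min``
  of its bases 5' (arm 5p) or 3' (arm 3p) of the terminal loop, with at
  most ``offside_max`` bases on the opposite side.

The defaults of this rule were fixed together with the folding model's
loop-penalty calibration (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import folding
from .io_small_rna import canonical, to_rna
from .reference_catalog import SequenceCatalog, reverse_complement

DEFAULT_FLANK = 75
DEFAULT_MFE_MAX = -20.0
DEFAULT_PRUNE = 5
DEFAULT_ARM_MIN = 15
DEFAULT_OFFSIDE_MAX = 4
DEFAULT_KNOWN_DISTANCE = 3


@dataclass(frozen=True)
class GenomeLocus:
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus {self}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class PrecursorCandidate:
    locus: GenomeLocus | None
    precursor_sequence: str  # RNA alphabet
    mature_offset: int
    mature_length: int
    structure: str | None = None
    mfe: float | None = None

    def fold(self):
        self.structure, self.mfe = folding.fold_mfe(self.precursor_sequence)
        return self


@dataclass
class NovelMiRNA:
    name: str
    mature_sequence: str
    precursor: PrecursorCandidate
    arm: str


@dataclass
class HairpinCall:
    passed: bool
    arm: str | None
    reason: str
    mfe: float | None = None
    loop: tuple[int, int] | None = None


def extract_precursor(genome: SequenceCatalog, locus: GenomeLocus,
                      flank: int = DEFAULT_FLANK) -> PrecursorCandidate:
    """Extract the mapped read plus ``flank`` nt on each side (clipped to
    contig bounds; reverse-complemented for the minus strand)."""
    if locus.contig not in genome.entries:
        raise KeyError(f"contig {locus.contig!r} not in genome")
    contig = genome.entries[locus.contig]
    if locus.end > len(contig):
        raise ValueError(f"locus {locus} outside contig of length {len(contig)}")
    lo = max(0, locus.start - flank)
    hi = min(len(contig), locus.end + flank)
    window = contig[lo:hi]
    if locus.strand == "+":
        offset = locus.start - lo
    else:
        window = reverse_complement(window)
        offset = hi - locus.end
    return PrecursorCandidate(locus=locus,
                              precursor_sequence=to_rna(window),
                              mature_offset=offset,
                              mature_length=locus.end - locus.start)


fold_mfe = folding.fold_mfe  # re-export: the folding engine lives in folding.py


def _pair_tree(db: str):
    pairs = folding.dotbracket_to_pairs(db)
    partner = dict(pairs)
    partner.update({j: i for i, j in pairs})

    def children(i, j):
        out, k = [], i + 1
        while k < j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    def roots(n):
        out, k = [], 0
        while k < n:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    return pairs, children, roots


def major_terminal_loops(db: str, prune: int = DEFAULT_PRUNE):
    """Terminal loops of the structure after ignoring side branches that
    contain at most ``prune`` base pairs."""
    pairs, children, roots = _pair_tree(db)
    if not pairs:
        return []

    def subtree_pairs(i, j):
        return 1 + sum(subtree_pairs(a, b) for a, b in children(i, j))

    loops = []

    def walk(i, j):
        ch = [c for c in children(i, j) if subtree_pairs(*c) > prune]
        if not ch:
            loops.append((i, j))
        else:
            for c in ch:
                walk(*c)

    for rt in roots(len(db)):
        if subtree_pairs(*rt) > prune:
            walk(*rt)
    return loops


def classify_hairpin(candidate: PrecursorCandidate,
                     mfe_threshold: float = DEFAULT_MFE_MAX,
                     prune: int = DEFAULT_PRUNE,
                     arm_min: int = DEFAULT_ARM_MIN,
                     offside_max: int = DEFAULT_OFFSIDE_MAX) -> HairpinCall:
    """Decide whether a folded candidate is a credible miRNA hairpin and
    on which arm the mature lies.  Returns a :class:`HairpinCall` with a
    reason code on failure."""
    m0 = candidate.mature_offset
    m1 = m0 + candidate.mature_length
    n = len(candidate.precursor_sequence)
    if not (0 <= m0 < m1 <= n):
        raise ValueError("mature outside precursor")
    if candidate.structure is None or candidate.mfe is None:
        candidate.fold()
    db, mfe = candidate.structure, candidate.mfe
    if mfe >= mfe_threshold:
        return HairpinCall(False, None, "energy", mfe)
    loops = major_terminal_loops(db, prune)
    if len(loops) != 1:
        return HairpinCall(False, None, f"{len(loops)} terminal loops", mfe)
    li, lj = loops[0]
    five = sum(1 for p in range(m0, m1) if p <= li)
    three = sum(1 for p in range(m0, m1) if p >= lj)
    if five >= three:
        arm, on_arm, offside = "5p", five, three
    else:
        arm, on_arm, offside = "3p", three, five
    if offside > offside_max:
        return HairpinCall(False, None, "mature spans the terminal loop", mfe, (li, lj))
    if on_arm < min(arm_min, candidate.mature_length):
        return HairpinCall(False, None, "mature not on an arm", mfe, (li, lj))
    return HairpinCall(True, arm, "ok", mfe, (li, lj))


def check_not_known(mature: str, known: SequenceCatalog,
                    max_distance: int = DEFAULT_KNOWN_DISTANCE) -> str:
    """'known-like' if within ``max_distance`` edits of any known mature
    (exhaustive banded edit distance), else 'novel'."""
    seq = canonical(mature)
    for other in known.entries.values():
        if _edit_distance_atmost(seq, other, max_distance):
            return "known-like"
    return "novel"


def _edit_distance_atmost(a: str, b: str, k: int) -> bool:
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        lo = max(1, i - k - 1)
        for j in range(1, len(b) + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != b[j - 1]))
        if min(cur[lo:]) > k:
            return False
        prev = cur
    return prev[-1] <= k


@dataclass
class _Accepted:
    candidate: PrecursorCandidate
    arm: str
    mature: str


def name_novel(accepted) -> list[NovelMiRNA]:
    """Assign ast-Novel-N-{5p,3p} names.

    ``accepted`` is an iterable of (candidate, arm) or ``_Accepted``;
    precursors are numbered in order of locus coordinate then sequence,
    and two matures from one precursor share N.
    """
    items = []
    for a in accepted:
        if isinstance(a, _Accepted):
            items.append(a)
        else:
            cand, arm = a
            m = cand.precursor_sequence[
                cand.mature_offset:cand.mature_offset + cand.mature_length]
            items.append(_Accepted(cand, arm, m))

    def locus_key(it: _Accepted):
        loc = it.candidate.locus
        if loc is None:
            return ("~", 0, it.candidate.precursor_sequence)
        return (loc.contig, loc.start, it.candidate.precursor_sequence)

    items.sort(key=lambda it: (locus_key(it), it.arm))
    out = []
    number = 0
    seen: dict[str, int] = {}
    for it in items:
        key = it.candidate.precursor_sequence
        if key not in seen:
            number += 1
            seen[key] = number
        out.append(NovelMiRNA(name=f"ast-Novel-{seen[key]}-{it.arm}",
                              mature_sequence=it.mature,
                              precursor=it.candidate,
                              arm=it.arm))
    return out


def discover_novel(read_loci, genome: SequenceCatalog, known: SequenceCatalog | None,
                   flank: int = DEFAULT_FLANK,
                   mfe_threshold: float = DEFAULT_MFE_MAX) -> list[NovelMiRNA]:
    """Full discovery pass: extract, fold, classify and name candidates.

    ``read_loci`` is an iterable of :class:`GenomeLocus` (one per candidate
    read, typically the most abundant unassigned read per locus).
    """
    accepted = []
    for locus in read_loci:
        cand = extract_precursor(genome, locus, flank).fold()
        call = classify_hairpin(cand, mfe_threshold)
        if not call.passed:
            continue
        mature = cand.precursor_sequence[
            cand.mature_offset:cand.mature_offset + cand.mature_length]
        if known is not None and check_not_known(mature, known) == "known-like":
            continue
        accepted.append((cand, call.arm))
    return name_novel(accepted)
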