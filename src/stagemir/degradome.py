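"""Degradome (PARE) analysis: tag mapping, cleavage-site scoring, T-plot
series and the category 0-4 evidence classification.

PARE sequencing captures the 5' ends of uncapped mRNA fragments.
miRNA-guided cleavage leaves a diagnostic 5' end on the transcript
opposite miRNA position 10, so a candidate site is a transcript window
complementary to the miRNA (scored by a penalty scheme) whose predicted
cleavage position carries at least one mapped tag.

Categories rank the cleavage evidence within one transcript profile
(abundances over occupied positions only):

* 0 - the site is the unique maximum and that abundance exceeds one read;
* 1 - the site is a maximum shared with other positions (abundance > 1);
* 2 - above the median but below the maximum;
* 3 - at or below the median;
* 4 - a single raw read at the position.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from .io_small_rna import canonical
from .reference_catalog import SequenceCatalog

TAG_MIN_LEN = 20
TAG_MAX_LEN = 25
DEFAULT_MAX_SCORE = 4.0
CLEAVAGE_MIRNA_POS = 10  # cleavage opposite miRNA position 10 (1-based)
CORE_START, CORE_END = 2, 13  # doubled penalties inside positions 2-13
FORBIDDEN = (10, 11)  # mismatch disallowed at these miRNA positions

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_GU = {("G", "T"), ("T", "G")}  # on DNA alphabet: G:U wobble


@dataclass(frozen=True)
class DegradomeTag:
    sequence: str
    count: int = 1

    def __post_init__(self):
        object.__setattr__(self, "sequence", canonical(self.sequence))
        if not (TAG_MIN_LEN <= len(self.sequence) <= TAG_MAX_LEN):
            raise ValueError(
                f"degradome tag length {len(self.sequence)} outside "
                f"[{TAG_MIN_LEN}, {TAG_MAX_LEN}]")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class TranscriptProfile:
    transcript_id: str
    transcript_length: int
    abundance: dict[int, int] = field(default_factory=dict)  # 1-based pos -> count
    multimapped: bool = False

    def add(self, position: int, count: int) -> None:
        if not (1 <= position <= self.transcript_length):
            raise ValueError(f"position {position} outside transcript")
        self.abundance[position] = self.abundance.get(position, 0) + count

    @property
    def total(self) -> int:
        return sum(self.abundance.values())


@dataclass
class CleavageCall:
    mirna: str
    transcript_id: str
    cleavage_position: int  # 1-based
    alignment_score: float
    category: int | None = None


def map_tags(tags, transcripts: SequenceCatalog) -> dict[str, TranscriptProfile]:
    """Exact-match tags to transcripts; each tag's count is added at the
    1-based position of its 5' end, on every transcript that contains it
    (multi-transcript matches are flagged)."""
    profiles: dict[str, TranscriptProfile] = {}
    items = sorted(transcripts.entries.items())
    for tag in tags:
        seq = tag.sequence
        matched = []
        for tid, tseq in items:
            start = 0
            positions = []
            while True:
                idx = tseq.find(seq, start)
                if idx < 0:
                    break
                positions.append(idx + 1)
                start = idx + 1
            if positions:
                matched.append((tid, positions))
        for tid, positions in matched:
            prof = profiles.get(tid)
            if prof is None:
                prof = profiles[tid] = TranscriptProfile(
                    tid, len(transcripts.entries[tid]))
            for pos in positions:
                prof.add(pos, tag.count)
            if len(matched) > 1:
                prof.multimapped = True
    return profiles


def score_site(mirna: str, transcript_window: str) -> float:
    """Penalty score of a miRNA against a transcript window of equal
    length (window 5'->3'; pairing is antiparallel, so miRNA position 1
    faces the window's 3' end).

    Mismatch +1, G:U +0.5, doubled at miRNA positions 2-13; any mismatch
    at positions 10-11 rejects the site (infinite penalty).
    """
    mi = canonical(mirna)
    win = canonical(transcript_window)
    if len(win) != len(mi):
        raise ValueError("window length must equal miRNA length")
    score = 0.0
    for k, base in enumerate(mi):  # k = 0-based miRNA position
        pos = k + 1
        t = win[len(win) - 1 - k]
        if _WC[base] == t:
            continue
        gu = (base.replace("U", "T"), t) in _GU
        pen = 0.5 if gu else 1.0
        if CORE_START <= pos <= CORE_END:
            pen *= 2.0
        if pos in FORBIDDEN and not gu:
            return math.inf
        score += pen
    return score


def cleavage_position_for_window(window_start_1based: int, mirna_len: int) -> int:
    """Transcript position paired with miRNA position 10 for a window
    starting at the given 1-based position."""
    return window_start_1based + mirna_len - CLEAVAGE_MIRNA_POS


def find_cleavage_sites(mirna_name: str, mirna_seq: str, transcript_seq: str,
                        profile: TranscriptProfile,
                        max_score: float = DEFAULT_MAX_SCORE) -> list[CleavageCall]:
    """Scan every window of the transcript; emit a call for windows with
    score <= max_score whose predicted cleavage position carries degradome
    evidence (abundance >= 1)."""
    mi = canonical(mirna_seq)
    tseq = canonical(transcript_seq)
    n, m = len(tseq), len(mi)
    calls = []
    for start in range(0, n - m + 1):  # 0-based window start
        cleave = cleavage_position_for_window(start + 1, m)
        if profile.abundance.get(cleave, 0) < 1:
            continue
        s = score_site(mi, tseq[start:start + m])
        if s <= max_score:
            calls.append(CleavageCall(mirna_name, profile.transcript_id,
                                      cleave, s))
    # one call per cleavage position: keep the best-scoring window
    best: dict[int, CleavageCall] = {}
    for c in calls:
        if c.cleavage_position not in best or \
                c.alignment_score < best[c.cleavage_position].alignment_score:
            best[c.cleavage_position] = c
    return [best[k] for k in sorted(best)]


def classify_category(profile: TranscriptProfile, position: int) -> int:
    """Category 0-4 of the evidence at one occupied position (see module
    docstring for the rules; median over occupied positions only, even
    cardinality as the mean of the central pair)."""
    a = profile.abundance.get(position, 0)
    if a < 1:
        raise ValueError(f"no degradome evidence at position {position}")
    if a == 1:
        return 4
    occ = sorted(profile.abundance.values())
    mx = occ[-1]
    mid = len(occ) // 2
    med = float(occ[mid]) if len(occ) % 2 else (occ[mid - 1] + occ[mid]) / 2.0
    if a == mx:
        return 0 if occ.count(mx) == 1 else 1
    if a > med:
        return 2
    return 3


def tplot_data(profile: TranscriptProfile, calls=()):
    """Full-length (position, abundance, is_call) series for plotting."""
    flagged = {c.cleavage_position for c in calls}
    return [(pos, profile.abundance.get(pos, 0), pos in flagged)
            for pos in range(1, profile.transcript_length + 1)]


def categorize_calls(profiles: dict[str, TranscriptProfile], calls) -> None:
    for c in calls:
        c.category = classify_category(profiles[c.transcript_id],
                                       c.cleavage_position)


def analyze_condition(mirnas: dict[str, str], transcripts: SequenceCatalog,
                      tags, max_score: float = DEFAULT_MAX_SCORE):
    """Map one condition's tags and call categorized cleavage sites for
    each miRNA; returns (profiles, calls)."""
    profiles = map_tags(tags, transcripts)
    calls = []
    for name in sorted(mirnas):
        for tid in sorted(profiles):
            cs = find_cleavage_sites(name, mirnas[name],
                                     transcripts.entries[tid],
                                     profiles[tid], max_score)
            calls.extend(cs)
    categorize_calls(profiles, calls)
    return profiles, calls


def compare_conditions(calls_per_condition: dict[str, list[CleavageCall]],
                       condition_order=("PBS", "SCR", "ANTIMIR")):
    """Per-target category table across conditions.

    Returns rows ``{mirna, transcript_id, categories: {condition: cat or
    None}, representative}``; the representative category is the first
    condition's (PBS by convention), falling back to the first condition
    in which the target was called.
    """
    targets = {}
    for cond in condition_order:
        for c in calls_per_condition.get(cond, ()):  # keep best category/call
            key = (c.mirna, c.transcript_id)
            row = targets.setdefault(
                key, {"mirna": c.mirna, "transcript_id": c.transcript_id,
                      "categories": {k: None for k in condition_order}})
            prev = row["categories"][cond]
            if prev is None or c.category < prev:
                row["categories"][cond] = c.category
    rows = []
    for key in sorted(targets):
        row = targets[key]
        rep = None
        for cond in condition_order:
            if row["categories"][cond] is not None:
                rep = row["categories"][cond]
                break
        row["representative"] = rep
        rows.append(row)
    return rows


def category_tally(rows, condition: str | None = None) -> dict[int, int]:
    """Count targets per category, using the representative category or a
    named condition's column."""
    tally: dict[int, int] = defaultdict(int)
    for row in rows:
        cat = row["representative"] if condition is None \
            else row["categories"].get(condition)
        if cat is not None:
            tally[cat] += 1
    return dict(tally)
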