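"""Seeded synthetic genomes, stage libraries and degradome tag sets with
known ground truth.

The generator emulates the structure of a developmental small-RNA
profiling experiment in a holometabolous insect:

* an AT-rich genome (A+T ~ 56%, as in anopheline genomes) carrying known
  miRNA genes and planted novel hairpin loci;
* six stage libraries (LM, LF, PM, PF, AM, AF) whose reads are Poisson
  draws around per-stage expected TPM values, with a bimodal length
  profile: miRNA reads at 20-23 nt plus a piRNA-like background at
  32-35 nt, and the 3' sequencing adapter still attached;
* degradome tag sets per injection condition (PBS, SCR, ANTIMIR) whose
  5'-end profiles realize prescribed evidence categories at planted
  cleavage positions.

Planted novel loci are drawn by rejection sampling: a locus (perfect stem
with a few G:U wobbles, short loop, genomic flanks) is redrawn until the
extraction window around the mature folds into a single major hairpin
clearing the MFE acceptance threshold, so the ground truth is a set of
loci that are true hairpins by construction.  Libraries are generated in
collapsed form (unique sequence + count); FASTQ materialization expands
duplicates only on request.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from . import novel_discovery
from .degradome import DegradomeTag, TranscriptProfile, classify_category
from .io_small_rna import CollapsedRead, ReadLibrary, STAGE_LABELS
from .novel_discovery import GenomeLocus, PrecursorCandidate, classify_hairpin
from .reference_catalog import SequenceCatalog, reverse_complement

_BASES = "ACGT"
_AT_WEIGHTS = (0.28, 0.22, 0.22, 0.28)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
READ_LENGTH = 50


class ConfigurationError(ValueError):
    pass


@dataclass
class DegradomeSpec:
    mirna: str
    transcript: str
    position: int  # 1-based planted cleavage position
    target_category: int
    background_sites: int = 3
    suppressed_by_antagomir: bool = False


@dataclass
class SimulationConfig:
    seed: int = 7
    n_contigs: int = 2
    contig_length: int = 10_000
    n_known_mirnas: int = 30
    n_novel_loci: int = 5
    novel_stem_pairs: int = 22
    novel_loop_len: int = 8
    read_depth: int = 1_000_000
    pirna_fraction: float = 0.30
    n_pirna_species: int = 400
    adapter: str = DEFAULT_ADAPTER
    n_de_mirnas: int = 5
    de_fold_change: float = 8.0
    de_up_stage: str = "AF"
    base_tpm: float = 15_000.0
    de_base_tpm: float = 1_500.0
    novel_tpm: float = 60.0
    stage_abundance: dict = field(default_factory=dict)  # stage -> {mirna: TPM}
    degradome: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.pirna_fraction <= 1.0):
            raise ConfigurationError("pirna_fraction must be in [0, 1]")
        if self.novel_stem_pairs < 15:
            raise ConfigurationError(
                "novel_stem_pairs < 15 cannot guarantee hairpins below the "
                "MFE acceptance threshold")


@dataclass
class GroundTruth:
    known_matures: dict[str, str] = field(default_factory=dict)
    novel_loci: list = field(default_factory=list)  # (name, GenomeLocus, arm, mature)
    expected_tpm: dict = field(default_factory=dict)  # stage -> {name: TPM}
    true_counts: dict = field(default_factory=dict)  # stage -> {name: count}
    de_mirnas: list = field(default_factory=list)
    degradome_calls: list = field(default_factory=list)  # (mirna, transcript, pos, cat)


def _rand_seq(rng: random.Random, n: int, weights=_AT_WEIGHTS) -> str:
    return "".join(rng.choices(_BASES, weights=weights, k=n))


def _wobbled_arm(mature: str, rng: random.Random, n_wobble: int = 3) -> str:
    """Reverse complement of the mature with a few C->T substitutions
    (G:U wobbles in the fold) so the arm is not an exact reverse
    complement and the mature maps uniquely."""
    arm = list(reverse_complement(mature))
    cs = [i for i, b in enumerate(arm) if b == "C" and 2 < i < len(arm) - 3]
    rng.shuffle(cs)
    for i in cs[:n_wobble]:
        arm[i] = "T"
    return "".join(arm)


def simulate_genome(config: SimulationConfig):
    """Build the genome with embedded known-miRNA genes and novel hairpin
    loci.  Returns (genome_catalog, locus_list, GroundTruth)."""
    rng = random.Random(config.seed)
    truth = GroundTruth()
    contigs = {f"contig{i+1}": list(_rand_seq(rng, config.contig_length))
               for i in range(config.n_contigs)}
    names = sorted(contigs)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def place(segment: str, min_margin: int = 120, pad: int = 80) -> tuple[str, int]:
        """Overwrite a random stretch, never overlapping (or folding-range
        adjacent to) a previously placed feature."""
        for _ in range(500):
            contig = names[rng.randrange(len(names))]
            arr = contigs[contig]
            pos = rng.randrange(min_margin, len(arr) - min_margin - len(segment))
            lo, hi = pos - pad, pos + len(segment) + pad
            if any(lo < e and s < hi for s, e in occupied[contig]):
                continue
            arr[pos:pos + len(segment)] = list(segment)
            occupied[contig].append((pos, pos + len(segment)))
            return contig, pos
        raise ConfigurationError("genome too small for requested features")

    # known miRNA genes
    for i in range(config.n_known_mirnas):
        length = rng.choice((20, 21, 22, 23))
        mature = _rand_seq(rng, length, weights=(0.25, 0.25, 0.25, 0.25))
        name = f"ast-sim-miR-{i+1}"
        truth.known_matures[name] = mature
        place(mature)

    # novel hairpin loci by rejection sampling
    loci = []
    for i in range(config.n_novel_loci):
        arm = "5p" if i % 2 == 0 else "3p"
        for attempt in range(200):
            mature = _rand_seq(rng, config.novel_stem_pairs,
                               weights=(0.2, 0.3, 0.3, 0.2))
            if mature.count("G") < 3:
                continue
            other = _wobbled_arm(mature, rng)
            loop = _rand_seq(rng, config.novel_loop_len)
            hairpin = (mature + loop + other) if arm == "5p" else \
                      (other + loop + mature)
            flank5 = _rand_seq(rng, 75)
            flank3 = _rand_seq(rng, 75)
            segment = flank5 + hairpin + flank3
            m0 = segment.find(mature)
            # validate on the exact extraction window (mature +- 75)
            lo = max(0, m0 - 75)
            hi = min(len(segment), m0 + len(mature) + 75)
            window = segment[lo:hi]
            cand = PrecursorCandidate(None, window.replace("T", "U"),
                                      m0 - lo, len(mature)).fold()
            call = classify_hairpin(cand)
            if not (call.passed and call.arm == arm):
                continue
            # hairpin alone must clear the threshold (config feasibility)
            solo = PrecursorCandidate(None, hairpin.replace("T", "U"),
                                      0, len(mature)).fold()
            if solo.mfe >= novel_discovery.DEFAULT_MFE_MAX:
                raise ConfigurationError(
                    f"designed stem of {config.novel_stem_pairs} bp folds at "
                    f"{solo.mfe:.1f} kcal/mol, above the acceptance threshold")
            contig, pos = place(segment)
            start = pos + m0
            locus = GenomeLocus(contig, start, start + len(mature), "+")
            name = f"sim-novel-{i+1}"
            truth.novel_loci.append((name, locus, arm, mature))
            loci.append(locus)
            break
        else:
            raise ConfigurationError("could not plant a qualifying hairpin locus")

    genome = SequenceCatalog(
        "genome", {n: "".join(arr) for n, arr in contigs.items()})
    return genome, loci, truth


def default_stage_abundance(config: SimulationConfig,
                            truth: GroundTruth) -> dict:
    """Per-stage expected TPM: flat for null miRNAs, a de_fold_change step
    in de_up_stage for the first n_de_mirnas, and a low flat level for
    planted novel matures."""
    if config.de_up_stage not in STAGE_LABELS:
        raise ConfigurationError(f"unknown stage {config.de_up_stage!r}")
    known = sorted(truth.known_matures)
    de = known[: config.n_de_mirnas]
    abundance = {}
    budget = (1.0 - config.pirna_fraction) * 1e6  # small-RNA TPM budget
    for stage in STAGE_LABELS:
        tab = {}
        for name in known:
            if name in de:
                tab[name] = config.de_base_tpm * (
                    config.de_fold_change if stage == config.de_up_stage else 1.0)
            else:
                tab[name] = config.base_tpm
        for (nname, _loc, _arm, _mat) in truth.novel_loci:
            tab[nname] = config.novel_tpm
        # normalize so the stage's miRNA mass fills the non-piRNA budget;
        # TPM is compositional, so up-regulation slightly deflates the rest
        scale = budget / sum(tab.values()) if tab else 0.0
        abundance[stage] = {k: v * scale for k, v in tab.items()}
    truth.de_mirnas = de
    return abundance


def simulate_stage_libraries(config: SimulationConfig, genome, truth: GroundTruth):
    """Draw the six stage libraries in collapsed form (adapter attached).

    Returns ``{stage: ReadLibrary}``; fills ``truth.true_counts`` and
    ``truth.expected_tpm``.
    """
    abundance = config.stage_abundance or default_stage_abundance(config, truth)
    truth.expected_tpm = abundance
    nrng = np.random.default_rng(config.seed + 1)
    rng = random.Random(config.seed + 2)

    seqs = dict(truth.known_matures)
    seqs.update({n: m for (n, _l, _a, m) in truth.novel_loci})

    pirna_species = [_rand_seq(rng, rng.choice((32, 33, 34, 35)))
                     for _ in range(config.n_pirna_species)]

    libs = {}
    for stage in STAGE_LABELS:
        reads = {}
        truth.true_counts.setdefault(stage, {})
        for name, tpm in sorted(abundance[stage].items()):
            lam = tpm * config.read_depth / 1e6
            c = int(nrng.poisson(lam)) if lam > 0 else 0
            truth.true_counts[stage][name] = c
            if c > 0:
                seq = (seqs[name] + config.adapter)[:READ_LENGTH]
                reads[seq] = reads.get(seq, 0) + c
        n_pirna = int(nrng.poisson(config.pirna_fraction * config.read_depth))
        if n_pirna > 0 and pirna_species:
            counts = nrng.multinomial(n_pirna,
                                      [1 / len(pirna_species)] * len(pirna_species))
            for s, c in zip(pirna_species, counts):
                if c > 0:
                    seq = (s + config.adapter)[:READ_LENGTH]
                    reads[seq] = reads.get(seq, 0) + int(c)
        libs[stage] = ReadLibrary(
            stage_label=stage,
            reads=[CollapsedRead(s, c) for s, c in sorted(reads.items())])
    return libs


# --------------------------------------------------------------------------
# degradome
# --------------------------------------------------------------------------

def default_degradome_specs(mirna_names) -> list[DegradomeSpec]:
    names = sorted(mirna_names)
    cats = [0, 1, 2, 3, 4]
    specs = []
    for i, cat in enumerate(cats):
        specs.append(DegradomeSpec(
            mirna=names[i % len(names)],
            transcript=f"tx{i+1}",
            position=400 + 137 * i,
            target_category=cat,
            suppressed_by_antagomir=(i % 2 == 0)))
    return specs


def _category_profile(cat: int, rng: random.Random):
    """(site_count, background_counts) realizing a category by the formal
    rules (backgrounds at other positions of the same transcript)."""
    if cat == 0:
        return 5, [1, 1, 2]
    if cat == 1:
        return 3, [3, 1]
    if cat == 2:
        return 2, [5, 1, 1]
    if cat == 3:
        return 2, [5, 4, 2]
    if cat == 4:
        return 1, [3, 2]
    raise ConfigurationError(f"unknown category {cat}")


def simulate_degradome(config: SimulationConfig, mirnas: dict[str, str],
                       specs: list[DegradomeSpec] | None = None,
                       transcript_length: int = 1200):
    """Build transcripts and per-condition tag sets realizing the
    requested categories.  Returns (transcripts, {condition: [tags]},
    GroundTruth-style call list)."""
    rng = random.Random(config.seed + 3)
    specs = specs if specs is not None else default_degradome_specs(mirnas)
    for s in specs:
        if s.mirna not in mirnas:
            raise ConfigurationError(f"unknown miRNA {s.mirna!r} in degradome spec")
        if s.target_category == 1 and s.background_sites < 1:
            raise ConfigurationError(
                "category 1 requires at least one shared-maximum background site")

    transcripts = {}
    for s in specs:
        if s.transcript not in transcripts:
            transcripts[s.transcript] = list(_rand_seq(rng, transcript_length))
        tseq = transcripts[s.transcript]
        m = mirnas[s.mirna]
        # complementary window placed so cleavage falls at s.position
        w0 = s.position - 1 - (len(m) - 10)  # 0-based window start
        if w0 < 0 or w0 + len(m) > len(tseq):
            raise ConfigurationError(
                f"planted position {s.position} infeasible for transcript "
                f"length {transcript_length}")
        tseq[w0:w0 + len(m)] = list(reverse_complement(m))

    transcripts = {k: "".join(v) for k, v in transcripts.items()}
    tx = SequenceCatalog("cds", transcripts)

    conditions = {"PBS": [], "SCR": [], "ANTIMIR": []}
    calls = []
    for s in specs:
        tseq = transcripts[s.transcript]
        site_count, bg_counts = _category_profile(s.target_category, rng)
        positions = {s.position: site_count}
        taken = {s.position}
        for c in bg_counts:
            for _ in range(100):
                p = rng.randrange(1, len(tseq) - 30)
                if all(abs(p - q) > 25 for q in taken):
                    taken.add(p)
                    positions[p] = c
                    break
        # sanity: the realized profile must classify as requested
        prof = TranscriptProfile(s.transcript, len(tseq),
                                 abundance=dict(positions))
        got = classify_category(prof, s.position)
        if got != s.target_category:
            raise ConfigurationError(
                f"background spec realizes category {got}, wanted "
                f"{s.target_category}")
        for pos, count in sorted(positions.items()):
            tag = tseq[pos - 1: pos - 1 + 20]
            for cond in conditions:
                if (cond == "ANTIMIR" and s.suppressed_by_antagomir
                        and pos == s.position):
                    continue
                conditions[cond].append(DegradomeTag(tag, count))
        calls.append((s.mirna, s.transcript, s.position, s.target_category,
                      s.suppressed_by_antagomir))
    return tx, conditions, calls
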