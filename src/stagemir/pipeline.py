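"""Pipeline orchestration and the curated reference tables.

The fixtures shipped under ``stagemir/fixtures`` are curated
transcriptions of the published stage-profiling tables: the 111-miRNA
six-stage TPM table with its detection mask, the 14 novel mature /
precursor records, and the 29 degradome targets with per-condition
categories.  Cells whose column placement could not be recovered
unambiguously from the source layout carry a curation flag
(``inferred`` / ``layout`` / ``bd`` in the mask) and the loader validates
the tables' structural invariants before use.

Reporting functions compute every summary through the ordinary
expression_de / degradome operations so fixture numbers and synthetic
runs go through identical code paths.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import expression_de as de
from . import degradome as deg
from .expression_de import TPMMatrix
from .io_small_rna import (CollapsedRead, ReadLibrary, STAGE_LABELS, collapse,
                           filter_by_length, trim_adapter, RawRead)

STAGES = list(STAGE_LABELS)


class FixtureIntegrityError(ValueError):
    pass


@dataclass
class FixtureTables:
    table2: TPMMatrix
    table2_meta: dict
    table3: list
    table5: list

    def validate(self):
        if len(self.table2.names) != 111:
            raise FixtureIntegrityError(
                f"stage TPM table has {len(self.table2.names)} rows, expected 111")
        if len(self.table3) != 14:
            raise FixtureIntegrityError(
                f"novel-miRNA table has {len(self.table3)} rows, expected 14")
        if len(self.table5) != 29:
            raise FixtureIntegrityError(
                f"degradome table has {len(self.table5)} rows, expected 29")
        for row in self.table3:
            mat = row["mature"].replace("T", "U")
            if mat not in row["precursor"]:
                raise FixtureIntegrityError(
                    f"{row['name']}: mature not in precursor")
        for row in self.table5:
            if all(row[c] is None for c in
                   ("pbs_category", "scr_category", "antimir_category")):
                raise FixtureIntegrityError(
                    f"{row['target']}: no condition category")
        return self


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("stagemir.fixtures") / name))


def load_fixtures(path: str | Path | None = None) -> FixtureTables:
    """Load and validate the shipped (or an alternative) fixture set."""
    base = Path(path) if path is not None else _fixture_path("")
    t2 = TPMMatrix()
    meta = {}
    with open(base / "table2_stage_tpm.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        stages = header[4:10]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            name = parts[1]
            mask = parts[10]
            meta[name] = dict(sno=int(parts[0]), length=int(parts[2]),
                              sequence=parts[3], curation=parts[11], mask=mask)
            for s, val, m in zip(stages, parts[4:10], mask):
                tpm = float(val) if val else 0.0
                t2.set(name, s, tpm, m == "d")
    t2.stages = stages

    t3 = []
    with open(base / "table3_novel_mirnas.tsv") as fh:
        header = fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            t3.append(dict(sno=int(p[0]), name=p[1], length=int(p[2]),
                           mature=p[3], precursor=p[4], mature_offset=int(p[5]),
                           published_arm=p[6],
                           tpm_values=[float(v) for v in p[7].split(";") if v],
                           note=p[8]))

    t5 = []
    with open(base / "table5_degradome_targets.tsv") as fh:
        header = fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            t5.append(dict(sno=int(p[0]), mirna=p[1], target=p[2],
                           pbs_category=int(p[3]) if p[3] else None,
                           scr_category=int(p[4]) if p[4] else None,
                           antimir_category=int(p[5]) if p[5] else None,
                           rnahybrid_predicted=bool(int(p[6])), go_term=p[7],
                           cleavage_position=p[8], ortholog=p[9], curation=p[10]))
    return FixtureTables(t2, meta, t3, t5).validate()


def write_table5(rows, path) -> None:
    """Writer matching the shipped table 5 format byte for byte."""
    with open(path, "w") as fh:
        fh.write("sno\tmirna\ttarget\tpbs_category\tscr_category\t"
                 "antimir_category\trnahybrid_predicted\tgo_term\t"
                 "cleavage_position\tortholog\tcuration\n")
        for r in rows:
            cats = ["" if r[c] is None else str(r[c]) for c in
                    ("pbs_category", "scr_category", "antimir_category")]
            fh.write(f"{r['sno']}\t{r['mirna']}\t{r['target']}\t{cats[0]}\t"
                     f"{cats[1]}\t{cats[2]}\t{int(r['rnahybrid_predicted'])}\t"
                     f"{r['go_term']}\t{r['cleavage_position']}\t"
                     f"{r['ortholog']}\t{r['curation']}\n")


def table5_condition_rows(table5):
    """Shape the fixture rows like degradome.compare_conditions output so
    the same tallies apply."""
    rows = []
    for r in table5:
        cats = {"PBS": r["pbs_category"], "SCR": r["scr_category"],
                "ANTIMIR": r["antimir_category"]}
        rep = next((cats[c] for c in ("PBS", "SCR", "ANTIMIR")
                    if cats[c] is not None), None)
        rows.append({"mirna": r["mirna"], "transcript_id": r["target"],
                     "categories": cats, "representative": rep})
    return rows


def fixture_reports(tables: FixtureTables) -> dict:
    """Repertoire and degradome summaries, all computed by the module
    operations (no special-cased counting)."""
    t2 = tables.table2
    rows5 = table5_condition_rows(tables.table5)
    per_mirna = Counter(r["mirna"] for r in rows5)
    return {
        "known_mirnas_total": len(t2.names),
        "detected_per_stage": de.detected_per_stage(t2),
        "expressed_in_all_stages": len(de.expressed_in_all_stages(t2)),
        "absent_in_some_stage": len(de.absent_in_some_stage(t2)),
        "absent_both_larvae_tpm10": sorted(
            de.absent_in_stages_expressed_elsewhere(t2, ["LM", "LF"])),
        "absent_only_LF": sorted(de.absent_only_in(t2, "LF")),
        "novel_matures": len(tables.table3),
        "novel_5p": sum(1 for r in tables.table3 if r["published_arm"] == "5p"),
        "degradome_targets_total": len(rows5),
        "degradome_targets_per_mirna": dict(per_mirna),
        "degradome_category_tally": deg.category_tally(rows5),
    }


# --------------------------------------------------------------------------
# stage runners (library API behind the CLI)
# --------------------------------------------------------------------------

def trim_library(lib: ReadLibrary, adapter: str, min_overlap: int = 5,
                 max_mismatch_rate: float = 0.1) -> ReadLibrary:
    """Adapter-trim a raw or collapsed library; fully-adapter reads drop."""
    out = []
    if lib.collapsed:
        merged: Counter = Counter()
        for r in lib.reads:
            t = trim_adapter(RawRead("r", r.sequence), adapter,
                             min_overlap, max_mismatch_rate)
            if t is not None:
                merged[t.sequence] += r.count
        out = [CollapsedRead(s, c) for s, c in sorted(merged.items())]
    else:
        for r in lib.reads:
            t = trim_adapter(r, adapter, min_overlap, max_mismatch_rate)
            if t is not None:
                out.append(t)
    return ReadLibrary(stage_label=lib.stage_label, reads=out)


def run_profile(libraries: dict, catalogs: list, min_len: int = 18,
                max_len: int = 30, adapter: str | None = None):
    """Trim (optionally), length-filter, collapse and hierarchically
    assign every stage library; returns (CountTable, per-stage class
    totals, per-stage assignments)."""
    from .reference_catalog import CountTable, assign_hierarchical, \
        class_totals, count_features

    table = CountTable()
    totals = {}
    assignments = {}
    for stage in libraries:
        lib = libraries[stage]
        if adapter:
            lib = trim_library(lib, adapter)
        lib = filter_by_length(lib, min_len, max_len)
        reads = collapse(lib)
        asg = assign_hierarchical(reads, catalogs)
        count_features(asg, reads, stage, table)
        totals[stage] = class_totals(asg, reads)
        assignments[stage] = (reads, asg)
    return table, totals, assignments


def novel_candidate_loci(assignments, genome):
    """Most-abundant unassigned read per genome locus, as candidate novel
    loci (merged across stages)."""
    from .reference_catalog import locate_in_genome
    from .novel_discovery import GenomeLocus

    pooled: Counter = Counter()
    for stage, (reads, asg) in assignments.items():
        for r, a in zip(reads, asg):
            if a.assigned_class == "genome":
                pooled[r.sequence] += r.count
    by_locus = {}
    for seq, count in pooled.items():
        hit = locate_in_genome(seq, genome)
        if hit is None:
            continue
        contig, start, end, strand = hit
        key = (contig, start // 50)
        if key not in by_locus or count > by_locus[key][0]:
            by_locus[key] = (count, GenomeLocus(contig, start, end, strand))
    return [loc for _c, loc in sorted(by_locus.values(),
                                      key=lambda t: (t[1].contig, t[1].start))]


def run_de(counts, contrasts, fc: float = 2.0, p: float = 0.05,
           tpm: float = 10.0):
    mat = de.compute_tpm(counts)
    results = de.run_contrasts(mat, counts, contrasts, fc, p, tpm)
    return mat, results, de.contrast_summary(results)


def run_manifest(path, **kwargs) -> None:
    """Write a key=value manifest sufficient to reproduce a stage run."""
    with open(path, "w") as fh:
        for k in sorted(kwargs):
            fh.write(f"{k}={json.dumps(kwargs[k], sort_keys=True, default=str)}\n")
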