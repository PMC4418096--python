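"""TPM normalization, two-library exact count testing, and the
three-criterion regulation filter.

Libraries here are pooled biological material without replicates, so the
between-stage test is a conditional binomial exact test: conditional on
the summed count of a miRNA in the two libraries, its count in library A
is Binomial(n, total_A / (total_A + total_B)) under the null of equal
relative abundance.  The two-sided p-value sums all outcomes whose
probability does not exceed that of the observed one.  This is a defined,
replicate-free substitute for a dispersion-based count model, not a
reproduction of one.

A miRNA counts as regulated between two stages when all three criteria
hold: fold change > 2 (either direction, pseudocounted TPM ratio),
p <= 0.05, and TPM > 10 in at least one of the two stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_FC = 2.0
DEFAULT_P = 0.05
DEFAULT_TPM = 10.0
PSEUDOCOUNT_TPM = 0.1


@dataclass
class TPMMatrix:
    """Tags-per-million per miRNA and stage, with a detection mask.

    ``values[name][stage]`` is count / library_total * 1e6; ``detected``
    marks cells with a positive underlying count (a value can be present
    but flagged not-detected when loaded from a curated table).
    """
    values: dict[str, dict[str, float]] = field(default_factory=dict)
    detected: dict[str, dict[str, bool]] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)

    def get(self, name: str, stage: str) -> float:
        return self.values.get(name, {}).get(stage, 0.0)

    def is_detected(self, name: str, stage: str) -> bool:
        return self.detected.get(name, {}).get(stage, False)

    def set(self, name: str, stage: str, tpm: float, detected: bool) -> None:
        self.values.setdefault(name, {})[stage] = tpm
        self.detected.setdefault(name, {})[stage] = detected
        if stage not in self.stages:
            self.stages.append(stage)

    @property
    def names(self) -> list[str]:
        return sorted(self.values)


@dataclass(frozen=True)
class Contrast:
    stage_a: str
    stage_b: str  # fold change is b over a

    def __post_init__(self):
        if self.stage_a == self.stage_b:
            raise ValueError("contrast of a stage with itself")


@dataclass
class DEResult:
    mirna: str
    fold_change: float
    p_value: float
    max_tpm: float
    passes: bool
    direction: str  # 'up' means higher in stage_b


def compute_tpm(counts) -> TPMMatrix:
    """Normalize a CountTable to tags per million of total library reads."""
    tpm = TPMMatrix()
    for stage in counts.stages:
        total = counts.library_totals.get(stage, 0)
        if total <= 0:
            raise ValueError(f"library total for {stage} must be positive")
    for name in counts.features:
        for stage in counts.stages:
            c = counts.get(name, stage)
            tpm.set(name, stage, c / counts.library_totals[stage] * 1e6, c > 0)
    tpm.stages = list(counts.stages)
    return tpm


def exact_count_test(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided conditional binomial test of equal relative abundance.

    Conditions on n = count_a + count_b with success probability
    total_a / (total_a + total_b); sums the probabilities of all outcomes
    no more likely than the observed count_a.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a < 0 or count_b < 0 or count_a > total_a or count_b > total_b:
        raise ValueError("counts must lie in [0, total]")
    n = count_a + count_b
    if n == 0:
        return 1.0
    p = total_a / (total_a + total_b)
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    obs = pmf[count_a]
    # tolerance handles ties under floating point, matching the exact rule
    pval = float(pmf[pmf <= obs * (1.0 + 1e-10)].sum())
    return min(1.0, pval)


def de_filter(fold_change: float, p_value: float, max_tpm: float,
              fc_threshold: float = DEFAULT_FC,
              p_threshold: float = DEFAULT_P,
              tpm_threshold: float = DEFAULT_TPM,
              mirna: str = "") -> DEResult:
    """Apply the three-criterion filter; fold-change thresholds are strict
    (> fc or < 1/fc), the p criterion inclusive (<=)."""
    if not all(np.isfinite([fold_change, p_value, max_tpm])):
        raise ValueError("non-finite inputs to de_filter")
    direction = "up" if fold_change >= 1.0 else "down"
    fc_ok = fold_change > fc_threshold or fold_change < 1.0 / fc_threshold
    passes = bool(fc_ok and p_value <= p_threshold and max_tpm > tpm_threshold)
    return DEResult(mirna, fold_change, p_value, max_tpm, passes, direction)


def fold_change_tpm(tpm_a: float, tpm_b: float,
                    pseudocount: float = PSEUDOCOUNT_TPM) -> float:
    """Pseudocounted TPM ratio, stage_b over stage_a."""
    return (tpm_b + pseudocount) / (tpm_a + pseudocount)


def run_contrasts(tpm: TPMMatrix, counts, contrasts,
                  fc_threshold: float = DEFAULT_FC,
                  p_threshold: float = DEFAULT_P,
                  tpm_threshold: float = DEFAULT_TPM):
    """Test every miRNA in every contrast.

    Returns ``{(stage_a, stage_b): [DEResult, ...]}`` sorted by miRNA.
    """
    out = {}
    for con in contrasts:
        a, b = con.stage_a, con.stage_b
        for stage in (a, b):
            if stage not in counts.library_totals:
                raise ValueError(f"unknown stage label {stage!r}")
        res = []
        for name in counts.features:
            ca, cb = counts.get(name, a), counts.get(name, b)
            pv = exact_count_test(ca, counts.library_totals[a],
                                  cb, counts.library_totals[b])
            fc = fold_change_tpm(tpm.get(name, a), tpm.get(name, b))
            mx = max(tpm.get(name, a), tpm.get(name, b))
            res.append(de_filter(fc, pv, mx, fc_threshold, p_threshold,
                                 tpm_threshold, mirna=name))
        out[(a, b)] = res
    return out


def contrast_summary(results) -> dict:
    """Up/down counts per contrast from run_contrasts output."""
    summary = {}
    for key, res in results.items():
        up = sum(1 for r in res if r.passes and r.direction == "up")
        down = sum(1 for r in res if r.passes and r.direction == "down")
        summary[key] = {"up": up, "down": down, "tested": len(res)}
    return summary


# --------------------------------------------------------------------------
# repertoire summaries (used for curated-table reporting)
# --------------------------------------------------------------------------

def detected_per_stage(tpm: TPMMatrix) -> dict[str, int]:
    return {s: sum(1 for n in tpm.names if tpm.is_detected(n, s))
            for s in tpm.stages}


def expressed_in_all_stages(tpm: TPMMatrix) -> list[str]:
    return [n for n in tpm.names
            if all(tpm.is_detected(n, s) for s in tpm.stages)]


def absent_in_some_stage(tpm: TPMMatrix) -> list[str]:
    return [n for n in tpm.names
            if not all(tpm.is_detected(n, s) for s in tpm.stages)]


def absent_in_stages_expressed_elsewhere(tpm: TPMMatrix, absent_stages,
                                         tpm_threshold: float = DEFAULT_TPM):
    """miRNAs not detected in all of ``absent_stages`` yet exceeding the
    TPM threshold in at least one other stage."""
    absent_stages = list(absent_stages)
    out = []
    for n in tpm.names:
        if any(tpm.is_detected(n, s) for s in absent_stages):
            continue
        others = [s for s in tpm.stages if s not in absent_stages]
        if max((tpm.get(n, s) for s in others if tpm.is_detected(n, s)),
               default=0.0) > tpm_threshold:
            out.append(n)
    return out


def absent_only_in(tpm: TPMMatrix, stage: str) -> list[str]:
    """miRNAs whose only undetected stage is ``stage``."""
    out = []
    for n in tpm.names:
        missing = [s for s in tpm.stages if not tpm.is_detected(n, s)]
        if missing == [stage]:
            out.append(n)
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Optional FDR adjustment (off by default in the filter)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out
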