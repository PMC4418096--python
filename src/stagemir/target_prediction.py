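"""miRNA target prediction on 3'UTRs.

A candidate site requires perfect Watson-Crick complementarity of the
miRNA seed (positions 2-8, a 7-mer) to the UTR; the duplex energy of a
window centred on the seed match is then computed with the intermolecular
dynamic program shared with the folding model, and significance is
assessed against dinucleotide-preserving shuffles of the UTR (an
empirical permutation p-value with the +1 correction, in place of an
extreme-value fit).  A reported target satisfies all three criteria:
perfect seed, p below threshold, duplex energy below threshold.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass

from .folding import duplex_energy
from .io_small_rna import canonical, to_rna

SEED_START = 1  # 0-based: miRNA positions 2..8
SEED_END = 8
DEFAULT_WINDOW = 40
DEFAULT_SHUFFLES = 99
DEFAULT_P = 0.05
DEFAULT_ENERGY = -20.0

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    utr_sequence: str  # stored canonical DNA, 5'->3'

    def __post_init__(self):
        object.__setattr__(self, "utr_sequence", canonical(self.utr_sequence))


@dataclass
class DuplexHit:
    mirna: str
    gene_id: str
    site_start: int  # 1-based UTR position of the seed-pairing window
    duplex_energy: float
    p_value: float


def _seed_rc(mirna_seq: str) -> str:
    """Reverse complement of the miRNA seed: the UTR motif to search."""
    seed = canonical(mirna_seq)[SEED_START:SEED_END]
    return "".join(_WC[c] for c in reversed(seed))


def find_seed_sites(mirna_seq: str, utr: UTRRecord) -> list[int]:
    """1-based UTR start positions of exact seed-complementary 7-mers
    (Watson-Crick only, no G:U)."""
    if len(canonical(mirna_seq)) < SEED_END:
        raise ValueError("miRNA shorter than the seed span")
    motif = _seed_rc(mirna_seq)
    seq = utr.utr_sequence
    sites, start = [], 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return sites
        sites.append(idx + 1)
        start = idx + 1


def site_window(utr: UTRRecord, site_start: int,
                window: int = DEFAULT_WINDOW) -> str:
    """Window of ``window`` nt centred on the seed match (clipped)."""
    seq = utr.utr_sequence
    centre = site_start - 1 + (SEED_END - SEED_START) // 2
    lo = max(0, centre - window // 2)
    return seq[lo:lo + window]


def site_energy(mirna_seq: str, utr: UTRRecord, site_start: int,
                window: int = DEFAULT_WINDOW) -> float:
    return duplex_energy(to_rna(canonical(mirna_seq)),
                         to_rna(site_window(utr, site_start, window)))


def best_site_energy(mirna_seq: str, utr: UTRRecord,
                     window: int = DEFAULT_WINDOW,
                     require_seed: bool = False) -> float:
    """Best (lowest) duplex energy over the UTR.

    With ``require_seed`` only seed-matched windows are scanned (0.0 when
    there is no seed site); otherwise the whole UTR is scanned in one
    intermolecular pass, which is the statistic used for the shuffle null.
    """
    if require_seed:
        sites = find_seed_sites(mirna_seq, utr)
        if not sites:
            return 0.0
        return min(site_energy(mirna_seq, utr, s, window) for s in sites)
    return duplex_energy(to_rna(canonical(mirna_seq)), to_rna(utr.utr_sequence))


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Altschul-Erickson dinucleotide-preserving shuffle.

    Builds the multigraph of dinucleotide transitions, samples a random
    Eulerian arrangement by the last-edge trick, and walks it.
    """
    s = canonical(seq)
    if len(s) < 2:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = sorted(edges)
    for _ in range(200):  # sample last edges until connected (a.s. quickly)
        lasts = {}
        for v in vertices:
            if v == last and not edges[v]:
                continue
            lasts[v] = rng.choice(edges[v])
        # check: every vertex with edges must reach `last` via last-edges
        ok = True
        for v in lasts:
            seen, cur = set(), v
            while cur != last and cur in lasts and cur not in seen:
                seen.add(cur)
                cur = lasts[cur]
            if cur != last and lasts:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - fallback, still a valid sequence
        return s
    pools = {}
    for v in vertices:
        rest = list(edges[v])
        if v in lasts:
            rest.remove(lasts[v])
        rng.shuffle(rest)
        if v in lasts:
            rest.append(lasts[v])
        pools[v] = rest
    out = [first]
    cur = first
    while any(pools.get(v) for v in pools):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def site_pvalue(observed_energy: float, mirna_seq: str, utr: UTRRecord,
                n_shuffles: int = DEFAULT_SHUFFLES, seed: int = 0,
                window: int = DEFAULT_WINDOW) -> float:
    """Empirical p-value of a site energy against dinucleotide shuffles.

    p = (1 + #{shuffles with best energy <= observed}) / (n_shuffles + 1).
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    if len(utr.utr_sequence) < 20:
        raise ValueError("UTR too short to shuffle (< 20 nt)")
    rng = random.Random(seed)
    hits = 0
    for _ in range(n_shuffles):
        shuf = UTRRecord(utr.gene_id, dinucleotide_shuffle(utr.utr_sequence, rng))
        if best_site_energy(mirna_seq, shuf, window) <= observed_energy:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)


def predict_targets(mirnas: dict[str, str], utrs, p_threshold: float = DEFAULT_P,
                    energy_threshold: float = DEFAULT_ENERGY,
                    n_shuffles: int = DEFAULT_SHUFFLES, seed: int = 0,
                    window: int = DEFAULT_WINDOW) -> list[DuplexHit]:
    """Predict targets for each miRNA over a UTR collection.

    For every UTR with at least one perfect seed site, the best site
    energy is evaluated; sites passing the energy threshold are assigned
    a shuffle p-value.  Hits satisfying all three criteria are returned
    sorted by (miRNA, energy).
    """
    hits = []
    for name in sorted(mirnas):
        mseq = mirnas[name]
        for utr in utrs:
            sites = find_seed_sites(mseq, utr)
            if not sites:
                continue
            energies = [(site_energy(mseq, utr, s, window), s) for s in sites]
            e, s = min(energies)
            if e >= energy_threshold:
                continue
            pv = site_pvalue(e, mseq, utr, n_shuffles,
                             seed=seed ^ zlib.crc32(f"{name}:{utr.gene_id}".encode()),
                             window=window)
            if pv < p_threshold:
                hits.append(DuplexHit(name, utr.gene_id, s, e, pv))
    hits.sort(key=lambda h: (h.mirna, h.duplex_energy, h.gene_id))
    return hits
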