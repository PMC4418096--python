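"""Minimum-free-energy RNA secondary structure and duplex hybridization.

The folding model is a compact nearest-neighbor model: Watson-Crick and G:U
wobble pairs, stacking energies for adjacent pairs, and size-dependent
initiation penalties for hairpin, bulge, internal and multibranch loops.
No pseudoknots, no dangling-end or terminal-mismatch terms.  The stacking
table follows the classic Turner-style values; the loop initiation tables
are scaled by a single calibration constant (``LOOP_SCALE``) chosen so that
the hairpin acceptance threshold of -20 kcal/mol used throughout the
pipeline behaves sensibly on AU-rich mosquito precursors (see
docs/methods.md for the calibration rationale).

Two independent search routines are provided:

* :func:`fold_mfe` — Zuker-style dynamic program over one strand.
* :func:`duplex_energy` — intermolecular-only dynamic program (two strands,
  intramolecular pairs forbidden), used for miRNA:target hybridization.

Both minimize the exact energy assigned by :func:`structure_energy` /
:func:`duplex_structure_energy`, which score an explicit structure and are
the single source of truth for the model (the test suite exploits this by
exhaustive enumeration on short sequences).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (a and callable(a[0])) else a[0]


# --------------------------------------------------------------------------
# alphabet and pair coding
# --------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIR_INDEX = {
    (1, 2): 0,  # CG
    (2, 1): 1,  # GC
    (0, 3): 2,  # AU
    (3, 0): 3,  # UA
    (2, 3): 4,  # GU
    (3, 2): 5,  # UG
}

#: minimum number of unpaired bases in a hairpin loop
MIN_HAIRPIN = 3
#: largest interior (bulge/internal) loop considered by the dynamic program
MAX_INTERIOR = 30

# stacking free energies, kcal/mol at 37 C; row = outer pair, col = inner
# pair, pair order CG GC AU UA GU UG
STACK = np.array(
    [
        [-3.3, -2.4, -2.1, -2.1, -1.4, -2.1],  # CG
        [-3.4, -3.3, -2.4, -2.2, -1.5, -2.5],  # GC
        [-2.2, -2.1, -0.9, -1.1, -0.6, -1.4],  # AU
        [-2.4, -2.1, -1.3, -0.9, -1.0, -1.3],  # UA
        [-2.5, -2.1, -1.3, -1.4, -0.5, +1.3],  # GU
        [-1.5, -1.4, -1.0, -0.6, +0.3, -0.5],  # UG
    ]
)

# loop initiation penalties before calibration scaling (kcal/mol); indexed
# by loop size, log-extrapolated past the tabulated sizes
_HAIRPIN_BASE = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_BASE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_BASE = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}

#: single calibration constant applied to every loop-initiation term
LOOP_SCALE = 0.32

#: internal-loop asymmetry penalty per unpaired-length difference, and cap
ASYM = 0.20
ASYM_MAX = 1.2

#: multibranch loop: closing penalty, per-branch, per-unpaired-base
ML_CLOSE = 3.4 * LOOP_SCALE
ML_BRANCH = 0.3
ML_UNPAIRED = 0.1

_LOG_COEF = 1.079  # 1.75 * R * T at 37 C
_TAB_LEN = 2048


def _loop_table(base: dict, scale: float) -> np.ndarray:
    tab = np.zeros(_TAB_LEN)
    tab[:] = np.inf
    mx = max(base)
    for n in range(1, _TAB_LEN):
        if n in base:
            tab[n] = base[n]
        elif n > mx:
            tab[n] = base[mx] + _LOG_COEF * math.log(n / mx)
    return tab * scale


HAIRPIN_TAB = _loop_table(_HAIRPIN_BASE, LOOP_SCALE)
BULGE_TAB = _loop_table(_BULGE_BASE, LOOP_SCALE)
INTERNAL_TAB = _loop_table(_INTERNAL_BASE, LOOP_SCALE)

INF = 1e9


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (T and U are equivalent)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence") from None


def pair_index(a: int, b: int) -> int:
    return _PAIR_INDEX.get((a, b), -1)


def _pair_matrix(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    pt = np.full((n, n), -1, dtype=np.int8)
    for i in range(n):
        for j in range(i + 1 + MIN_HAIRPIN, n):
            pt[i, j] = pair_index(int(codes[i]), int(codes[j]))
    return pt


# --------------------------------------------------------------------------
# explicit-structure scoring (single source of truth for the energy model)
# --------------------------------------------------------------------------

def interior_energy(pt_outer: int, pt_inner: int, l1: int, l2: int) -> float:
    """Energy of the loop between pair (i,j) and its only child (k,l).

    ``l1``/``l2`` are the unpaired run lengths on the 5' and 3' sides.
    """
    if l1 == 0 and l2 == 0:
        return float(STACK[pt_outer, pt_inner])
    if l1 == 0 or l2 == 0:
        return float(BULGE_TAB[l1 + l2])
    asym = min(ASYM * abs(l1 - l2), ASYM_MAX)
    return float(INTERNAL_TAB[l1 + l2]) + asym


def structure_energy(seq: str, pairs) -> float:
    """Score an explicit secondary structure (set of pair tuples).

    Raises ``ValueError`` for invalid structures (non-nested, disallowed
    pairs, hairpin loops shorter than ``MIN_HAIRPIN``).
    """
    codes = encode(seq)
    n = len(codes)
    plist = sorted(pairs)
    partner = {}
    for i, j in plist:
        if not (0 <= i < j < n):
            raise ValueError("pair out of range")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError("hairpin loop too short")
        if pair_index(int(codes[i]), int(codes[j])) < 0:
            raise ValueError(f"disallowed pair at ({i},{j})")
        if i in partner or j in partner:
            raise ValueError("base in two pairs")
        partner[i] = j
        partner[j] = i
    for (i, j) in plist:
        for (k, l) in plist:
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot)")

    def children(i: int, j: int):
        out = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    def loop_e(i: int, j: int) -> float:
        ch = children(i, j)
        pt_ij = pair_index(int(codes[i]), int(codes[j]))
        if not ch:
            return float(HAIRPIN_TAB[j - i - 1])
        if len(ch) == 1:
            (k, l) = ch[0]
            return interior_energy(pt_ij, pair_index(int(codes[k]), int(codes[l])),
                                   k - i - 1, j - l - 1)
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in ch)
        return ML_CLOSE + ML_BRANCH * len(ch) + ML_UNPAIRED * unpaired

    return float(sum(loop_e(i, j) for i, j in plist))


# --------------------------------------------------------------------------
# Zuker dynamic program
# --------------------------------------------------------------------------

@njit(cache=False)
def _fill(pt, stack, hairpin_tab, bulge_tab, internal_tab,
          asym, asym_max, ml_close, ml_branch, ml_unpaired,
          min_hairpin, max_interior):  # pragma: no cover - numba kernel
    n = pt.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pt[i, j] >= 0:
                best = hairpin_tab[j - i - 1]
                # stack / bulge / internal
                kmax = min(i + max_interior + 1, j - min_hairpin - 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + min_hairpin + 1, j - 1 - (max_interior - l1))
                    for l in range(lmin, j):
                        if pt[k, l] < 0:
                            continue
                        l2 = j - l - 1
                        if l1 == 0 and l2 == 0:
                            e = stack[pt[i, j], pt[k, l]]
                        elif l1 == 0 or l2 == 0:
                            e = bulge_tab[l1 + l2]
                        else:
                            a = asym * abs(l1 - l2)
                            if a > asym_max:
                                a = asym_max
                            e = internal_tab[l1 + l2] + a
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multibranch: >= 2 branches in (i+1 .. j-1)
                for m in range(i + 2, j - 1):
                    cand = ml_close + WM[i + 1, m] + WM[m + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # WM
            w = INF
            if V[i, j] < INF:
                w = V[i, j] + ml_branch
            if i + 1 <= j and WM[i + 1, j] + ml_unpaired < w:
                w = WM[i + 1, j] + ml_unpaired
            if j - 1 >= i and WM[i, j - 1] + ml_unpaired < w:
                w = WM[i, j - 1] + ml_unpaired
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and V[k, j] < INF:
                    cand = WM[i, k - 1] + V[k, j] + ml_branch
                    if cand < w:
                        w = cand
            WM[i, j] = w
    W = np.zeros(n + 1)
    for j in range(n):
        w = W[j]
        for i in range(0, j):
            if V[i, j] < INF:
                cand = W[i] + V[i, j]
                if cand < w:
                    w = cand
        if V[0, j] < INF and V[0, j] < w:
            w = V[0, j]
        W[j + 1] = w
    return V, WM, W


def _fill_args(pt):
    return (pt, STACK, HAIRPIN_TAB, BULGE_TAB, INTERNAL_TAB,
            ASYM, ASYM_MAX, ML_CLOSE, ML_BRANCH, ML_UNPAIRED,
            MIN_HAIRPIN, MAX_INTERIOR)


_EPS = 1e-9


def _traceback(pt, V, WM, W):
    n = pt.shape[0]
    pairs = []

    def trace_v(i, j):
        pairs.append((i, j))
        e = V[i, j]
        if abs(e - HAIRPIN_TAB[j - i - 1]) < _EPS:
            return
        kmax = min(i + MAX_INTERIOR + 1, j - MIN_HAIRPIN - 1)
        for k in range(i + 1, kmax + 1):
            l1 = k - i - 1
            lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - l1))
            for l in range(lmin, j):
                if pt[k, l] < 0 or V[k, l] >= INF:
                    continue
                le = interior_energy(pt[i, j], pt[k, l], l1, j - l - 1)
                if abs(e - (le + V[k, l])) < _EPS:
                    trace_v(k, l)
                    return
        for m in range(i + 2, j - 1):
            if abs(e - (ML_CLOSE + WM[i + 1, m] + WM[m + 1, j - 1])) < _EPS:
                trace_wm(i + 1, m)
                trace_wm(m + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")

    def trace_wm(i, j):
        while True:
            e = WM[i, j]
            if V[i, j] < INF and abs(e - (V[i, j] + ML_BRANCH)) < _EPS:
                trace_v(i, j)
                return
            if abs(e - (WM[i + 1, j] + ML_UNPAIRED)) < _EPS:
                i += 1
                continue
            if abs(e - (WM[i, j - 1] + ML_UNPAIRED)) < _EPS:
                j -= 1
                continue
            done = False
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and V[k, j] < INF and \
                        abs(e - (WM[i, k - 1] + V[k, j] + ML_BRANCH)) < _EPS:
                    trace_v(k, j)
                    j = k - 1
                    done = True
                    break
            if done:
                continue
            raise AssertionError("traceback failed in WM")

    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j):
            if V[i, j - 1] < INF and abs(W[j] - (W[i] + V[i, j - 1])) < _EPS:
                trace_v(i, j - 1)
                j = i
                found = True
                break
        if not found:
            raise AssertionError("traceback failed in W")
    return sorted(pairs)


def pairs_to_dotbracket(n: int, pairs) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def dotbracket_to_pairs(db: str):
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def fold_mfe(seq: str):
    """Fold one RNA strand; returns ``(dot_bracket, mfe_kcal_mol)``.

    The all-unpaired structure has energy 0, so the MFE is never positive.
    """
    codes = encode(seq)
    n = len(codes)
    if n <= MIN_HAIRPIN + 1:
        return "." * n, 0.0
    pt = _pair_matrix(codes)
    V, WM, W = _fill(*_fill_args(pt))
    mfe = float(W[n])
    if mfe >= 0.0:
        return "." * n, 0.0
    pairs = _traceback(pt, V, WM, W)
    return pairs_to_dotbracket(n, pairs), round(mfe, 6)


# --------------------------------------------------------------------------
# intermolecular duplex
# --------------------------------------------------------------------------

#: affine penalty for interior loops / bulges inside a duplex
DUPLEX_LOOP_OPEN = 3.0
DUPLEX_LOOP_EXT = 0.5
#: largest unpaired run considered on either strand inside a duplex
DUPLEX_MAX_GAP = 15


@njit(cache=False)
def _duplex_fill(x, y, stack, loop_open, loop_ext, max_gap):  # pragma: no cover
    n = x.shape[0]
    m = y.shape[0]
    # pair code of x[i] with y[j] (antiparallel: x 5'->3' vs y 3'->5')
    P = np.full((n, m), INF)
    best = 0.0
    for i in range(n):
        for j in range(m):
            a = x[i]
            b = y[j]
            pc = -1
            if a == 1 and b == 2:
                pc = 0
            elif a == 2 and b == 1:
                pc = 1
            elif a == 0 and b == 3:
                pc = 2
            elif a == 3 and b == 0:
                pc = 3
            elif a == 2 and b == 3:
                pc = 4
            elif a == 3 and b == 2:
                pc = 5
            if pc < 0:
                continue
            e = 0.0  # duplex may start here
            for pi in range(max(0, i - max_gap - 1), i):
                for pj in range(max(0, j - max_gap - 1), j):
                    if P[pi, pj] >= INF:
                        continue
                    gx = i - pi - 1
                    gy = j - pj - 1
                    if gx + gy == 0:
                        pa = x[pi]
                        pb = y[pj]
                        ppc = -1
                        if pa == 1 and pb == 2:
                            ppc = 0
                        elif pa == 2 and pb == 1:
                            ppc = 1
                        elif pa == 0 and pb == 3:
                            ppc = 2
                        elif pa == 3 and pb == 0:
                            ppc = 3
                        elif pa == 2 and pb == 3:
                            ppc = 4
                        elif pa == 3 and pb == 2:
                            ppc = 5
                        step = stack[ppc, pc]
                    else:
                        if gx > max_gap or gy > max_gap:
                            continue
                        step = loop_open + loop_ext * (gx + gy)
                    cand = P[pi, pj] + step
                    if cand < e:
                        e = cand
            P[i, j] = e
            if e < best:
                best = e
    return best


def duplex_energy(mirna: str, window: str) -> float:
    """Minimum free energy of the intermolecular miRNA:target duplex.

    Only pairs between the two strands are allowed; both sequences are
    given 5'->3'.  0.0 means no stabilizing duplex exists.
    """
    x = encode(mirna)
    y = encode(window)[::-1].copy()  # scan target 3'->5' against miRNA 5'->3'
    if len(x) == 0 or len(y) == 0:
        return 0.0
    e = float(_duplex_fill(x, y, STACK, DUPLEX_LOOP_OPEN, DUPLEX_LOOP_EXT,
                           DUPLEX_MAX_GAP))
    return round(min(e, 0.0), 6)


def duplex_structure_energy(mirna: str, window: str, pairs) -> float:
    """Score an explicit duplex structure.

    ``pairs`` are ``(i, j)`` index tuples, ``i`` on the miRNA (5'->3') and
    ``j`` on the window (5'->3'); successive pairs must be antiparallel
    (``i`` strictly increasing, ``j`` strictly decreasing).
    """
    x = encode(mirna)
    y = encode(window)
    plist = sorted(pairs)
    e = 0.0
    prev = None
    for i, j in plist:
        pc = pair_index(int(x[i]), int(y[j]))
        if pc < 0:
            raise ValueError(f"disallowed duplex pair ({i},{j})")
        if prev is not None:
            pi, pj = prev
            if j >= pj:
                raise ValueError("duplex pairs must be antiparallel")
            gx = i - pi - 1
            gy = pj - j - 1
            if gx == 0 and gy == 0:
                e += float(STACK[pair_index(int(x[pi]), int(y[pj])), pc])
            else:
                e += DUPLEX_LOOP_OPEN + DUPLEX_LOOP_EXT * (gx + gy)
        prev = (i, j)
    return e
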