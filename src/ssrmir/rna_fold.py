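"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over nested structures with a frozen
Turner-style nearest-neighbour energy model:

* stacking free energies for the 21 Watson-Crick / G:U wobble stack types
  (kcal/mol at 37 C, frozen constants below);
* hairpin-loop size penalties (table through size 9, Jacobson-Stockmayer
  logarithmic extrapolation beyond);
* bulge and interior-loop size penalties (no asymmetry term, no terminal
  mismatch bonuses -- deliberate simplifications, see docs/methods.md);
* a linear multiloop penalty a + b*branches (+ 0 per unpaired base).

The model is internally consistent and deterministic; it is NOT meant to
reproduce any external folder's exact numbers -- downstream filters are
thresholds on this model's kcal/mol scale. Interior loops are capped at 30
unpaired nt total (standard MAXLOOP restriction). Minimum hairpin loop is
3 nt; lonely pairs are permitted. Tie-breaking in the traceback prefers the
paired state, then the 5'-most branch, so refolding is byte-reproducible.

The inner DP runs as a numba-compiled kernel so that scanning thousands of
120-nt windows stays fast; `brute_force_mfe` is a deliberately naive
exhaustive enumerator over the same energy model used as an independent
cross-check in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

from .io_formats import Interval

# ---------------------------------------------------------------------------
# Energy parameters (frozen)
# ---------------------------------------------------------------------------

_ALPHA = "ACGU"
_IDX = {c: i for i, c in enumerate(_ALPHA)}

#: allowed base pairs: Watson-Crick plus G:U wobble
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

#: stack free energies, kcal/mol. Key (a, b, c, d): pair a.b at (i, j)
#: stacked on pair c.d at (i+1, j-1). The symmetric stack (d, c, b, a) is
#: the same physical motif and is filled in programmatically.
_STACK_DG = {
    # Watson-Crick on Watson-Crick
    ("A", "U", "A", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "G", "U", "A"): -2.08,
    ("C", "G", "A", "U"): -2.11,
    ("G", "C", "U", "A"): -2.24,
    ("G", "C", "A", "U"): -2.35,
    ("C", "G", "G", "C"): -2.36,
    ("G", "C", "G", "C"): -3.26,
    ("G", "C", "C", "G"): -3.42,
    # Watson-Crick on G:U wobble
    ("A", "U", "G", "U"): -0.50,
    ("A", "U", "U", "G"): -1.40,
    ("U", "A", "G", "U"): -1.30,
    ("U", "A", "U", "G"): -1.00,
    ("C", "G", "G", "U"): -1.50,
    ("C", "G", "U", "G"): -2.10,
    ("G", "C", "G", "U"): -1.50,
    ("G", "C", "U", "G"): -2.50,
    # G:U on G:U
    ("G", "U", "G", "U"): -0.50,
    ("G", "U", "U", "G"): 0.50,
    ("U", "G", "G", "U"): -0.60,
}

_HAIRPIN_DG = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_DG = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_DG = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.0}

#: multiloop closure / branch / unpaired-base penalties
ML_A, ML_B, ML_C = 3.4, 0.4, 0.0

#: Ninio interior-loop asymmetry penalty: slope per unpaired-count
#: difference between the two sides, and its cap
NINIO_SLOPE, NINIO_MAX = 0.6, 3.0

_RT = 0.6163  # kcal/mol at 37 C
_LXC = 1.75 * _RT  # Jacobson-Stockmayer loop-entropy coefficient

MAXLOOP = 30  # max total unpaired nt in a bulge/interior loop
MAX_SEQ = 500
MIN_HAIRPIN_SEQ = 5  # 2*1 + 3: shortest sequence that can form a pair

_INF = 1e9


def _js_extrapolate(table: dict[int, float], size: int) -> float:
    ref = max(table)
    if size <= ref:
        return table[size]
    return table[ref] + _LXC * math.log(size / ref)


def _build_arrays():
    pairable = np.zeros((4, 4), dtype=np.bool_)
    for a, b in _PAIRS:
        pairable[_IDX[a], _IDX[b]] = True
    stack = np.full((4, 4, 4, 4), _INF)
    for (a, b, c, d), e in _STACK_DG.items():
        stack[_IDX[a], _IDX[b], _IDX[c], _IDX[d]] = e
        stack[_IDX[d], _IDX[c], _IDX[b], _IDX[a]] = e
    hp = np.full(MAX_SEQ + 2, _INF)
    for l in range(3, MAX_SEQ + 2):
        hp[l] = _js_extrapolate(_HAIRPIN_DG, l)
    bulge = np.full(MAXLOOP + 1, _INF)
    for l in range(1, MAXLOOP + 1):
        bulge[l] = _js_extrapolate(_BULGE_DG, l)
    internal = np.full(MAXLOOP + 1, _INF)
    for l in range(2, MAXLOOP + 1):
        internal[l] = _js_extrapolate(_INTERNAL_DG, l)
    return pairable, stack, hp, bulge, internal


PAIRABLE, STACK, HAIRPIN_PEN, BULGE_PEN, INTERNAL_PEN = _build_arrays()


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def stack_energy(a: str, b: str, c: str, d: str) -> float:
    """Energy of pair a.b stacked on adjacent pair c.d (both must pair)."""
    e = STACK[_IDX[a], _IDX[b], _IDX[c], _IDX[d]]
    if e >= _INF / 2:
        raise KeyError(f"no stack entry for {a}{b}/{c}{d}")
    return float(e)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# DP kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fold_kernel(
    s, pairable, stack, hp, bulge, internal, ml_a, ml_b, ml_c,
    ninio_slope, ninio_max, maxloop,
):
    n = s.shape[0]
    inf = 1e9
    V = np.full((n, n), inf)
    WM = np.full((n, n), inf)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if span >= 4 and pairable[s[i], s[j]]:
                best = hp[span - 1]
                pmax = min(i + 1 + maxloop, j - 5)
                for p in range(i + 1, pmax + 1):
                    l1 = p - i - 1
                    qlo = j - 1 - (maxloop - l1)
                    if qlo < p + 4:
                        qlo = p + 4
                    for q in range(qlo, j):
                        v = V[p, q]
                        if v >= inf / 2:
                            continue
                        l2 = j - q - 1
                        if l1 == 0 and l2 == 0:
                            e = stack[s[i], s[j], s[p], s[q]]
                        elif l1 == 0 or l2 == 0:
                            e = bulge[l1 + l2]
                        else:
                            asym = ninio_slope * abs(l1 - l2)
                            if asym > ninio_max:
                                asym = ninio_max
                            e = internal[l1 + l2] + asym
                        if e + v < best:
                            best = e + v
                for k in range(i + 2, j - 1):
                    a = WM[i + 1, k]
                    b = WM[k + 1, j - 1]
                    if a < inf / 2 and b < inf / 2 and ml_a + ml_b + a + b < best:
                        best = ml_a + ml_b + a + b
                V[i, j] = best
            # WM: >= 1 branch somewhere in [i, j]
            w = inf
            if V[i, j] < inf / 2:
                w = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < w:
                w = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < w:
                w = WM[i, j - 1] + ml_c
            for k in range(i + 1, j):
                a = WM[i, k]
                b = WM[k + 1, j]
                if a < inf / 2 and b < inf / 2 and a + b < w:
                    w = a + b
            WM[i, j] = w
    WR = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = WR[i + 1]
        for j in range(i + 4, n):
            if V[i, j] < inf / 2 and V[i, j] + WR[j + 1] < best:
                best = V[i, j] + WR[j + 1]
        WR[i] = best
    return V, WM, WR


# ---------------------------------------------------------------------------
# Structure container + traceback
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """A nested secondary structure: pair table plus model free energy."""

    seq: str
    pairs: list  # pairs[i] = j if paired, -1 if unpaired
    energy: float

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)

    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)


_TOL = 1e-6


def _trace_V(i, j, s, V, WM, pairs):
    pairs[i], pairs[j] = j, i
    v = V[i, j]
    pmax = min(i + 1 + MAXLOOP, j - 5)
    for p in range(i + 1, pmax + 1):
        l1 = p - i - 1
        qlo = max(p + 4, j - 1 - (MAXLOOP - l1))
        for q in range(j - 1, qlo - 1, -1):
            if V[p, q] >= _INF / 2:
                continue
            l2 = j - q - 1
            if l1 == 0 and l2 == 0:
                e = STACK[s[i], s[j], s[p], s[q]]
            elif l1 == 0 or l2 == 0:
                e = BULGE_PEN[l1 + l2]
            else:
                e = INTERNAL_PEN[l1 + l2] + min(
                    NINIO_MAX, NINIO_SLOPE * abs(l1 - l2)
                )
            if abs(e + V[p, q] - v) < _TOL:
                _trace_V(p, q, s, V, WM, pairs)
                return
    for k in range(i + 2, j - 1):
        a, b = WM[i + 1, k], WM[k + 1, j - 1]
        if a < _INF / 2 and b < _INF / 2 and abs(ML_A + ML_B + a + b - v) < _TOL:
            _trace_WM(i + 1, k, s, V, WM, pairs)
            _trace_WM(k + 1, j - 1, s, V, WM, pairs)
            return
    if abs(HAIRPIN_PEN[j - i - 1] - v) < _TOL:
        return
    raise AssertionError(f"traceback failed at V[{i},{j}]")


def _trace_WM(i, j, s, V, WM, pairs):
    w = WM[i, j]
    if V[i, j] < _INF / 2 and abs(V[i, j] + ML_B - w) < _TOL:
        _trace_V(i, j, s, V, WM, pairs)
        return
    for k in range(i + 1, j):
        a, b = WM[i, k], WM[k + 1, j]
        if a < _INF / 2 and b < _INF / 2 and abs(a + b - w) < _TOL:
            _trace_WM(i, k, s, V, WM, pairs)
            _trace_WM(k + 1, j, s, V, WM, pairs)
            return
    if j - 1 >= i and abs(WM[i, j - 1] + ML_C - w) < _TOL:
        _trace_WM(i, j - 1, s, V, WM, pairs)
        return
    if abs(WM[i + 1, j] + ML_C - w) < _TOL:
        _trace_WM(i + 1, j, s, V, WM, pairs)
        return
    raise AssertionError(f"traceback failed at WM[{i},{j}]")


def fold_mfe(seq: str) -> Structure:
    """Fold an RNA sequence into its minimum-free-energy nested structure.

    Deterministic: ties are broken by a fixed traceback order (paired state
    first, then 5'-most branch). Energy is never positive; a sequence that
    cannot form a favourable structure folds to the open chain at 0.0.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n > MAX_SEQ:
        raise ValueError(f"sequence length {n} exceeds {MAX_SEQ}")
    s = encode(seq)
    if n < MIN_HAIRPIN_SEQ:
        return Structure(seq=seq, pairs=[-1] * n, energy=0.0)
    V, WM, WR = _fold_kernel(
        s, PAIRABLE, STACK, HAIRPIN_PEN, BULGE_PEN, INTERNAL_PEN,
        ML_A, ML_B, ML_C, NINIO_SLOPE, NINIO_MAX, MAXLOOP,
    )
    mfe = float(WR[0])
    pairs = [-1] * n
    if mfe >= -_TOL:
        return Structure(seq=seq, pairs=pairs, energy=0.0)
    # external traceback: scan 5' to 3', prefer pairing when it is optimal
    i = 0
    while i < n:
        if abs(WR[i] - WR[i + 1]) < _TOL and not any(
            V[i, j] < _INF / 2 and abs(V[i, j] + WR[j + 1] - WR[i]) < _TOL
            for j in range(i + 4, n)
        ):
            i += 1
            continue
        placed = False
        for j in range(i + 4, n):
            if V[i, j] < _INF / 2 and abs(V[i, j] + WR[j + 1] - WR[i]) < _TOL:
                _trace_V(i, j, s, V, WM, pairs)
                i = j + 1
                placed = True
                break
        if not placed:
            i += 1
    return Structure(seq=seq, pairs=pairs, energy=mfe)


# ---------------------------------------------------------------------------
# Independent scorer + brute-force enumerator (cross-check oracle)
# ---------------------------------------------------------------------------


def score_structure(seq: str, pairs: list) -> float:
    """Score an explicit nested structure by loop decomposition.

    Walks the structure (independently of the DP) and sums hairpin, stack,
    bulge/interior and multiloop terms under the same frozen parameters.
    """
    seq = seq.upper().replace("T", "U")
    s = encode(seq)
    n = len(seq)
    energy = 0.0
    for i in range(n):
        j = pairs[i]
        if j <= i:
            continue
        # direct children of pair (i, j)
        children = []
        k = i + 1
        while k < j:
            if pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        if not children:
            energy += float(HAIRPIN_PEN[j - i - 1])
        elif len(children) == 1:
            p, q = children[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                energy += float(STACK[s[i], s[j], s[p], s[q]])
            elif l1 == 0 or l2 == 0:
                energy += float(BULGE_PEN[l1 + l2])
            else:
                energy += float(INTERNAL_PEN[l1 + l2]) + min(
                    NINIO_MAX, NINIO_SLOPE * abs(l1 - l2)
                )
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in children)
            energy += ML_A + ML_B * (1 + len(children)) + ML_C * unpaired
    return energy


def _enumerate_pairsets(seq: str):
    """Yield every valid nested pair set (min hairpin loop 3, WC/GU pairs)."""
    s = encode(seq.upper().replace("T", "U"))
    n = len(s)

    @lru_cache(maxsize=None)
    def region(i: int, j: int):
        if i >= j:
            return ((),)
        out = list(region(i + 1, j))
        for k in range(i + 4, j + 1):
            if PAIRABLE[s[i], s[k]]:
                for inner in region(i + 1, k - 1):
                    for rest in region(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    result = region(0, n - 1)
    region.cache_clear()
    return result


def brute_force_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE over the same energy model (small n only).

    Enumerates every valid nested structure explicitly and scores each with
    `score_structure`; used as the independent oracle for `fold_mfe`.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    best = 0.0
    for pairset in _enumerate_pairsets(seq):
        if not pairset:
            continue
        # respect the DP's interior-loop cap so the models are identical
        pairs = [-1] * n
        for a, b in pairset:
            pairs[a], pairs[b] = b, a
        e = score_structure(seq, pairs)
        if e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# Hairpin extraction
# ---------------------------------------------------------------------------


@dataclass
class StemDefect:
    """One bulge/interior loop inside a stem: unpaired stretches on each side."""

    five: tuple  # (start, end) 0-based half-open on the 5' side (may be empty)
    three: tuple
    size: int  # total unpaired nt


@dataclass
class Hairpin:
    """A terminal stem-loop: helix run enclosing exactly one hairpin loop,
    extended outward through bulges/interior loops until a multiloop or the
    exterior region is reached."""

    span: Interval
    arm5: Interval
    arm3: Interval
    loop_size: int
    stem_pairs: int
    largest_interior_defect: int
    defects: list = field(default_factory=list)
    pairs: list = field(default_factory=list)  # pair table of parent structure


def extract_hairpins(s: Structure) -> list[Hairpin]:
    """Extract every terminal stem-loop from a folded structure."""
    pairs = s.pairs
    n = len(pairs)
    hairpins: list[Hairpin] = []
    for i in range(n):
        j = pairs[i]
        if j <= i:
            continue
        # hairpin-closing pair: nothing paired strictly inside
        if any(pairs[k] >= 0 for k in range(i + 1, j)):
            continue
        inner5, inner3 = i, j
        outer5, outer3 = i, j
        stem_pairs = 1
        defects: list[StemDefect] = []
        while True:
            p = outer5 - 1
            while p >= 0 and pairs[p] < 0:
                p -= 1
            q = outer3 + 1
            while q < n and pairs[q] < 0:
                q += 1
            if p < 0 or q >= n or pairs[p] != q:
                break  # exterior or multiloop boundary
            l1 = outer5 - p - 1
            l2 = q - outer3 - 1
            if l1 + l2 > 0:
                defects.append(
                    StemDefect(
                        five=(p + 1, outer5),
                        three=(outer3 + 1, q),
                        size=l1 + l2,
                    )
                )
            outer5, outer3 = p, q
            stem_pairs += 1
        hairpins.append(
            Hairpin(
                span=Interval(outer5, outer3 + 1),
                arm5=Interval(outer5, inner5 + 1),
                arm3=Interval(inner3, outer3 + 1),
                loop_size=inner3 - inner5 - 1,
                stem_pairs=stem_pairs,
                largest_interior_defect=max((d.size for d in defects), default=0),
                defects=defects,
                pairs=pairs,
            )
        )
    return hairpins


# ---------------------------------------------------------------------------
# Duplex energy and AU content
# ---------------------------------------------------------------------------


def duplex_energy(
    mirna: str, site: str, mismatch_penalty: float = 0.0
) -> float:
    """Hybridisation energy of a gap-free antisense miRNA:target alignment.

    Position k of the miRNA (5'->3') faces position len-1-k of the site
    (5'->3'). Nearest-neighbour stack terms are summed over steps where both
    facing positions form a pair (Watson-Crick or G:U); steps interrupted by
    a mismatch contribute nothing, so a fully mismatched alignment scores 0.
    No initiation term.
    """
    q = mirna.upper().replace("T", "U")
    t = site.upper().replace("T", "U")
    if len(q) != len(t):
        raise ValueError(f"length mismatch: {len(q)} vs {len(t)}")
    m = len(q)
    sq, st = encode(q), encode(t)
    energy = 0.0
    n_mm = 0
    for k in range(m):
        if not PAIRABLE[sq[k], st[m - 1 - k]]:
            n_mm += 1
    for k in range(m - 1):
        a, b = sq[k], st[m - 1 - k]
        c, d = sq[k + 1], st[m - 2 - k]
        if PAIRABLE[a, b] and PAIRABLE[c, d]:
            e = STACK[a, b, c, d]
            if e < _INF / 2:
                energy += float(e)
    return energy + mismatch_penalty * n_mm


def au_content(seq: str) -> float:
    """Percent A+U (T counted as U) of a DNA or RNA string."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    au = sum(1 for c in seq if c in "AUT")
    return 100.0 * au / len(seq)


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)
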