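"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's data structures and search
strategies; the folding oracles share only the energy *parameters* with the
engine (they must, to be comparable on the same scale).
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import factorial, inf, log

# ---------------------------------------------------------------------------
# Hamming reference matching


def brute_ref_hits(tag: str, references: dict[str, str], max_mm: int):
    """All (ref_id, best_offset, distance) with distance <= max_mm."""
    tag = tag.upper().replace("U", "T")
    out = []
    for ref_id in sorted(references):
        ref = references[ref_id].upper().replace("U", "T")
        if len(tag) > len(ref):
            continue
        best = None
        for off in range(len(ref) - len(tag) + 1):
            d = sum(1 for a, b in zip(tag, ref[off : off + len(tag)]) if a != b)
            if best is None or d < best[1]:
                best = (off, d)
        if best is not None and best[1] <= max_mm:
            out.append((ref_id, best[0], best[1]))
    out.sort(key=lambda h: (h[2], h[0]))
    return out


# ---------------------------------------------------------------------------
# target-site scoring (independent rule transcription)

_RNA_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_RNA_WOBBLE = {("G", "U"), ("U", "G")}


def brute_target_sites(mirna: str, transcripts: dict[str, str], max_score: float,
                       strict: bool = False, allow_cleavage: bool = False):
    """(mirna-position weighting re-derived from first principles.)"""
    m = mirna.upper().replace("T", "U")
    L = len(m)
    sites = []
    for tid in sorted(transcripts):
        t = transcripts[tid].upper().replace("T", "U")
        for off in range(len(t) - L + 1):
            window = t[off : off + L]
            total = 0.0
            dead = False
            for pos1 in range(1, L + 1):
                mb = m[pos1 - 1]
                tb = window[L - pos1]  # antiparallel
                if (mb, tb) in _RNA_PAIR:
                    continue
                if (mb, tb) in _RNA_WOBBLE and not strict:
                    pen = 0.5
                else:
                    pen = 1.0
                    if pos1 in (10, 11) and not allow_cleavage:
                        dead = True
                if 2 <= pos1 <= 13:
                    pen *= 2
                total += pen
            if not dead and total <= max_score:
                sites.append((tid, off, total))
    return sites


# ---------------------------------------------------------------------------
# exact conditional count-test arithmetic


def exact_pmf(y: int, x: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return (
        r**y
        * factorial(x + y)
        / (factorial(x) * factorial(y))
        / (1 + r) ** (x + y + 1)
    )


def exact_lower_tail(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(exact_pmf(k, x, n1, n2) for k in range(y + 1))


# ---------------------------------------------------------------------------
# folding oracles (share energy parameters with the engine by necessity)

from saltmir.fold import (  # noqa: E402
    MIN_LOOP,
    MULTI_BRANCH,
    MULTI_CLOSE,
    _ENC,
    _PIDX,
    _STACK,
)


def _pairable(enc, i, j):
    return j - i - 1 >= MIN_LOOP and _PIDX[enc[i], enc[j]] >= 0


def _hairpin(n):
    return 5.4 + 1.6 * log(n / 3.0)


def _interior(n1, n2, p, q):
    if n1 == 0 and n2 == 0:
        return float(_STACK[p, q])
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return 3.9 + 1.6 * log(n)
    return 2.0 + 1.6 * log(n / 2.0)


def min_energy_search(sequence: str) -> float:
    """Independent minimum-energy recursion (no interior-loop cap, distinct
    multibranch decomposition).  Intended for n <= 30."""
    enc = [_ENC[c] for c in sequence.upper()]
    n = len(enc)

    @lru_cache(maxsize=None)
    def closed(i, j):
        if not _pairable(enc, i, j):
            return inf
        p = _PIDX[enc[i], enc[j]]
        best = _hairpin(j - i - 1)
        for k in range(i + 1, j - MIN_LOOP):
            for l in range(k + MIN_LOOP + 1, j):
                if _pairable(enc, k, l):
                    e = closed(k, l) + _interior(k - i - 1, j - l - 1, p, _PIDX[enc[k], enc[l]])
                    if e < best:
                        best = e
        e = MULTI_CLOSE + branches(i + 1, j - 1, 2)
        if e < best:
            best = e
        return best

    @lru_cache(maxsize=None)
    def branches(i, j, need):
        # min energy of >= need branches in [i, j]; unpaired bases cost 0
        best = inf if need > 0 else 0.0
        if i > j:
            return best
        b = branches(i + 1, j, need)
        if b < best:
            best = b
        for t in range(i + MIN_LOOP + 1, j + 1):
            if _pairable(enc, i, t):
                e = closed(i, t) + MULTI_BRANCH + branches(t + 1, j, max(0, need - 1))
                if e < best:
                    best = e
        return best

    @lru_cache(maxsize=None)
    def outer(i):
        if i >= n:
            return 0.0
        best = outer(i + 1)
        for t in range(i + MIN_LOOP + 1, n):
            if _pairable(enc, i, t):
                e = closed(i, t) + outer(t + 1)
                if e < best:
                    best = e
        return best

    return min(0.0, outer(0))


def enumerate_structures(sequence: str):
    """Yield every nested structure (as a tuple of pairs).  Use n <= 18."""
    enc = [_ENC[c] for c in sequence.upper()]
    n = len(enc)

    def gen(i, j):
        if j - i + 1 <= MIN_LOOP:
            yield ()
            return
        yield from gen(i + 1, j)
        for t in range(i + MIN_LOOP + 1, j + 1):
            if _pairable(enc, i, t):
                for inner in gen(i + 1, t - 1):
                    for rest in gen(t + 1, j):
                        yield ((i, t), *inner, *rest)

    yield from gen(0, n - 1)


def dotbracket(n: int, pairs) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)
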