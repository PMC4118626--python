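"""Minimum free energy RNA secondary structure prediction.

A self-contained folding engine with a simplified nearest-neighbor energy
model: stacking energies for the 16 pair-on-pair combinations (Turner-style
37degC values), logarithmic loop penalties for hairpin/bulge/internal loops,
and an affine multibranch-loop cost.  The recursion is the classic interval
dynamic program (closed-structure / multibranch-segment / exterior tables)
restricted to nested structures with a minimum hairpin loop of 3 nt.

The engine is deliberately pluggable: everything downstream consumes a
:class:`HairpinFold` and configurable thresholds, so a full thermodynamic
backend can be substituted without touching callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "HairpinFold",
    "fold",
    "is_hairpin",
    "structure_energy",
    "pair_table",
    "MIN_LOOP",
]

MIN_LOOP = 3          # minimum unpaired nt in a hairpin loop
MAXLOOP = 30          # interior/bulge loop size cap inside the DP
MULTI_CLOSE = 3.4     # multibranch loop closing penalty (kcal/mol)
MULTI_BRANCH = 0.4    # per-branch penalty inside a multibranch loop
_INF = 1e9

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair indices: CG GC GU UG AU UA
_PIDX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate(((1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0))):
    _PIDX[_a, _b] = _k

# stacking free energies, closing pair (rows) over inner pair (cols), kcal/mol
_STACK = np.array(
    [  # CG     GC     GU     UG     AU     UA
        [-3.3, -3.4, -2.2, -2.4, -2.1, -2.1],  # CG
        [-3.4, -3.3, -2.5, -2.2, -2.2, -2.4],  # GC
        [-2.2, -2.5, -1.4, -1.3, -1.4, -1.3],  # GU
        [-2.4, -2.2, -1.3, -1.4, -1.0, -1.4],  # UG
        [-2.1, -2.2, -1.4, -1.0, -0.9, -1.3],  # AU
        [-2.1, -2.4, -1.3, -1.4, -1.3, -0.9],  # UA
    ]
)


@njit(cache=False)
def _hairpin_e(n):
    if n < 3:
        return _INF
    return 5.4 + 1.6 * math.log(n / 3.0)


@njit(cache=False)
def _interior_e(n1, n2, p, q, stack):
    """Energy of the loop between closing pair p and inner pair q."""
    if n1 == 0 and n2 == 0:
        return stack[p, q]
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return 3.9 + 1.6 * math.log(n)
    return 2.0 + 1.6 * math.log(n / 2.0)


@njit(cache=False)
def _fill(seq, pidx, stack):
    n = seq.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            p = pidx[seq[i], seq[j]]
            if p >= 0:
                best = _hairpin_e(j - i - 1)
                # interior loops / stacks / bulges
                kmax = min(i + MAXLOOP + 1, j - 4)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = max(k + 4, j - 1 - (MAXLOOP - n1))
                    for l in range(lmin, j):
                        q = pidx[seq[k], seq[l]]
                        if q < 0 or V[k, l] >= _INF / 2:
                            continue
                        e = V[k, l] + _interior_e(n1, j - l - 1, p, q, stack)
                        if e < best:
                            best = e
                # multibranch closing: >= 2 branches inside
                for m in range(i + 5, j - 5):
                    if WM[i + 1, m] < _INF / 2 and WM[m + 1, j - 1] < _INF / 2:
                        e = MULTI_CLOSE + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: >=1 branch in [i, j], unpaired bases free
            wm = WM[i + 1, j]
            for t in range(i + 4, j + 1):
                if V[i, t] < _INF / 2:
                    e = V[i, t] + MULTI_BRANCH
                    if t + 1 <= j and WM[t + 1, j] < 0.0:
                        e += WM[t + 1, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    # exterior loop
    W = np.zeros(n)
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for i in range(0, j - 3):
            if V[i, j] < _INF / 2:
                e = V[i, j] + (W[i - 1] if i > 0 else 0.0)
                if e < w:
                    w = e
        W[j] = w
    return V, WM, W


@dataclass(frozen=True)
class HairpinFold:
    """A sequence with its MFE dot-bracket structure and energy (kcal/mol)."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure/sequence length mismatch")

    def vienna(self, name: str = "seq") -> str:
        return f">{name}\n{self.sequence}\n{self.structure} ({self.mfe:.2f})\n"


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


_EPS = 1e-7


def _traceback(seq, V, WM, W):
    n = seq.shape[0]
    struct = ["."] * n
    pairs: list[tuple[int, int]] = []

    def trace_v(i, j):
        pairs.append((i, j))
        struct[i], struct[j] = "(", ")"
        e = V[i, j]
        p = _PIDX[seq[i], seq[j]]
        if abs(e - _hairpin_e(j - i - 1)) < _EPS:
            return
        kmax = min(i + MAXLOOP + 1, j - 4)
        for k in range(i + 1, kmax + 1):
            n1 = k - i - 1
            lmin = max(k + 4, j - 1 - (MAXLOOP - n1))
            for l in range(lmin, j):
                q = _PIDX[seq[k], seq[l]]
                if q < 0 or V[k, l] >= _INF / 2:
                    continue
                if abs(e - (V[k, l] + _interior_e(n1, j - l - 1, p, q, _STACK))) < _EPS:
                    trace_v(k, l)
                    return
        for m in range(i + 5, j - 5):
            if WM[i + 1, m] < _INF / 2 and WM[m + 1, j - 1] < _INF / 2:
                if abs(e - (MULTI_CLOSE + WM[i + 1, m] + WM[m + 1, j - 1])) < _EPS:
                    trace_wm(i + 1, m)
                    trace_wm(m + 1, j - 1)
                    return
        raise AssertionError("traceback failed in V")

    def trace_wm(i, j):
        e = WM[i, j]
        if i + 1 <= j and abs(e - WM[i + 1, j]) < _EPS:
            trace_wm(i + 1, j)
            return
        for t in range(i + 4, j + 1):
            if V[i, t] >= _INF / 2:
                continue
            cand = V[i, t] + MULTI_BRANCH
            rest = t + 1 <= j and WM[t + 1, j] < 0.0
            if rest:
                cand += WM[t + 1, j]
            if abs(e - cand) < _EPS:
                trace_v(i, t)
                if rest:
                    trace_wm(t + 1, j)
                return
        raise AssertionError("traceback failed in WM")

    j = n - 1
    while j >= 0:
        if j == 0 or abs(W[j] - W[j - 1]) < _EPS:
            if j > 0 or abs(W[j]) < _EPS:
                j -= 1
                continue
        placed = False
        for i in range(0, j - 3):
            if V[i, j] >= _INF / 2:
                continue
            prev = W[i - 1] if i > 0 else 0.0
            if abs(W[j] - (V[i, j] + prev)) < _EPS:
                trace_v(i, j)
                j = i - 1
                placed = True
                break
        if not placed:
            j -= 1
    return "".join(struct), pairs


def fold(sequence: str) -> HairpinFold:
    """Return the minimum free energy structure of an RNA sequence.

    Deterministic: ties between equal-energy structures are broken by a
    fixed traceback exploration order (hairpin, then interior loops by
    ascending inner 5' index, then multibranch splits).
    """
    seq = _encode(sequence)
    if seq.shape[0] < 15:
        raise ValueError("sequence shorter than 15 nt")
    V, WM, W = _fill(seq, _PIDX, _STACK)
    mfe = float(min(W[-1], 0.0))
    if mfe >= -_EPS:
        return HairpinFold(sequence.upper().replace("T", "U"), "." * len(sequence), 0.0)
    structure, _ = _traceback(seq, V, WM, W)
    return HairpinFold(sequence.upper().replace("T", "U"), structure, mfe)


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 when unpaired) from dot-bracket."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket char {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def structure_energy(sequence: str, structure: str) -> float:
    """Evaluate any nested structure under the engine's energy model.

    Decomposes the structure into loops: each closed pair contributes the
    energy of the loop it closes (stack, hairpin, bulge/internal, or
    multibranch); exterior-loop bases are free.
    """
    seq = _encode(sequence)
    pt = pair_table(structure)
    n = len(seq)
    energy = 0.0
    for i in range(n):
        j = pt[i]
        if j <= i:
            continue
        p = _PIDX[seq[i], seq[j]]
        if p < 0:
            raise ValueError(f"disallowed pair at ({i},{j})")
        # top-level branches inside (i, j)
        branches = []
        k = i + 1
        while k < j:
            if pt[k] > k:
                branches.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        if not branches:
            energy += _hairpin_e(j - i - 1)
        elif len(branches) == 1:
            k, l = branches[0]
            q = _PIDX[seq[k], seq[l]]
            energy += _interior_e(k - i - 1, j - l - 1, p, q, _STACK)
        else:
            energy += MULTI_CLOSE + MULTI_BRANCH * len(branches)
    return energy


def is_hairpin(
    hp: HairpinFold,
    min_stem_pairs: int = 16,
    mfe_max: float = -18.0,
):
    """Decide whether a fold is a qualifying single-stem hairpin.

    True iff the structure contains exactly one terminal (hairpin) loop,
    carries at least ``min_stem_pairs`` base pairs on the stem, and has
    ``mfe <= mfe_max``.  Returns ``(ok, arms)`` where ``arms`` maps
    '5p'/'3p' to half-open position ranges of the stem arms (or None).
    """
    pt = pair_table(hp.structure)
    paired = [i for i in range(len(pt)) if pt[i] >= 0]
    if not paired:
        return False, None
    # terminal loops: pairs with no paired base strictly inside
    terminal = []
    for i in paired:
        j = pt[i]
        if j > i and all(pt[k] < 0 for k in range(i + 1, j)):
            terminal.append((i, j))
    if len(terminal) != 1:
        return False, None
    n_pairs = len(paired) // 2
    if n_pairs < min_stem_pairs:
        return False, None
    if hp.mfe > mfe_max:
        return False, None
    ti, tj = terminal[0]
    outer_i = min(i for i in paired if pt[i] > i)
    arms = {"5p": (outer_i, ti + 1), "3p": (tj, int(pt[outer_i]) + 1)}
    return True, arms
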