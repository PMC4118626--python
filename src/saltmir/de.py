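"""Normalization, exact count-ratio test, and up/down regulation calls.

The significance test is the exact conditional test for comparing a count
``x`` in a library of ``N1`` total reads with a count ``y`` in a library of
``N2`` total reads:

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

All probabilities are computed in log space via log-gamma so that counts in
the 1e5 range remain stable.  The lower/upper tails C and D satisfy
``C + D = 1 + p(y|x)`` and the two-sided p-value is ``min(1, 2*min(C, D))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = ["LibraryPair", "DEResult", "normalize", "ac_pmf", "ac_test", "call_de"]


@dataclass(frozen=True)
class LibraryPair:
    """Total clean read counts of the two libraries being compared."""

    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")

    @property
    def ratio(self) -> float:
        return self.n2 / self.n1


def normalize(count: int, total: int) -> float:
    """Reads-per-million: count * 1e6 / total clean reads."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1_000_000 / total


def _log_pmf(ys: np.ndarray, x: int, pair: LibraryPair) -> np.ndarray:
    r = pair.ratio
    ys = np.asarray(ys, dtype=np.float64)
    return (
        ys * math.log(r)
        + gammaln(x + ys + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ys + 1.0)
        - (x + ys + 1.0) * math.log1p(r)
    )


def ac_pmf(y: int, x: int, pair: LibraryPair) -> float:
    """Probability of observing count y in library 2 given x in library 1."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative integers")
    return float(np.exp(_log_pmf(np.array([y]), x, pair)[0]))


def _upper_tail_cutoff(y: int, x: int, pair: LibraryPair) -> int:
    # conditional distribution has mean (x+1)*r and variance (x+1)*r*(1+r)
    r = pair.ratio
    mu = (x + 1) * r
    sd = math.sqrt((x + 1) * r * (1.0 + r))
    return int(max(y + 200, mu + 20 * sd + 200))


def ac_test(x: int, y: int, pair: LibraryPair) -> tuple[float, float, float]:
    """Lower tail C, upper tail D, and two-sided p for counts (x, y).

    C = sum_{k<=y} p(k|x); D = 1 - C + p(y|x); the tail actually summed is
    the smaller one so that precision is kept on both sides.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative integers")
    point = ac_pmf(y, x, pair)
    mode = (x + 1) * pair.ratio
    if y <= mode:
        logc = logsumexp(_log_pmf(np.arange(0, y + 1), x, pair))
        c = min(1.0, float(np.exp(logc)))
        d = min(1.0, 1.0 - c + point)
    else:
        hi = _upper_tail_cutoff(y, x, pair)
        logd = logsumexp(_log_pmf(np.arange(y, hi + 1), x, pair))
        d = min(1.0, float(np.exp(logd)))
        c = min(1.0, 1.0 - d + point)
    p2 = min(1.0, 2.0 * min(c, d))
    return c, d, p2


@dataclass
class DEResult:
    mirna_id: str
    x: int
    y: int
    norm1: float
    norm2: float
    log2fc: float
    c: float
    d: float
    p_two_sided: float
    call: str
    zero_substituted: bool = False


def call_de(
    counts: Mapping[str, Mapping[str, int]],
    treatment: str,
    control: str,
    totals: Mapping[str, int],
    fc_cut: float = 0.5,
    p_cut: float = 0.05,
    min_norm: float = 1.0,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Differential expression calls between two libraries.

    Expression below ``min_norm`` RPM on both sides is filtered out.  When
    exactly one side is zero its normalized value is substituted with
    ``min_norm`` for the fold-change only (flagged in the output).  A miRNA
    is up iff log2fc > fc_cut and p < p_cut; down iff log2fc < -fc_cut and
    p < p_cut.  ``bh_correction`` optionally adds a Benjamini-Hochberg
    adjusted p column (and uses it for the calls).
    """
    pair = LibraryPair(totals[treatment], totals[control])
    results: list[DEResult] = []
    for mid in sorted(counts):
        x = int(counts[mid].get(treatment, 0))
        y = int(counts[mid].get(control, 0))
        n1 = normalize(x, pair.n1)
        n2 = normalize(y, pair.n2)
        if n1 < min_norm and n2 < min_norm:
            results.append(DEResult(mid, x, y, n1, n2, float("nan"), float("nan"),
                                    float("nan"), float("nan"), "filtered"))
            continue
        sub = False
        f1, f2 = n1, n2
        if f1 == 0.0:
            f1, sub = min_norm, True
        if f2 == 0.0:
            f2, sub = min_norm, True
        log2fc = math.log2(f1 / f2)
        c, d, p2 = ac_test(x, y, pair)
        results.append(DEResult(mid, x, y, n1, n2, log2fc, c, d, p2, "unchanged", sub))

    df = pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "count_treatment": r.x,
                "count_control": r.y,
                "norm_treatment": r.norm1,
                "norm_control": r.norm2,
                "log2fc": r.log2fc,
                "C": r.c,
                "D": r.d,
                "p_two_sided": r.p_two_sided,
                "call": r.call,
                "zero_substituted": r.zero_substituted,
            }
            for r in results
        ]
    )
    if df.empty:
        return df
    pcol = "p_two_sided"
    if bh_correction:
        tested = df["call"] != "filtered"
        pvals = df.loc[tested, "p_two_sided"].to_numpy()
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        run_min = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            run_min = min(run_min, pvals[idx] * m / (rank + 1))
            adj[idx] = run_min
        df["p_adjusted"] = np.nan
        df.loc[tested, "p_adjusted"] = adj
        pcol = "p_adjusted"
    tested = df["call"] != "filtered"
    sig = tested & (df[pcol] < p_cut)
    df.loc[sig & (df["log2fc"] > fc_cut), "call"] = "up"
    df.loc[sig & (df["log2fc"] < -fc_cut), "call"] = "down"
    return df
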