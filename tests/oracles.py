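"""Independent reference implementations used only by the test suite.

Each oracle re-derives a result from first principles with a different
algorithmic route than the package (literal enumeration, textbook DP,
exact rational arithmetic), so agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numba
import numpy as np

# base codes: A=0, C=1, G=2, T=3 (N never appears in oracle inputs)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


@numba.njit(cache=False)
def _pair_penalty(m: int, t: int) -> float:
    wc = (
        (m == 0 and t == 3)
        or (m == 3 and t == 0)
        or (m == 2 and t == 1)
        or (m == 1 and t == 2)
    )
    if wc:
        return 0.0
    if (m == 2 and t == 3) or (m == 3 and t == 2):  # G:U wobble
        return 0.5
    return 1.0


@numba.njit(cache=False)
def _weight(p: int) -> float:
    return 2.0 if 2 <= p <= 13 else 1.0


@numba.njit(cache=False)
def _enumerate_scores(m_codes, t_codes, max_bulge):
    """Literal enumeration of every (window end, bulge pos, bulge len).

    Returns a dense score array of shape (L, max_bulge + 1, N + 1) where
    entry [k, b, e] is the expectation of the window ending at e with a
    b-nt bulge after miRNA position k (k row 0 with b = 0 holds the
    bulgeless config); impossible configs hold +inf.
    """
    L = len(m_codes)
    N = len(t_codes)
    scores = np.full((L, max_bulge + 1, N + 1), np.inf)
    for e in range(L, N + 1):
        s = 0.0
        for p in range(1, L + 1):
            s += _weight(p) * _pair_penalty(m_codes[p - 1], t_codes[e - p])
        scores[0, 0, e] = s
    for k in range(1, L):
        for b in range(1, max_bulge + 1):
            for e in range(L + b, N + 1):
                s = b * 0.5 * _weight(k)
                for p in range(1, L + 1):
                    if p <= k:
                        t_idx = e - p
                    else:
                        t_idx = e - p - b
                    s += _weight(p) * _pair_penalty(m_codes[p - 1], t_codes[t_idx])
                scores[k, b, e] = s
    return scores


def duplex_oracle(
    mirna: str, target: str, max_expectation: float = 3.0, max_bulge: int = 3
) -> set[tuple]:
    """All hits as (start, end, bulge_pos, bulge_len, states, expectation)."""
    m_codes = encode(mirna)
    t_codes = encode(target)
    scores = _enumerate_scores(m_codes, t_codes, max_bulge)
    L = len(mirna)
    hits = set()
    ks, bs, es = np.nonzero(scores <= max_expectation)
    for k, b, e in zip(ks.tolist(), bs.tolist(), es.tolist()):
        states = []
        for p in range(1, L + 1):
            t_idx = e - p if (b == 0 or p <= k) else e - p - b
            pen = _pair_penalty(m_codes[p - 1], t_codes[t_idx])
            states.append("WC" if pen == 0.0 else ("GU" if pen == 0.5 else "MM"))
        hits.add(
            (e - L - b, e, k, b, tuple(states), float(scores[k, b, e]))
        )
    return hits


def etm_oracle(mirna: str, target: str, require_bulge: bool = False) -> set[tuple]:
    """Windows satisfying the three mimicry criteria, by literal checking."""
    m_codes = encode(mirna)
    t_codes = encode(target)
    L, N = len(mirna), len(target)
    configs = [] if require_bulge else [(0, 0)]
    configs += [(k, 3) for k in (9, 10, 11, 12) if k < L]
    hits = set()
    for k, b in configs:
        for e in range(L + b, N + 1):
            states = []
            for p in range(1, L + 1):
                t_idx = e - p if (b == 0 or p <= k) else e - p - b
                pen = _pair_penalty(m_codes[p - 1], t_codes[t_idx])
                states.append("WC" if pen == 0.0 else ("GU" if pen == 0.5 else "MM"))
            if any(s != "WC" for s in states[1:8]):
                continue
            if sum(1 for s in states if s != "WC") > 3:
                continue
            hits.add((e - L - b, e, k, b, tuple(states)))
    return hits


@numba.njit(cache=False)
def smith_waterman_score(a_codes, b_codes) -> float:
    """Textbook local-alignment DP: match +1, mismatch -1, gap -2."""
    n, m = len(a_codes), len(b_codes)
    prev = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        cur = np.zeros(m + 1)
        for j in range(1, m + 1):
            s = 1.0 if a_codes[i - 1] == b_codes[j - 1] else -1.0
            v = prev[j - 1] + s
            if prev[j] - 2.0 > v:
                v = prev[j] - 2.0
            if cur[j - 1] - 2.0 > v:
                v = cur[j - 1] - 2.0
            if v < 0.0:
                v = 0.0
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def bh_reference(p_values: np.ndarray) -> np.ndarray:
    """BH step-up via statsmodels (independent of the package's version)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_values, method="fdr_bh")[1]


def hypergeom_upper_tail_exact(k: int, N: int, m: int, n: int) -> Fraction:
    """P(X >= k) by exact rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(m, n) + 1):
        total += Fraction(comb(m, x) * comb(N - m, n - x), comb(N, n))
    return total


def brute_force_longest_orf(seq: str) -> int:
    """Longest ATG..stop ORF (codons, stop excluded) by direct enumeration."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j:j + 3] in stops:
                best = max(best, (j - i) // 3)
                break
            j += 3
    return best


def interval_relation(
    lnc_start, lnc_end, lnc_strand, gene_start, gene_end, gene_strand
) -> str:
    """Exhaustive pairwise relation for positional-class checking."""
    if lnc_end <= gene_start or gene_end <= lnc_start:
        return "disjoint"
    if lnc_start <= gene_start and gene_end <= lnc_end:
        return "contains"
    return "antisense_overlap" if lnc_strand != gene_strand else "sense_overlap"
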