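"""miRNA-RNA duplex search, target/eTM calling and precursor identification.

The duplex engine slides a mature miRNA (5'->3') against every window of a
target transcript read 3'->5', classifying each miRNA position as a
Watson-Crick pair, a G:U wobble, or a mismatch, with at most one target-side
bulge of 1-3 nt. The expectation penalty is

    mismatch 1.0, G:U 0.5, bulged target nt 0.5 each,
    all doubled at miRNA positions 2-13,

and a window is a hit when its expectation does not exceed the threshold
(default 3.0). A bulge of b nt "at position k" sits between the target
partners of miRNA positions k and k+1; its penalty weight uses k.

The eTM caller reuses the same pairing classification under three hard
criteria: (i) Watson-Crick pairing at miRNA positions 2-8 (G:U does not
qualify); (ii) at most three mismatches plus G:U pairs over the whole
pairing region, bulge excluded; (iii) any bulge must be target-side,
exactly 3 nt, and located at positions 9-12. The bulge is permitted, not
required, unless ``require_bulge`` is set.

All sequences are on the internal DNA alphabet; pairing semantics are the
RNA ones (U == T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .edges import InteractionEdge

MIN_MIRNA_LEN = 18
MAX_EXPECTATION = 3.0
MM_PENALTY = 1.0
GU_PENALTY = 0.5
BULGE_PENALTY = 0.5  # per bulged nucleotide
SEED_WEIGHT_RANGE = (2, 13)  # penalties doubled at these miRNA positions
MAX_BULGE = 3

ETM_SEED_RANGE = (2, 8)
ETM_MAX_EDITS = 3
ETM_BULGE_LEN = 3
ETM_BULGE_POSITIONS = (9, 10, 11, 12)

PRECURSOR_MIN_IDENTITY = 0.90  # strict
PRECURSOR_MIN_COVERAGE = 0.80

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# Watson-Crick partners on the DNA-encoded RNA alphabet
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # miRNA base first, target base second


@dataclass(frozen=True)
class DuplexAlignment:
    """One miRNA/target window alignment with per-position pairing states.

    ``states[i]`` is the state of miRNA position i+1 (1 = 5' end), one of
    "WC", "GU", "MM". ``bulge_pos`` is the miRNA position immediately 5' of
    a target-side bulge of ``bulge_len`` unpaired nucleotides (0 = none).
    The target window is [start, end) on the target, 0-based half-open.
    """

    mirna_id: str
    target_id: str
    start: int
    end: int
    states: tuple[str, ...]
    bulge_pos: int
    bulge_len: int
    expectation: float

    def sort_key(self):
        return (self.expectation, self.start, self.bulge_pos, self.bulge_len)


def position_weight(p: int) -> float:
    lo, hi = SEED_WEIGHT_RANGE
    return 2.0 if lo <= p <= hi else 1.0


def pair_state(mirna_base: str, target_base: str) -> str:
    if (mirna_base, target_base) in _WC:
        return "WC"
    if (mirna_base, target_base) in _GU:
        return "GU"
    return "MM"


def state_penalty(state: str) -> float:
    return {"WC": 0.0, "GU": GU_PENALTY, "MM": MM_PENALTY}[state]


def _alignment_from_config(
    mirna: str,
    target: str,
    end: int,
    bulge_pos: int,
    bulge_len: int,
    mirna_id: str,
    target_id: str,
) -> DuplexAlignment:
    """Reconstruct states and expectation for a (window end, bulge) config."""
    L = len(mirna)
    states = []
    expectation = 0.0
    for p in range(1, L + 1):
        t_idx = end - p if (bulge_len == 0 or p <= bulge_pos) else end - p - bulge_len
        state = pair_state(mirna[p - 1], target[t_idx])
        states.append(state)
        expectation += position_weight(p) * state_penalty(state)
    if bulge_len:
        expectation += bulge_len * BULGE_PENALTY * position_weight(bulge_pos)
    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        start=end - L - bulge_len,
        end=end,
        states=tuple(states),
        bulge_pos=bulge_pos if bulge_len else 0,
        bulge_len=bulge_len,
        expectation=expectation,
    )


def duplex_scan(
    mirna: str,
    target: str,
    max_expectation: float = MAX_EXPECTATION,
    max_bulge: int = MAX_BULGE,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[DuplexAlignment]:
    """All duplex alignments with expectation <= ``max_expectation``.

    Every window end and every single-bulge placement (length 1..max_bulge
    between any two adjacent miRNA positions) is scored; results are sorted
    by (expectation, window start, bulge position, bulge length) for a
    deterministic total order.

    Scores are computed with vectorised prefix/suffix penalty sums: for a
    window ending at target index ``e`` with a bulge of ``b`` nt after
    miRNA position ``k``, miRNA position p pairs target index ``e - p``
    (p <= k) or ``e - p - b`` (p > k), so the total penalty splits into a
    k-prefix evaluated at ``e`` plus a k-suffix evaluated at ``e - b``.
    """
    L = len(mirna)
    if L < MIN_MIRNA_LEN:
        raise ValueError(f"miRNA shorter than {MIN_MIRNA_LEN} nt ({L})")
    N = len(target)
    if N < L:
        raise ValueError("target shorter than miRNA")

    t_codes = np.array([_CODE[c] for c in target], dtype=np.int64)
    # per-position penalty lookup rows over target base codes A,C,G,T,N
    bases = "ACGTN"
    pen_rows = np.empty((L, 5))
    for p in range(1, L + 1):
        w = position_weight(p)
        for code, base in enumerate(bases):
            pen_rows[p - 1, code] = w * state_penalty(pair_state(mirna[p - 1], base))

    # pre[k][e] = sum over p=1..k of pen(p, target[e - p]); shape (L+1, N+1)
    shifted = np.zeros((L, N + 1))
    for p in range(1, L + 1):
        row = pen_rows[p - 1][t_codes]
        shifted[p - 1, p:] = row[: N + 1 - p]
    pre = np.zeros((L + 1, N + 1))
    np.cumsum(shifted, axis=0, out=pre[1:])

    hits: list[DuplexAlignment] = []

    total = pre[L]
    for e in np.nonzero(total[L:] <= max_expectation)[0] + L:
        hits.append(
            _alignment_from_config(mirna, target, int(e), 0, 0, mirna_id, target_id)
        )

    for k in range(1, L):
        suffix = pre[L] - pre[k]
        for b in range(1, max_bulge + 1):
            if N < L + b:
                continue
            bpen = b * BULGE_PENALTY * position_weight(k)
            scores = pre[k][b:] + suffix[:-b] + bpen  # indexed by e - b
            es = np.nonzero(scores[L:] <= max_expectation)[0] + L + b
            for e in es:
                hits.append(
                    _alignment_from_config(
                        mirna, target, int(e), k, b, mirna_id, target_id
                    )
                )

    hits.sort(key=DuplexAlignment.sort_key)
    return hits


def etm_scan(
    mirna: str,
    target: str,
    require_bulge: bool = False,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[DuplexAlignment]:
    """All windows satisfying the three eTM criteria (see module docstring)."""
    L = len(mirna)
    if L < MIN_MIRNA_LEN:
        raise ValueError(f"miRNA shorter than {MIN_MIRNA_LEN} nt ({L})")
    N = len(target)
    configs: list[tuple[int, int]] = []
    if not require_bulge:
        configs.append((0, 0))
    configs.extend(
        (k, ETM_BULGE_LEN) for k in ETM_BULGE_POSITIONS if k < L
    )

    seed_lo, seed_hi = ETM_SEED_RANGE
    hits = []
    for k, b in configs:
        for e in range(L + b, N + 1):
            aln = _alignment_from_config(mirna, target, e, k, b, mirna_id, target_id)
            seed_ok = all(
                aln.states[p - 1] == "WC" for p in range(seed_lo, seed_hi + 1)
            )
            if not seed_ok:
                continue
            edits = sum(1 for s in aln.states if s != "WC")
            if edits > ETM_MAX_EDITS:
                continue
            hits.append(aln)
    hits.sort(key=DuplexAlignment.sort_key)
    return hits


def sites_table(alignments: list[DuplexAlignment]) -> pd.DataFrame:
    """Per-site table with a per-position state string (| WC, o GU, x MM)."""
    code = {"WC": "|", "GU": "o", "MM": "x"}
    return pd.DataFrame(
        {
            "miRNA": [a.mirna_id for a in alignments],
            "transcript": [a.target_id for a in alignments],
            "start": [a.start for a in alignments],
            "end": [a.end for a in alignments],
            "bulge_pos": [a.bulge_pos for a in alignments],
            "bulge_len": [a.bulge_len for a in alignments],
            "expectation": [a.expectation for a in alignments],
            "states": ["".join(code[s] for s in a.states) for a in alignments],
        }
    )


def call_targets(
    mirna_seqs: dict[str, str],
    transcript_seqs: dict[str, str],
    transcript_kinds: dict[str, str],
    max_expectation: float = MAX_EXPECTATION,
) -> tuple[list[InteractionEdge], pd.DataFrame]:
    """One edge per (miRNA, transcript) with >= 1 passing duplex window.

    The edge score is the best (lowest) expectation; the site table lists
    every passing window. ``transcript_kinds`` maps ids to mRNA/lncRNA and
    determines the edge type.
    """
    missing = [t for t in transcript_seqs if t not in transcript_kinds]
    if missing:
        raise KeyError(f"no kind for transcripts: {missing[:5]}")
    edges = []
    all_sites: list[DuplexAlignment] = []
    for mid, mseq in mirna_seqs.items():
        for tid, tseq in transcript_seqs.items():
            if len(tseq) < len(mseq):
                continue
            hits = duplex_scan(
                mseq, tseq, max_expectation, mirna_id=mid, target_id=tid
            )
            if not hits:
                continue
            all_sites.extend(hits)
            kind = transcript_kinds[tid]
            edge_type = (
                "miRNA_target_lncRNA" if kind == "lncRNA" else "miRNA_target_mRNA"
            )
            edges.append(
                InteractionEdge(mid, tid, edge_type, hits[0].expectation)
            )
    table = sites_table(all_sites)
    return edges, table


def call_etms(
    mirna_seqs: dict[str, str],
    lncrna_seqs: dict[str, str],
    require_bulge: bool = False,
) -> tuple[list[InteractionEdge], pd.DataFrame]:
    """eTM edges: lncRNAs whose sites satisfy all three mimicry criteria."""
    edges = []
    all_sites: list[DuplexAlignment] = []
    for mid, mseq in mirna_seqs.items():
        for lid, lseq in lncrna_seqs.items():
            if len(lseq) < len(mseq):
                continue
            hits = etm_scan(
                mseq, lseq, require_bulge, mirna_id=mid, target_id=lid
            )
            if not hits:
                continue
            all_sites.extend(hits)
            edges.append(InteractionEdge(lid, mid, "eTM", hits[0].expectation))
    return edges, sites_table(all_sites)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def local_alignment_identity(query: str, reference: str) -> tuple[float, float, int]:
    """Best local alignment of query vs reference.

    Returns (identity, reference coverage fraction, score). Identity is
    matches / alignment columns including gap columns within the aligned
    region; coverage is the aligned reference span over its length.
    """
    aligner = _make_aligner()
    alignments = aligner.align(query, reference)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0
    aln = alignments[0]
    q_blocks, r_blocks = aln.aligned
    matches = 0
    block_cols = 0
    for (qs, qe), (rs, re) in zip(q_blocks, r_blocks):
        block_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], reference[rs:re]) if a == b)
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    r_span = r_blocks[-1][1] - r_blocks[0][0]
    columns = q_span + r_span - block_cols
    identity = matches / columns if columns else 0.0
    coverage = r_span / len(reference)
    return identity, coverage, int(aln.score)


def identify_precursors(
    lncrna_seqs: dict[str, str],
    hairpin_seqs: dict[str, str],
    min_identity: float = PRECURSOR_MIN_IDENTITY,
    min_coverage: float = PRECURSOR_MIN_COVERAGE,
) -> tuple[list[InteractionEdge], pd.DataFrame]:
    """Precursor edges: local-alignment identity strictly above the cutoff.

    Each lncRNA is aligned to every reference hairpin (match +1, mismatch
    -1, gap -2, local). The aligned region must span >= ``min_coverage`` of
    the hairpin; identity is matches over alignment columns.
    """
    if not hairpin_seqs:
        import warnings

        warnings.warn("empty hairpin reference; no precursors can be found")
        return [], pd.DataFrame(
            columns=["lncRNA", "hairpin", "identity", "coverage", "score"]
        )
    edges = []
    rows = []
    for lid, lseq in lncrna_seqs.items():
        for hid, hseq in hairpin_seqs.items():
            identity, coverage, score = local_alignment_identity(lseq, hseq)
            if coverage < min_coverage or identity <= min_identity:
                continue
            edges.append(InteractionEdge(lid, hid, "precursor", identity))
            rows.append(
                {
                    "lncRNA": lid,
                    "hairpin": hid,
                    "identity": identity,
                    "coverage": coverage,
                    "score": score,
                }
            )
    return edges, pd.DataFrame(
        rows, columns=["lncRNA", "hairpin", "identity", "coverage", "score"]
    )
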