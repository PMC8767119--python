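"""Cis and trans target-gene assignment for differential lncRNAs.

Cis candidates are differential genes within 100 kb (edge-to-edge,
inclusive) of the lncRNA on the same chromosome; trans candidates are all
differential genes genome-wide. Both are gated on the absolute Pearson
correlation of expression across all samples. A pair reported cis is
excluded from the trans table so each pair carries one mechanism label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import TranscriptModel
from .io.matrix import ExpressionMatrix

CIS_WINDOW_BP = 100_000
CIS_R_THRESHOLD = 0.95   # inclusive (|r| >= threshold)
TRANS_R_THRESHOLD = 0.95  # strict   (|r| >  threshold)


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    distance_bp: int        # edge-to-edge, 0 when overlapping
    orientation: str        # lncRNA upstream/downstream of the gene, gene-strand frame
    correlation: float


@dataclass(frozen=True)
class TransPair:
    lncrna_id: str
    gene_id: str
    correlation: float


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN sentinel for constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need >= 3 paired samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _orientation(lnc: TranscriptModel, gene: TranscriptModel) -> str:
    """Where the lncRNA sits relative to the gene, in the gene's strand frame."""
    if lnc.interval.overlaps(gene.interval):
        return "overlapping"
    lnc_mid = (lnc.interval.start + lnc.interval.end) / 2
    gene_mid = (gene.interval.start + gene.interval.end) / 2
    lnc_is_left = lnc_mid < gene_mid
    if gene.strand == "+":
        return "upstream" if lnc_is_left else "downstream"
    return "downstream" if lnc_is_left else "upstream"


def assign_cis(
    del_ids: list[str],
    deg_ids: list[str],
    annotation: dict[str, TranscriptModel],
    expression: ExpressionMatrix,
    window_bp: int = CIS_WINDOW_BP,
    r_threshold: float = CIS_R_THRESHOLD,
) -> list[CisPair]:
    """Window + co-expression cis assignment.

    Retains (lncRNA, gene) pairs with edge-to-edge distance <= ``window_bp``
    (inclusive, either strand, same chromosome) and |Pearson r| >=
    ``r_threshold`` over all samples. Constant expression vectors make the
    correlation undefined; such pairs are skipped.
    """
    expr = expression.values
    pairs = []
    for lid in del_ids:
        lnc = annotation.get(lid)
        if lnc is None:
            raise KeyError(f"DEL {lid!r} missing from annotation")
        for gid in deg_ids:
            gene = annotation.get(gid)
            if gene is None:
                raise KeyError(f"DEG {gid!r} missing from annotation")
            if gene.chrom != lnc.chrom:
                continue
            dist = lnc.interval.distance_to(gene.interval)
            if dist > window_bp:
                continue
            r = pearson_r(expr.loc[lid].to_numpy(), expr.loc[gid].to_numpy())
            if math.isnan(r) or abs(r) < r_threshold:
                continue
            pairs.append(
                CisPair(
                    lncrna_id=lid,
                    gene_id=gid,
                    distance_bp=dist,
                    orientation=_orientation(lnc, gene),
                    correlation=r,
                )
            )
    return pairs


def assign_trans(
    del_ids: list[str],
    deg_ids: list[str],
    expression: ExpressionMatrix,
    cis_pairs: list[CisPair] | None = None,
    r_threshold: float = TRANS_R_THRESHOLD,
) -> list[TransPair]:
    """Genome-wide co-expression trans assignment (|r| strictly > threshold).

    Pairs already reported cis are excluded so cis wins the mechanism label.
    """
    cis_keys = {(p.lncrna_id, p.gene_id) for p in (cis_pairs or [])}
    expr = expression.values
    pairs = []
    for lid in del_ids:
        x = expr.loc[lid].to_numpy()
        for gid in deg_ids:
            if (lid, gid) in cis_keys:
                continue
            r = pearson_r(x, expr.loc[gid].to_numpy())
            if math.isnan(r) or abs(r) <= r_threshold:
                continue
            pairs.append(TransPair(lncrna_id=lid, gene_id=gid, correlation=r))
    return pairs


def cis_table(pairs: list[CisPair]) -> pd.DataFrame:
    """Cis pairs with distance reported in kb to 2 decimals."""
    return pd.DataFrame(
        {
            "lncRNA": [p.lncrna_id for p in pairs],
            "gene": [p.gene_id for p in pairs],
            "distance_kb": [round(p.distance_bp / 1e3, 2) for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "r": [p.correlation for p in pairs],
        }
    )


def trans_table(pairs: list[TransPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncRNA": [p.lncrna_id for p in pairs],
            "gene": [p.gene_id for p in pairs],
            "r": [p.correlation for p in pairs],
        }
    )
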