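"""Hypergeometric over-representation test for target-gene sets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

SIGNIFICANCE_P = 0.05


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene<TAB>term TSV (no header) -> term -> gene set."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    terms: dict[str, set[str]] = {}
    for gene, term in zip(frame["gene"].astype(str), frame["term"].astype(str)):
        terms.setdefault(term, set()).add(gene)
    return terms


def hypergeometric_enrichment(
    query_genes: set[str],
    term_annotations: dict[str, set[str]],
    universe: set[str] | None = None,
    p_threshold: float = SIGNIFICANCE_P,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    p = P(X >= k) for k query hits in a term of size m, with query size n
    drawn from a universe of N annotated genes. The universe defaults to
    all genes carrying >= 1 term annotation. Raw p < 0.05 flags
    significance by default; BH-adjusted values are reported alongside.
    """
    if universe is None:
        universe = set().union(*term_annotations.values()) if term_annotations else set()
    stray = query_genes - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    for term, genes in term_annotations.items():
        if not genes:
            raise ValueError(f"term {term!r} has an empty gene set")
        if not genes <= universe:
            raise ValueError(f"term {term!r} contains genes outside the universe")

    N = len(universe)
    n = len(query_genes)
    rows = []
    for term, genes in sorted(term_annotations.items()):
        m = len(genes)
        k = len(query_genes & genes)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        fold = (k / n) / (m / N) if n and m else float("nan")
        rows.append({"term": term, "k": k, "m": m, "n": n, "N": N, "p": p, "fold": fold})
    table = pd.DataFrame(rows, columns=["term", "k", "m", "n", "N", "p", "fold"])
    if len(table):
        table["padj"] = benjamini_hochberg(table["p"].to_numpy())
        gate = table["padj"] if use_adjusted else table["p"]
        table["significant"] = gate < p_threshold
    else:
        table["padj"] = []
        table["significant"] = []
    return table[["term", "k", "m", "n", "N", "p", "padj", "fold", "significant"]]
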