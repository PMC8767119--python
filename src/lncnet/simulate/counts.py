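"""Replicated NB count matrices with planted fold changes and correlations.

Counts are NB(mean, dispersion) with Var = mu + alpha * mu^2. Planted DE
features have group-mean ratio 2^log2FC. Planted cis/trans partner pairs
additionally share a per-sample log-normal latent factor, and are
rejection-sampled until the realized FPKM Pearson correlation is >= 0.97;
decoy pair members get independent noise and are rejection-sampled to
|r| <= 0.5, so every TruthTable correlation claim holds on the emitted
matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..expression import compute_fpkm
from ..io.matrix import ExpressionMatrix
from ..targets import pearson_r
from .config import SimulationConfig
from .genome import GenomeSim


def nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB sample with Var = mu + dispersion * mu^2 (Poisson when ~0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _library_factors(
    rng: np.random.Generator, n: int, spread: float
) -> np.ndarray:
    if spread <= 1.0:
        return np.ones(n)
    return rng.uniform(1.0 / spread, spread, n)


def simulate_counts(
    sim: GenomeSim, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts for every annotated feature plus a miRNA count matrix.

    Returns (transcript counts, miRNA counts, features truth with planted
    DE columns filled, pairs truth with achieved_r filled, miRNA truth).
    """
    features = sim.features.copy()
    pairs = sim.pairs.copy()
    samples = config.sample_ids
    n_rep = config.replicates
    group_mask = np.array([1.0] * n_rep + [0.0] * n_rep)  # 1 = group A
    lib = _library_factors(rng, 2 * n_rep, config.library_size_factor)

    ids = features["id"].tolist()
    lengths = dict(zip(features["id"], features["length"]))
    idx = {fid: i for i, fid in enumerate(ids)}

    partner_ids = set(pairs["lncrna_id"]) | set(
        pairs.loc[pairs["pair_kind"] != "decoy", "gene_id"]
    )
    decoy_gene_ids = set(pairs.loc[pairs["pair_kind"] == "decoy", "gene_id"])
    zero_ids = set(features.loc[features["kind"] == "decoy_low_expression", "id"])

    # ordinary planted DE among features not already special
    ordinary = [
        fid
        for fid in ids
        if fid not in partner_ids and fid not in decoy_gene_ids and fid not in zero_ids
    ]
    n_de = int(round(config.de_fraction * len(ordinary)))
    de_ids = list(rng.choice(ordinary, n_de, replace=False)) if n_de else []

    log2fc = {fid: 0.0 for fid in ids}
    for i, fid in enumerate(de_ids):
        log2fc[fid] = config.log2fc if i % 2 == 0 else -config.log2fc
    for _, row in pairs.iterrows():
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * config.log2fc
        log2fc[row["lncrna_id"]] = lfc
        if row["pair_kind"] != "decoy":
            log2fc[row["gene_id"]] = lfc
        # decoy genes stay at log2FC 0 with independent noise

    base_mean = {
        fid: float(
            config.mean_expression * np.exp(rng.normal(0.0, 0.6))
        )
        for fid in ids
    }

    def feature_means(fid: str, latent: np.ndarray | None) -> np.ndarray:
        lfc = log2fc[fid]
        group_scale = 2.0 ** (lfc * (group_mask - 0.5))
        mu = base_mean[fid] * group_scale * lib
        if latent is not None:
            mu = mu * latent
        return mu

    counts = np.zeros((len(ids), 2 * n_rep), dtype=np.int64)
    for fid in ids:
        if fid in zero_ids:
            continue
        if fid in partner_ids or fid in decoy_gene_ids:
            continue  # drawn below with their pair
        counts[idx[fid]] = nb_draw(
            rng, feature_means(fid, None), config.dispersion
        )

    def fpkm_frame() -> pd.DataFrame:
        matrix = ExpressionMatrix(
            pd.DataFrame(counts, index=ids, columns=samples),
            unit="count",
            groups=config.groups,
        )
        return compute_fpkm(matrix, lengths).values

    # partner pairs: shared latent; rejection-sample until the realized FPKM
    # correlations hold simultaneously on the final matrix (each redraw
    # shifts library sums, so sweep until a full pass is clean)
    def redraw(lid: str, gid: str, kind: str) -> None:
        if kind == "decoy":
            latent_l = np.exp(rng.normal(0, config.partner_latent_sd, 2 * n_rep))
            latent_g = np.exp(rng.normal(0, config.partner_latent_sd, 2 * n_rep))
        else:
            latent_l = latent_g = np.exp(
                rng.normal(0, config.partner_latent_sd, 2 * n_rep)
            )
        counts[idx[lid]] = nb_draw(rng, feature_means(lid, latent_l), config.dispersion)
        counts[idx[gid]] = nb_draw(rng, feature_means(gid, latent_g), config.dispersion)

    for _, row in pairs.iterrows():
        redraw(row["lncrna_id"], row["gene_id"], row["pair_kind"])
    achieved: dict[tuple[str, str], float] = {}
    for _ in range(200):
        fpkm = fpkm_frame()
        clean = True
        for _, row in pairs.iterrows():
            lid, gid, kind = row["lncrna_id"], row["gene_id"], row["pair_kind"]
            r = pearson_r(fpkm.loc[lid].to_numpy(), fpkm.loc[gid].to_numpy())
            ok = abs(r) <= 0.5 if kind == "decoy" else r >= 0.97
            if ok:
                achieved[(lid, gid)] = r
            else:
                redraw(lid, gid, kind)
                clean = False
        if clean:
            break
    else:
        raise RuntimeError("could not realize the planted pair correlations")

    pairs["achieved_r"] = [
        achieved[(row["lncrna_id"], row["gene_id"])] for _, row in pairs.iterrows()
    ]
    features["planted_de"] = [log2fc[fid] != 0.0 for fid in features["id"]]
    features["log2fc"] = [log2fc[fid] for fid in features["id"]]

    transcript_counts = ExpressionMatrix(
        pd.DataFrame(counts, index=ids, columns=samples),
        unit="count",
        groups=config.groups,
    )

    mirna_counts_mat, mirna_truth = simulate_mirna_counts(config, rng)
    return transcript_counts, mirna_counts_mat, features, pairs, mirna_truth


def simulate_mirna_counts(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """NB counts for the miRNA set; roughly half are planted DE."""
    n_rep = config.replicates
    group_mask = np.array([1.0] * n_rep + [0.0] * n_rep)
    lib = _library_factors(rng, 2 * n_rep, config.library_size_factor)
    ids = [f"miR{i + 1:03d}" for i in range(config.n_mirnas)]
    rows = []
    mat = np.zeros((len(ids), 2 * n_rep), dtype=np.int64)
    for i, mid in enumerate(ids):
        planted = i % 2 == 0
        lfc = (config.log2fc if i % 4 == 0 else -config.log2fc) if planted else 0.0
        base = config.mean_expression * np.exp(rng.normal(0.0, 0.6))
        mu = base * 2.0 ** (lfc * (group_mask - 0.5)) * lib
        mat[i] = nb_draw(rng, mu, config.dispersion)
        rows.append({"id": mid, "planted_de": planted, "log2fc": lfc})
    matrix = ExpressionMatrix(
        pd.DataFrame(mat, index=ids, columns=config.sample_ids),
        unit="count",
        groups=config.groups,
    )
    return matrix, pd.DataFrame(rows)
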