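"""End-to-end run: simulate -> discover -> de -> targets -> mirna -> enrich
-> network, with one config, one seed, and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    build_records,
    classify_positional,
    coding_potential_surrogate,
    filter_candidates,
    summarize_features,
)
from .edges import InteractionEdge
from .enrich import hypergeometric_enrichment
from .expression import compute_fpkm, compute_mirna_tpm, nb_differential_test, results_to_frame
from .io.network_io import write_edge_list, write_graphml
from .mirna import call_etms, call_targets, identify_precursors
from .network import build_network
from .simulate import SimulationConfig, simulate_study
from .targets import assign_cis, assign_trans, cis_table, trans_table


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline on a freshly simulated study.

    Writes every stage's result table under ``outdir`` and returns a summary
    dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    study.write(outdir / "sim")

    models = study.sim.models
    genes = [t for t in models if t.biotype == "protein_coding"]
    candidates = [t for t in models if t.biotype != "protein_coding"]
    by_id = {t.id: t for t in models}
    lengths = {t.id: t.length for t in models}

    # --- discovery -------------------------------------------------------
    fpkm = compute_fpkm(study.transcript_counts, lengths)
    survivors, tally = filter_candidates(candidates, fpkm, genes)
    lncrnas = []
    orf_rows = []
    for tm in survivors:
        verdict, orf = coding_potential_surrogate(
            study.transcript_seqs[tm.id], config.orf_codon_threshold
        )
        orf_rows.append({"id": tm.id, "verdict": verdict, "longest_orf_codons": orf})
        if verdict == "noncoding":
            lncrnas.append(tm)
    tally["removed_coding"] = len(survivors) - len(lncrnas)
    tally["lncRNAs"] = len(lncrnas)
    records = build_records(lncrnas, genes, fpkm)
    lnc_frame = pd.DataFrame(
        {
            "id": [r.transcript.id for r in records],
            "positional_class": [r.positional_class for r in records],
            "length": [r.length for r in records],
            "exons": [r.exon_count for r in records],
            **{
                f"mean_FPKM_{g}": [r.mean_fpkm[g] for r in records]
                for g in sorted(set(fpkm.groups.values()))
            },
        }
    )
    _write(lnc_frame, outdir / "lncrnas.tsv")
    _write(
        pd.DataFrame([tally]).T.reset_index().set_axis(["step", "count"], axis=1),
        outdir / "filter_tally.tsv",
    )
    summaries = summarize_features(records)
    for name, frame in summaries.items():
        _write(frame.reset_index(names=name), outdir / f"summary_{name}.tsv")

    # --- differential expression ----------------------------------------
    lnc_ids = {r.transcript.id for r in records}
    kind_of = {t.id: ("lncRNA" if t.id in lnc_ids else "mRNA") for t in models}
    tested_ids = [g.id for g in genes] + sorted(lnc_ids)
    de_results = []
    for kind, ids in (
        ("mRNA", [g.id for g in genes]),
        ("lncRNA", sorted(lnc_ids)),
    ):
        if not ids:
            continue
        sub = study.transcript_counts.subset(ids)
        de_results.extend(
            nb_differential_test(sub, config.group_a, config.group_b, kind)
        )
    de_frame = results_to_frame(de_results)
    _write(de_frame, outdir / "de_transcripts.tsv", index=True)

    dem_results = nb_differential_test(
        study.mirna_counts, config.group_a, config.group_b, "miRNA"
    )
    dem_frame = results_to_frame(dem_results)
    _write(dem_frame, outdir / "de_mirnas.tsv", index=True)
    tpm = compute_mirna_tpm(study.mirna_counts)
    tpm.write_tsv(outdir / "mirna_tpm.tsv")

    dels = sorted(
        fid
        for fid, row in de_frame.iterrows()
        if row["call"] != "not_DE" and row["feature_kind"] == "lncRNA"
    )
    degs = sorted(
        fid
        for fid, row in de_frame.iterrows()
        if row["call"] != "not_DE" and row["feature_kind"] == "mRNA"
    )
    dems = sorted(fid for fid, row in dem_frame.iterrows() if row["call"] != "not_DE")

    # --- target assignment ----------------------------------------------
    cis_pairs = assign_cis(dels, degs, by_id, fpkm)
    trans_pairs = assign_trans(dels, degs, fpkm, cis_pairs)
    _write(cis_table(cis_pairs), outdir / "cis_pairs.tsv")
    _write(trans_table(trans_pairs), outdir / "trans_pairs.tsv")

    # --- miRNA interactions ---------------------------------------------
    dem_seqs = {m: study.mirnas[m] for m in dems}
    del_seqs = {t: study.transcript_seqs[t] for t in dels}
    deg_seqs = {t: study.transcript_seqs[t] for t in degs}
    target_edges, target_sites = call_targets(
        dem_seqs, {**del_seqs, **deg_seqs}, kind_of
    )
    etm_edges, etm_sites = call_etms(dem_seqs, del_seqs)
    precursor_edges, precursor_hits = identify_precursors(del_seqs, study.hairpins)
    _write(target_sites, outdir / "mirna_target_sites.tsv")
    _write(etm_sites, outdir / "etm_sites.tsv")
    _write(precursor_hits, outdir / "precursor_hits.tsv")

    # --- enrichment ------------------------------------------------------
    term_map = _toy_term_map(genes, config)
    target_gene_set = {p.gene_id for p in cis_pairs} | {p.gene_id for p in trans_pairs}
    universe = set().union(*term_map.values()) if term_map else set()
    enrichment = hypergeometric_enrichment(target_gene_set & universe, term_map)
    _write(enrichment, outdir / "enrichment.tsv")

    # --- network ---------------------------------------------------------
    cis_edges = [
        InteractionEdge(p.lncrna_id, p.gene_id, "cis", p.correlation)
        for p in cis_pairs
    ]
    trans_edges = [
        InteractionEdge(p.lncrna_id, p.gene_id, "trans", p.correlation)
        for p in trans_pairs
    ]
    node_classes = {t.id: kind_of[t.id] for t in models}
    node_classes.update({m: "miRNA" for m in study.mirnas})
    node_classes.update({h: "miRNA" for h in study.hairpins})
    direction = {fid: row["call"] for fid, row in de_frame.iterrows()}
    direction.update({fid: row["call"] for fid, row in dem_frame.iterrows()})
    net = build_network(
        cis_edges, trans_edges, target_edges, etm_edges, precursor_edges,
        node_classes, direction,
    )
    write_edge_list(net.edges, net.node_classes, outdir / "network_edges.tsv")
    write_graphml(net.edges, net.node_classes, outdir / "network.graphml")
    _write(net.degree_table(), outdir / "network_degrees.tsv")
    composition = net.composition()
    _write(pd.DataFrame([composition]), outdir / "network_composition.tsv")

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in vars(config).items()},
        "counts": {
            "candidates": len(candidates),
            "lncRNAs": len(lncrnas),
            "DELs": len(dels),
            "DEGs": len(degs),
            "DEMs": len(dems),
            "cis_pairs": len(cis_pairs),
            "trans_pairs": len(trans_pairs),
            "target_edges": len(target_edges),
            "etm_edges": len(etm_edges),
            "precursor_edges": len(precursor_edges),
            "network": composition,
        },
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    manifest["output_sha256"] = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        for name in manifest["outputs"]
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def _jsonable(value):
    if isinstance(value, tuple):
        return list(value)
    return value


def _toy_term_map(genes, config: SimulationConfig) -> dict[str, set[str]]:
    """Deterministic toy gene->term annotation (3 overlapping terms)."""
    ids = sorted(g.id for g in genes)
    terms: dict[str, set[str]] = {"TERM001": set(), "TERM002": set(), "TERM003": set()}
    for i, gid in enumerate(ids):
        terms["TERM001"].add(gid) if i % 2 == 0 else terms["TERM002"].add(gid)
        if i % 3 == 0:
            terms["TERM003"].add(gid)
    return {t: g for t, g in terms.items() if g}
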