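"""Synthetic study generator with machine-readable planted truth."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..intervals import TranscriptModel
from ..io.annotation import write_gtf
from ..io.fasta import write_fasta
from ..io.matrix import ExpressionMatrix
from .config import SITE_CLASSES, SimulationConfig, load_config
from .counts import nb_draw, simulate_counts, simulate_mirna_counts
from .genome import GenomeSim, PlacementError, noncoding_seq, random_seq, simulate_genome
from .sites import (
    build_site_sequence,
    design_site,
    make_hairpins,
    make_mirnas,
    plant_mirna_sites,
    plant_precursors,
)
from .truth import TruthTable


@dataclass
class SyntheticStudy:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    sim: GenomeSim
    mirnas: dict[str, str]
    hairpins: dict[str, str]
    transcript_seqs: dict[str, str]
    transcript_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    mirna_truth: pd.DataFrame
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sim.genome_strings(), outdir / "genome.fa")
        write_gtf(self.sim.models, outdir / "annotation.gtf")
        write_fasta(self.transcript_seqs, outdir / "transcripts.fa")
        write_fasta(self.mirnas, outdir / "mirnas.fa")
        write_fasta(self.hairpins, outdir / "hairpins.fa")
        self.transcript_counts.write_tsv(outdir / "transcript_counts.tsv")
        self.mirna_counts.write_tsv(outdir / "mirna_counts.tsv")
        with open(outdir / "groups.tsv", "w") as handle:
            for sample, group in self.config.groups.items():
                handle.write(f"{sample}\t{group}\n")
        self.truth.write(outdir)
        self.mirna_truth.to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator chain under one seed.

    Genome/annotation first, then miRNA site and hairpin planting (written
    back into the genome so spliced extraction stays consistent), then the
    count matrices. Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sim = simulate_genome(config, rng)
    mirnas = make_mirnas(config, rng)
    hairpins = make_hairpins(config, rng)
    by_id = {t.id: t for t in sim.models}

    # plan lncRNA sites: hosts cycle through rule classes and miRNAs
    plan = []
    host_iter = iter(sim.roles["site_hosts"])
    mirna_ids = sorted(mirnas)
    i = 0
    for rule_class in SITE_CLASSES:
        for _ in range(config.sites_per_class.get(rule_class, 0)):
            plan.append((next(host_iter), mirna_ids[i % len(mirna_ids)], rule_class))
            i += 1
    mrna_ranges = {}
    for j, gid in enumerate(sim.roles["mrna_site_hosts"]):
        plan.append((gid, mirna_ids[(i + j) % len(mirna_ids)], "target"))
        length = by_id[gid].length
        mrna_ranges[gid] = (length - 120, length - 5)

    spliced = {t.id: sim.spliced(t) for t in sim.models}
    kinds = {
        t.id: ("mRNA" if t.biotype == "protein_coding" else "lncRNA")
        for t in sim.models
    }
    edited, sites = plant_mirna_sites(
        spliced, kinds, mirnas, plan, rng, position_ranges=mrna_ranges,
        orf_threshold=config.orf_codon_threshold,
    )
    edited, precursors = plant_precursors(
        edited,
        hairpins,
        sim.roles["precursor_hosts"],
        sim.roles["precursor_decoy_hosts"],
        rng,
        orf_threshold=config.orf_codon_threshold,
    )
    # write edits back so genome extraction matches the transcript FASTA
    for tid, seq in edited.items():
        if seq != spliced[tid]:
            sim.write_spliced(by_id[tid], seq)
    transcript_seqs = {t.id: sim.spliced(t) for t in sim.models}

    # planting must not have created an ORF in any intended survivor
    from ..discovery import longest_orf

    for _, row in sim.features.iterrows():
        if row["expected_fate"] == "survivor":
            orf = longest_orf(transcript_seqs[row["id"]])
            if orf >= config.orf_codon_threshold:
                raise PlacementError(
                    f"planting created a {orf}-codon ORF in {row['id']}; "
                    "re-run with a different seed"
                )

    counts, mirna_counts, features, pairs, mirna_truth = simulate_counts(
        sim, config, rng
    )
    truth = TruthTable(
        features=features, pairs=pairs, sites=sites, precursors=precursors
    )
    return SyntheticStudy(
        config=config,
        sim=sim,
        mirnas=mirnas,
        hairpins=hairpins,
        transcript_seqs=transcript_seqs,
        transcript_counts=counts,
        mirna_counts=mirna_counts,
        mirna_truth=mirna_truth,
        truth=truth,
    )


__all__ = [
    "SITE_CLASSES",
    "SimulationConfig",
    "load_config",
    "GenomeSim",
    "PlacementError",
    "SyntheticStudy",
    "TruthTable",
    "simulate_genome",
    "simulate_counts",
    "simulate_mirna_counts",
    "simulate_study",
    "make_mirnas",
    "make_hairpins",
    "plant_mirna_sites",
    "plant_precursors",
    "design_site",
    "build_site_sequence",
    "nb_draw",
    "random_seq",
    "noncoding_seq",
]
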