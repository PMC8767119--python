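"""Toy annotated genome with planted lncRNA classes and filter decoys.

Every feature is placed so its downstream fate is known by construction:
protein-coding genes carry a real ORF; candidate lncRNAs of all four
positional classes (lincRNA, antisense, sense, overlapping) are ORF-free
and survive the filter cascade; decoys violate exactly one rule each
(same-strand exonic overlap, coding ORF, length < 200 nt, or near-zero
expression). Sequence placement is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..discovery import longest_orf
from ..intervals import GenomicInterval, TranscriptModel, reverse_complement
from ..targets import _orientation
from .config import SimulationConfig
from .truth import FEATURE_COLUMNS, PAIR_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

LINC_LENGTH_SAMPLERS = ((250, 550), (650, 950), (1050, 1350), (1500, 2200))
MARGIN = 1000
GAP_RANGE = (1500, 4000)


class PlacementError(RuntimeError):
    pass


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def noncoding_seq(rng: np.random.Generator, n: int, threshold: int) -> str:
    """Random sequence rejected-sampled to carry no ORF >= threshold codons."""
    for _ in range(100):
        seq = random_seq(rng, n)
        if longest_orf(seq) < threshold:
            return seq
    raise PlacementError(f"could not draw an ORF-free sequence of {n} nt")


def coding_spliced(
    rng: np.random.Generator, total_len: int, orf_codons: int
) -> str:
    """Spliced mRNA of given length whose longest ORF is >= orf_codons."""
    orf_nt = 3 * orf_codons + 3
    utr5 = 30
    utr3 = total_len - utr5 - 3 - orf_nt
    if utr3 < 0:
        raise ValueError("transcript too short for the requested ORF")
    body = "".join(rng.choice(_CODONS, orf_codons))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return (
        noncoding_seq(rng, utr5, orf_codons) + "ATG" + body + stop
        + (noncoding_seq(rng, utr3, orf_codons) if utr3 > 0 else "")
    )


@dataclass
class GenomeSim:
    """simulate_genome output: sequences, models, planted truth, role lists."""

    genome: dict[str, bytearray]
    genes: list[TranscriptModel] = field(default_factory=list)
    candidates: list[TranscriptModel] = field(default_factory=list)
    roles: dict[str, list[str]] = field(default_factory=dict)
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def models(self) -> list[TranscriptModel]:
        return self.genes + self.candidates

    def genome_strings(self) -> dict[str, str]:
        return {c: bytes(s).decode() for c, s in self.genome.items()}

    def write_spliced(self, tm: TranscriptModel, spliced: str) -> None:
        """Write a spliced sequence back into the genome at the exon chunks."""
        if len(spliced) != tm.length:
            raise ValueError("spliced length does not match exon union")
        plus = spliced if tm.strand == "+" else reverse_complement(spliced)
        chrom = self.genome[tm.chrom]
        offset = 0
        for exon in tm.exons:
            chunk = plus[offset:offset + len(exon)]
            chrom[exon.start:exon.end] = chunk.encode()
            offset += len(exon)

    def spliced(self, tm: TranscriptModel) -> str:
        return tm.spliced_sequence(self.genome_strings())


def _make_exons(
    chrom: str,
    strand: str,
    start: int,
    exon_lengths: list[int],
    intron_lengths: list[int],
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i, elen in enumerate(exon_lengths):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return exons


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeSim:
    """Build the annotated toy genome (see module docstring).

    Raises :class:`PlacementError` when a chromosome is too short for the
    requested feature load.
    """
    rng = rng or np.random.default_rng(config.seed)
    for name, bound in (
        ("n_sense", config.n_coding_genes),
        ("n_antisense", config.n_coding_genes),
        ("n_decoy_overlap", config.n_coding_genes),
    ):
        if getattr(config, name) > bound:
            raise ValueError(f"{name} cannot exceed n_coding_genes")

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sim = GenomeSim(
        genome={
            c: bytearray(random_seq(rng, config.chrom_length).encode())
            for c in chroms
        }
    )
    threshold = config.orf_codon_threshold
    cursors = {c: MARGIN for c in chroms}
    feature_rows: list[dict] = []

    def place(chrom: str, width: int) -> int:
        gap = int(rng.integers(*GAP_RANGE))
        start = cursors[chrom] + gap
        if start + width > config.chrom_length - MARGIN:
            raise PlacementError(
                f"{chrom} too short for requested features; increase "
                f"chrom_length (>{config.chrom_length})"
            )
        cursors[chrom] = start + width
        return start

    def record(tm: TranscriptModel, kind: str, pclass: str, fate: str) -> None:
        feature_rows.append(
            {
                "id": tm.id,
                "kind": kind,
                "positional_class": pclass,
                "chrom": tm.chrom,
                "start": tm.interval.start,
                "end": tm.interval.end,
                "strand": tm.strand,
                "length": tm.length,
                "exons": tm.exon_count,
                "expected_fate": fate,
                "planted_de": False,
                "log2fc": 0.0,
            }
        )

    # --- hosting assignments across genes -------------------------------
    ng = config.n_coding_genes
    sense_hosts = {i: j for j, i in enumerate(range(config.n_sense))}
    antisense_hosts = {
        (config.n_sense + j) % ng: j for j in range(config.n_antisense)
    }
    overlap_decoy_hosts = {
        (config.n_sense + config.n_antisense + j) % ng: j
        for j in range(config.n_decoy_overlap)
    }

    def build_gene(index: int, chrom: str) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        sense_len = (
            int(rng.integers(250, 1200)) if index in sense_hosts else 0
        )
        exon_lengths = [300, 500]
        intron = sense_len + 400 if sense_len else int(rng.integers(200, 800))
        width = sum(exon_lengths) + intron
        start = place(chrom, width)
        exons = _make_exons(chrom, strand, start, exon_lengths, [intron])
        gene = TranscriptModel(
            id=f"GENE{index + 1:03d}",
            gene_id=f"g{index + 1:03d}",
            interval=GenomicInterval(chrom, start, start + width, strand),
            exons=exons,
            biotype="protein_coding",
        )
        orf_codons = threshold + 20 + int(rng.integers(0, 40))

        extracted: list[tuple[TranscriptModel, str, str, str]] = []
        if index in antisense_hosts:
            alen = int(rng.integers(250, 850))
            astart = start + 100
            anti = TranscriptModel(
                id=f"LNCAS{antisense_hosts[index] + 1:03d}",
                gene_id=f"lncas{antisense_hosts[index] + 1:03d}",
                interval=GenomicInterval(
                    chrom, astart, astart + alen, "-" if strand == "+" else "+"
                ),
                biotype="candidate",
            )
            extracted.append((anti, "lncRNA_candidate", "antisense", "survivor"))
        if index in overlap_decoy_hosts:
            dlen = int(rng.integers(200, 260))
            dstart = start + 20
            decoy = TranscriptModel(
                id=f"DOVL{overlap_decoy_hosts[index] + 1:03d}",
                gene_id=f"dovl{overlap_decoy_hosts[index] + 1:03d}",
                interval=GenomicInterval(chrom, dstart, dstart + dlen, strand),
                biotype="candidate",
            )
            extracted.append((decoy, "decoy_overlap", "", "removed_overlap"))

        # regenerate gene sequence until extracted candidates are ORF-free
        genome_str = None
        for _ in range(60):
            sim.write_spliced(gene, coding_spliced(rng, gene.length, orf_codons))
            genome_str = sim.genome_strings()
            ok = all(
                longest_orf(tm.spliced_sequence(genome_str)) < threshold
                for tm, _, _, _ in extracted
            )
            if ok:
                break
        else:
            raise PlacementError(f"could not make candidates of {gene.id} ORF-free")

        sim.genes.append(gene)
        record(gene, "gene", "", "gene")
        for tm, kind, pclass, fate in extracted:
            sim.candidates.append(tm)
            record(tm, kind, pclass, fate)

        if index in sense_hosts:
            intron_start = exons[0].end
            sstart = intron_start + 200
            sense = TranscriptModel(
                id=f"LNCSE{sense_hosts[index] + 1:03d}",
                gene_id=f"lncse{sense_hosts[index] + 1:03d}",
                interval=GenomicInterval(chrom, sstart, sstart + sense_len, strand),
                biotype="candidate",
            )
            sim.write_spliced(sense, noncoding_seq(rng, sense_len, threshold))
            sim.candidates.append(sense)
            record(sense, "lncRNA_candidate", "sense", "survivor")

    def build_overlapping(index: int, chrom: str) -> None:
        lnc_strand = "+" if rng.random() < 0.5 else "-"
        olen = int(rng.integers(1000, 1600))
        start = place(chrom, olen)
        lnc = TranscriptModel(
            id=f"LNCOV{index + 1:03d}",
            gene_id=f"lncov{index + 1:03d}",
            interval=GenomicInterval(chrom, start, start + olen, lnc_strand),
            biotype="candidate",
        )
        gene = TranscriptModel(
            id=f"GENEOV{index + 1:03d}",
            gene_id=f"gov{index + 1:03d}",
            interval=GenomicInterval(
                chrom, start + 200, start + 600, "-" if lnc_strand == "+" else "+"
            ),
            biotype="protein_coding",
        )
        for _ in range(60):
            sim.write_spliced(gene, coding_spliced(rng, 400, threshold + 5))
            if longest_orf(sim.spliced(lnc)) < threshold:
                break
            # re-randomise the lncRNA's non-gene flanks as well
            for lo, hi in ((start, start + 200), (start + 600, start + olen)):
                sim.genome[chrom][lo:hi] = random_seq(rng, hi - lo).encode()
        else:
            raise PlacementError(f"could not make {lnc.id} ORF-free")
        sim.genes.append(gene)
        sim.candidates.append(lnc)
        record(gene, "gene", "", "gene")
        record(lnc, "lncRNA_candidate", "overlapping", "survivor")

    def build_linc(index: int, chrom: str) -> TranscriptModel:
        lo, hi = LINC_LENGTH_SAMPLERS[index % len(LINC_LENGTH_SAMPLERS)]
        spliced_len = int(rng.integers(lo, hi))
        n_exons = int(rng.integers(1, 4)) if spliced_len >= 600 else 1
        cuts = (
            sorted(rng.choice(np.arange(200, spliced_len - 200, 100), n_exons - 1,
                              replace=False).tolist())
            if n_exons > 1
            else []
        )
        bounds = [0] + cuts + [spliced_len]
        exon_lengths = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        intron_lengths = [int(rng.integers(100, 400)) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        width = sum(exon_lengths) + sum(intron_lengths)
        start = place(chrom, width)
        linc = TranscriptModel(
            id=f"LINC{index + 1:03d}",
            gene_id=f"linc{index + 1:03d}",
            interval=GenomicInterval(chrom, start, start + width, strand),
            exons=_make_exons(chrom, strand, start, exon_lengths, intron_lengths),
            biotype="candidate",
        )
        sim.write_spliced(linc, noncoding_seq(rng, spliced_len, threshold))
        sim.candidates.append(linc)
        record(linc, "lncRNA_candidate", "lincRNA", "survivor")
        return linc

    def build_simple_decoy(index: int, chrom: str, kind: str) -> None:
        if kind == "decoy_short":
            length = int(rng.integers(150, 200))
            seq = noncoding_seq(rng, length, threshold)
            fate, tag = "removed_short", "DSHORT"
        elif kind == "decoy_low_expression":
            length = int(rng.integers(300, 800))
            seq = noncoding_seq(rng, length, threshold)
            fate, tag = "removed_low_fpkm", "DLOW"
        else:  # decoy_coding
            length = int(rng.integers(450, 900))
            seq = coding_spliced(rng, length, threshold + int(rng.integers(5, 40)))
            fate, tag = "removed_coding", "DCOD"
        strand = "+" if rng.random() < 0.5 else "-"
        start = place(chrom, length)
        tm = TranscriptModel(
            id=f"{tag}{index + 1:03d}",
            gene_id=f"{tag.lower()}{index + 1:03d}",
            interval=GenomicInterval(chrom, start, start + length, strand),
            biotype="candidate",
        )
        sim.write_spliced(tm, seq)
        sim.candidates.append(tm)
        record(tm, kind, "", fate)

    # --- interleave genes and lincRNAs round-robin over chromosomes -----
    units: list[tuple[str, int]] = []
    gi = li = 0
    while gi < config.n_coding_genes or li < config.n_lincrna:
        if gi < config.n_coding_genes:
            units.append(("gene", gi))
            gi += 1
        if li < config.n_lincrna:
            units.append(("linc", li))
            li += 1
    units.extend(("overlapping", i) for i in range(config.n_overlapping))
    units.extend(("decoy_coding", i) for i in range(config.n_decoy_coding))
    units.extend(("decoy_short", i) for i in range(config.n_decoy_short))
    units.extend(
        ("decoy_low_expression", i) for i in range(config.n_decoy_low_expression)
    )

    lincs: list[TranscriptModel] = []
    for u, (utype, idx) in enumerate(units):
        # consecutive units pair up on one chromosome so gene/lincRNA
        # neighbours (future cis pairs) share a chromosome
        chrom = chroms[(u // 2) % len(chroms)]
        if utype == "gene":
            build_gene(idx, chrom)
        elif utype == "linc":
            lincs.append(build_linc(idx, chrom))
        elif utype == "overlapping":
            build_overlapping(idx, chrom)
        else:
            build_simple_decoy(idx, chrom, utype)

    # --- role allocation over lincRNAs ----------------------------------
    pool = list(lincs)

    def take(n: int) -> list[str]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return [t.id for t in taken]

    n_sites = sum(config.sites_per_class.values())
    sim.roles = {
        "site_hosts": take(n_sites),
        "precursor_hosts": take(config.n_precursor_lncrnas),
        "precursor_decoy_hosts": take(config.n_precursor_decoys),
        "cis_lnc": take(config.n_cis_pairs),
        "trans_lnc": take(config.n_trans_pairs),
        "decoy_lnc": take(config.n_decoy_pairs),
        "free_lnc": [t.id for t in pool],
        "mrna_site_hosts": [
            sim.genes[
                (config.n_sense + config.n_antisense + config.n_decoy_overlap + j)
                % max(len(sim.genes), 1)
            ].id
            for j in range(config.n_mrna_target_sites)
        ],
    }

    # --- co-expression pair truth ---------------------------------------
    by_id = {t.id: t for t in sim.models}
    plain_genes = [g for g in sim.genes if not g.id.startswith("GENEOV")]

    def nearest_gene(lnc: TranscriptModel, used: set[str]) -> TranscriptModel:
        same = [
            g
            for g in plain_genes
            if g.chrom == lnc.chrom
            and g.id not in used
            and lnc.interval.distance_to(g.interval) <= 100_000
        ]
        if not same:
            raise PlacementError("no gene on the lncRNA's chromosome for a cis pair")
        return min(same, key=lambda g: lnc.interval.distance_to(g.interval))

    def other_chrom_gene(lnc: TranscriptModel, used: set[str]) -> TranscriptModel:
        away = [
            g
            for g in plain_genes
            if g.id not in used
            and (
                g.chrom != lnc.chrom
                or lnc.interval.distance_to(g.interval) > 100_000
            )
        ]
        if not away:
            raise PlacementError("no distant gene available for a trans pair")
        return away[0]

    pair_rows: list[dict] = []
    used_genes: set[str] = set()
    for lid in sim.roles["cis_lnc"]:
        lnc = by_id[lid]
        gene = nearest_gene(lnc, used_genes)
        used_genes.add(gene.id)
        pair_rows.append(
            {
                "lncrna_id": lid,
                "gene_id": gene.id,
                "pair_kind": "cis",
                "distance_bp": lnc.interval.distance_to(gene.interval),
                "orientation": _orientation(lnc, gene),
                "achieved_r": np.nan,
            }
        )
    for lid in sim.roles["trans_lnc"]:
        lnc = by_id[lid]
        gene = other_chrom_gene(lnc, used_genes)
        used_genes.add(gene.id)
        pair_rows.append(
            {
                "lncrna_id": lid,
                "gene_id": gene.id,
                "pair_kind": "trans",
                "distance_bp": -1,
                "orientation": "",
                "achieved_r": np.nan,
            }
        )
    for lid in sim.roles["decoy_lnc"]:
        lnc = by_id[lid]
        gene = nearest_gene(lnc, used_genes)
        used_genes.add(gene.id)
        pair_rows.append(
            {
                "lncrna_id": lid,
                "gene_id": gene.id,
                "pair_kind": "decoy",
                "distance_bp": lnc.interval.distance_to(gene.interval),
                "orientation": _orientation(lnc, gene),
                "achieved_r": np.nan,
            }
        )

    sim.features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    sim.pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    return sim
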