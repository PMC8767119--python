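"""lncRNA identification cascade and positional classification.

Candidates are filtered in three logged steps (same-strand exonic overlap
with a coding gene, max FPKM < 0.5 across samples, length < 200 nt), then
screened with an ORF-length coding-potential surrogate, and finally placed
into one of four positional classes relative to the coding annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import TranscriptModel
from .io.matrix import ExpressionMatrix

MIN_LENGTH = 200
MIN_FPKM = 0.5
ORF_CODON_THRESHOLD = 100

LENGTH_BINS = ((200, 600), (601, 1000), (1001, 1400))  # plus >1400

POSITIONAL_CLASSES = ("lincRNA", "antisense", "sense", "overlapping")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    positional_class: str
    mean_fpkm: dict[str, float]  # per group

    @property
    def length(self) -> int:
        return self.transcript.length

    @property
    def exon_count(self) -> int:
        return self.transcript.exon_count


def filter_candidates(
    transcripts: list[TranscriptModel],
    fpkm: ExpressionMatrix,
    coding_genes: list[TranscriptModel],
    min_fpkm: float = MIN_FPKM,
    min_length: int = MIN_LENGTH,
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Apply the three removal predicates in order, logging a tally per step.

    Step 1 removes candidates with >= 1 bp exonic same-strand overlap with a
    protein-coding gene; step 2 removes candidates whose maximum FPKM across
    all samples is strictly below ``min_fpkm``; step 3 removes candidates
    shorter than ``min_length`` nt. The predicates are independent, so the
    surviving set does not depend on the order — only the tallies do.
    """
    if fpkm.unit != "FPKM":
        raise ValueError(f"expected FPKM matrix, got unit {fpkm.unit!r}")
    missing = [t.id for t in transcripts if t.id not in fpkm.values.index]
    if missing:
        raise KeyError(f"transcripts absent from FPKM matrix: {missing[:10]}")

    by_chrom: dict[str, list[TranscriptModel]] = {}
    for gene in coding_genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)

    tally = {"input": len(transcripts)}
    stage = []
    removed = 0
    for tm in transcripts:
        hit = any(
            tm.exonic_overlap(gene, stranded=True)
            for gene in by_chrom.get(tm.chrom, [])
            if gene.interval.overlaps(tm.interval)
        )
        if hit:
            removed += 1
        else:
            stage.append(tm)
    tally["removed_same_strand_exonic_overlap"] = removed

    max_fpkm = fpkm.values.max(axis=1)
    survivors = [t for t in stage if max_fpkm[t.id] >= min_fpkm]
    tally["removed_low_fpkm"] = len(stage) - len(survivors)

    final = [t for t in survivors if t.length >= min_length]
    tally["removed_short"] = len(survivors) - len(final)
    tally["survivors"] = len(final)
    return final, tally


def longest_orf(sequence: str) -> int:
    """Longest ATG..stop ORF over the 3 forward frames, in codons.

    Counts coding codons excluding the stop; an ORF must terminate at a stop
    codon within the sequence. Returns 0 when no such ORF exists.
    """
    seq = sequence.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def coding_potential_surrogate(
    sequence: str, codon_threshold: int = ORF_CODON_THRESHOLD
) -> tuple[str, int]:
    """Classify a transcript sequence as coding/noncoding by longest ORF.

    Coding iff the longest forward-frame ATG-to-stop ORF spans at least
    ``codon_threshold`` codons. Sequences shorter than one codon are
    noncoding with ORF length 0.
    """
    if len(sequence) < 3:
        return "noncoding", 0
    orf = longest_orf(sequence)
    return ("coding" if orf >= codon_threshold else "noncoding"), orf


def classify_positional(
    lncrna: TranscriptModel, genes: list[TranscriptModel]
) -> str:
    """Assign one of {lincRNA, antisense, sense, overlapping}.

    overlapping: the lncRNA fully contains a gene (either strand);
    antisense: overlap with an opposite-strand gene; sense: same-strand
    overlap confined to non-exonic (intronic) gene regions; lincRNA: no
    overlap at all. Precedence overlapping > antisense > sense.
    """
    contains_gene = False
    antisense = False
    sense = False
    for gene in genes:
        if not lncrna.interval.overlaps(gene.interval):
            continue
        if lncrna.interval.contains(gene.interval):
            contains_gene = True
        if gene.strand != lncrna.strand:
            antisense = True
        else:
            sense = True
    if contains_gene:
        return "overlapping"
    if antisense:
        return "antisense"
    if sense:
        return "sense"
    return "lincRNA"


def build_records(
    lncrnas: list[TranscriptModel],
    genes: list[TranscriptModel],
    fpkm: ExpressionMatrix,
) -> list[LncRNARecord]:
    groups = sorted(set(fpkm.groups.values()))
    records = []
    for tm in lncrnas:
        means = {
            g: float(fpkm.values.loc[tm.id, fpkm.samples_in_group(g)].mean())
            for g in groups
        }
        records.append(
            LncRNARecord(
                transcript=tm,
                positional_class=classify_positional(tm, genes),
                mean_fpkm=means,
            )
        )
    return records


def summarize_features(records: list[LncRNARecord]) -> dict[str, pd.DataFrame]:
    """Length-bin, exon-count and positional-class proportion tables.

    Length bins are [200,600], [601,1000], [1001,1400] and >1400 nt;
    percentages sum to 100 within rounding. Empty input yields empty tables.
    """
    if not records:
        import warnings

        warnings.warn("summarize_features called on an empty record set")
        empty = pd.DataFrame(columns=["count", "percent"])
        return {"length_bins": empty, "exon_counts": empty, "classes": empty}

    lengths = np.array([r.length for r in records])
    labels = [f"{lo}-{hi}" for lo, hi in LENGTH_BINS] + [">1400"]
    counts = []
    for lo, hi in LENGTH_BINS:
        counts.append(int(((lengths >= lo) & (lengths <= hi)).sum()))
    counts.append(int((lengths > LENGTH_BINS[-1][1]).sum()))
    n = len(records)
    length_tab = pd.DataFrame(
        {"count": counts, "percent": [100.0 * c / n for c in counts]}, index=labels
    )

    exon_series = pd.Series([r.exon_count for r in records]).value_counts().sort_index()
    exon_tab = pd.DataFrame(
        {"count": exon_series, "percent": 100.0 * exon_series / n}
    )

    class_series = pd.Series([r.positional_class for r in records])
    class_counts = class_series.value_counts().reindex(
        POSITIONAL_CLASSES, fill_value=0
    )
    class_tab = pd.DataFrame(
        {"count": class_counts, "percent": 100.0 * class_counts / n}
    )
    return {"length_bins": length_tab, "exon_counts": exon_tab, "classes": class_tab}
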