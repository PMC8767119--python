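"""GTF / GFF3 reading and writing.

File coordinates (1-based inclusive) are converted to the internal 0-based
half-open convention on read and back on write, so a read->write round trip
preserves the file numbers exactly. Parsing is delegated to gffutils over an
in-memory database after a light line-level validation pass that reports
malformed lines by number.
"""

from __future__ import annotations

import contextlib
import io
from pathlib import Path

import gffutils

from ..intervals import GenomicInterval, TranscriptModel

TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "ncRNA"}


class AnnotationError(ValueError):
    pass


def _sniff_dialect(path: str | Path) -> str:
    """Return 'gff3' or 'gtf' from the first feature line's attribute syntax."""
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            if "=" in attrs and '"' not in attrs:
                return "gff3"
            return "gtf"
    return "gtf"


def _validate_lines(path: str | Path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid 1-based coordinates "
                    f"{start}..{end}"
                )
            if fields[6] not in {"+", "-"}:
                raise AnnotationError(
                    f"{path}:{lineno}: unstranded or invalid strand "
                    f"{fields[6]!r} rejected"
                )


def _attr(feature: gffutils.Feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into transcript models.

    Exon lists are assembled per transcript; transcript bounds come from the
    transcript-level record when present, otherwise from the exon span.
    The biotype is taken from a ``biotype``/``transcript_biotype``/
    ``gene_biotype`` attribute, defaulting to ``candidate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_lines(path)
    dialect = _sniff_dialect(path)
    # gffutils logs warnings for inferred features; neither applies here
    # because transcript-level records are validated as present below.
    with contextlib.redirect_stderr(io.StringIO()):
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )

    transcripts: dict[str, dict] = {}
    order: list[str] = []

    for feature in db.all_features():
        if feature.featuretype in TRANSCRIPT_TYPES:
            if dialect == "gtf":
                tid = _attr(feature, "transcript_id")
            else:
                tid = _attr(feature, "ID", "transcript_id")
            if tid is None:
                raise AnnotationError(
                    f"{path}: {feature.featuretype} record without a "
                    "transcript identifier"
                )
            gene = _attr(feature, "gene_id", "Parent", "geneID") or tid
            biotype = (
                _attr(feature, "biotype", "transcript_biotype", "gene_biotype")
                or "candidate"
            )
            entry = transcripts.setdefault(tid, {"exons": []})
            entry["interval"] = GenomicInterval(
                feature.seqid, feature.start - 1, feature.end, feature.strand
            )
            entry["gene_id"] = gene
            entry["biotype"] = biotype
            if tid not in order:
                order.append(tid)
        elif feature.featuretype == "exon":
            if dialect == "gtf":
                tid = _attr(feature, "transcript_id")
            else:
                tid = _attr(feature, "Parent", "transcript_id")
            if tid is None:
                raise AnnotationError(
                    f"{path}: exon record without a transcript identifier"
                )
            entry = transcripts.setdefault(tid, {"exons": []})
            entry["exons"].append(
                GenomicInterval(
                    feature.seqid, feature.start - 1, feature.end, feature.strand
                )
            )
            if tid not in order:
                order.append(tid)

    models = []
    for tid in order:
        entry = transcripts[tid]
        exons = sorted(entry["exons"], key=lambda e: e.start)
        interval = entry.get("interval")
        if interval is None:
            if not exons:
                continue
            interval = GenomicInterval(
                exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
            )
        for exon in exons:
            if exon.start < interval.start or exon.end > interval.end:
                raise AnnotationError(
                    f"{path}: exon [{exon.start}, {exon.end}) of {tid} "
                    "outside transcript bounds"
                )
        models.append(
            TranscriptModel(
                id=tid,
                gene_id=entry.get("gene_id", tid),
                interval=interval,
                exons=exons or [interval],
                biotype=entry.get("biotype", "candidate"),
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as handle:
        for tm in models:
            attrs = (
                f'gene_id "{tm.gene_id}"; transcript_id "{tm.id}"; '
                f'biotype "{tm.biotype}";'
            )
            iv = tm.interval
            handle.write(
                f"{iv.chrom}\tlncnet\ttranscript\t{iv.start + 1}\t{iv.end}\t."
                f"\t{iv.strand}\t.\t{attrs}\n"
            )
            for exon in tm.exons:
                handle.write(
                    f"{exon.chrom}\tlncnet\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{exon.strand}\t.\t{attrs}\n"
                )
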