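# lncnet

A tested, reusable pipeline from transcript models and expression counts to
a lncRNA–miRNA–mRNA regulatory network:

1. **lncRNA discovery** — filter cascade (same-strand exonic overlap with
   coding genes, max-FPKM < 0.5, length < 200 nt), an ORF-based
   coding-potential surrogate (≥ 100 codons ⇒ coding), and positional
   classification into lincRNA / antisense / sense / overlapping.
2. **Differential expression** — FPKM and per-million TPM normalization,
   one coherent negative-binomial pipeline (median-of-ratios size factors,
   moments dispersion, Wald test), Benjamini–Hochberg adjustment.
   Transcripts gate on |log2FC| > 1 and raw p < 0.05; miRNAs on adjusted
   p < 0.05.
3. **Target assignment** — cis (genes within 100 kb, inclusive, plus
   |Pearson r| ≥ 0.95 co-expression) and trans (genome-wide, |r| > 0.95
   strict), with distance/orientation reporting in kb.
4. **miRNA interactions** — a seed-weighted duplex scanner (mismatch 1.0,
   G:U 0.5, bulged nt 0.5, doubled at miRNA positions 2–13; expectation
   ≤ 3 ⇒ target), a three-criterion endogenous-target-mimic (eTM) caller
   (perfect Watson–Crick pairing at positions 2–8; ≤ 3 mismatches + G:U
   overall; an optional 3-nt target-side bulge only at positions 9–12),
   and precursor identification by local alignment (> 90 % identity,
   ≥ 80 % hairpin coverage).
5. **Enrichment** — upper-tail hypergeometric over-representation against
   a user-supplied gene→term map.
6. **Network assembly** — typed edges (cis, trans, miRNA target, eTM,
   precursor) merged into a tripartite network with a miRNA-anchored
   inclusion filter, exported as edge-list TSV and GraphML.
7. **Synthetic data** — a fully seeded generator that emits a toy annotated
   genome, count matrices, miRNA/hairpin sets and machine-readable planted
   truth (feature fates, co-expression partners and decoys, binding sites
   per rule class, precursor copies) so every stage can be validated
   against ground truth.

## Layout

| module | role |
| --- | --- |
| `lncnet.io` | GTF/GFF3, FASTA, count-matrix TSV, edge-list/GraphML I/O (internal coordinates 0-based half-open; DNA alphabet, U→T) |
| `lncnet.simulate` | synthetic study generator + `TruthTable` |
| `lncnet.discovery` | filter cascade, ORF surrogate, positional classes, summaries |
| `lncnet.expression` | FPKM/TPM, BH, NB Wald differential test |
| `lncnet.targets` | Pearson r, cis/trans assignment |
| `lncnet.mirna` | duplex scan, eTM caller, precursor identification |
| `lncnet.enrich` | hypergeometric enrichment |
| `lncnet.network` / `lncnet.pipeline` | network assembly, end-to-end run |

## CLI

```sh
lncnet simulate --seed 1 --out sim/                 # synthetic study + truth
lncnet discover --annotation sim/annotation.gtf \
    --transcripts sim/transcripts.fa \
    --counts sim/transcript_counts.tsv --groups sim/groups.tsv --out disc/
lncnet de --counts sim/mirna_counts.tsv --groups sim/groups.tsv \
    --group-a G1 --group-b G2 --kind miRNA --out de_mirnas.tsv
lncnet targets --annotation sim/annotation.gtf --expression fpkm.tsv \
    --dels dels.txt --degs degs.txt --out targets/
lncnet mirna --mirnas sim/mirnas.fa --transcripts sim/transcripts.fa \
    --hairpins sim/hairpins.fa --out mirna_out/
lncnet enrich --genes genes.txt --terms gene2term.tsv --out enrichment.tsv
lncnet network --edges edges.tsv --out net/
lncnet all --seed 1 --out run/                      # whole chain + manifest
```

`lncnet all` chains simulate → discover → de → targets → mirna → enrich →
network under one seed and writes a `manifest.json` with parameters and
sha256 checksums of every output; runs are byte-for-byte reproducible.
Simulation parameters can be supplied as a TOML file via `--config`
(see `lncnet/simulate/config.py` for the keys).

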