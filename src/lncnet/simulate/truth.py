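"""Machine-readable planted truth for every downstream pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FEATURE_COLUMNS = [
    "id",
    "kind",
    "positional_class",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "exons",
    "expected_fate",
    "planted_de",
    "log2fc",
]

PAIR_COLUMNS = [
    "lncrna_id",
    "gene_id",
    "pair_kind",  # cis | trans | decoy
    "distance_bp",
    "orientation",
    "achieved_r",
]

SITE_COLUMNS = [
    "mirna_id",
    "host_id",
    "host_kind",  # lncRNA | mRNA
    "rule_class",
    "start",
    "end",
    "bulge_pos",
    "bulge_len",
    "expectation",
    "target_expected",
    "etm_expected",
]

PRECURSOR_COLUMNS = [
    "lncrna_id",
    "hairpin_id",
    "n_substitutions",
    "planted_identity",
    "expected_hit",
]


@dataclass
class TruthTable:
    """Planted ground truth as four tables, written/read as plain TSV."""

    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FEATURE_COLUMNS)
    )
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PAIR_COLUMNS)
    )
    sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SITE_COLUMNS)
    )
    precursors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PRECURSOR_COLUMNS)
    )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(directory / "truth_features.tsv", sep="\t", index=False)
        self.pairs.to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)
        self.sites.to_csv(directory / "truth_sites.tsv", sep="\t", index=False)
        self.precursors.to_csv(
            directory / "truth_precursors.tsv", sep="\t", index=False
        )

    @classmethod
    def read(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        return cls(
            features=pd.read_csv(directory / "truth_features.tsv", sep="\t"),
            pairs=pd.read_csv(directory / "truth_pairs.tsv", sep="\t"),
            sites=pd.read_csv(directory / "truth_sites.tsv", sep="\t"),
            precursors=pd.read_csv(directory / "truth_precursors.tsv", sep="\t"),
        )
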