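"""Simulation configuration: one dataclass, loadable from a TOML file."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

SITE_CLASSES = (
    "target",
    "etm",
    "near_miss_seed",
    "near_miss_budget",
    "near_miss_bulge",
)


@dataclass
class SimulationConfig:
    """Every knob of the synthetic study; the seed fully determines output."""

    seed: int = 0

    # genome shape
    n_chromosomes: int = 2
    chrom_length: int = 400_000

    # annotation content
    n_coding_genes: int = 12
    n_lincrna: int = 24
    n_antisense: int = 4
    n_sense: int = 4
    n_overlapping: int = 2
    n_decoy_coding: int = 3
    n_decoy_overlap: int = 3
    n_decoy_short: int = 2
    n_decoy_low_expression: int = 2
    orf_codon_threshold: int = 100

    # count matrices
    replicates: int = 3
    group_a: str = "G1"
    group_b: str = "G2"
    de_fraction: float = 0.3
    log2fc: float = 2.0
    dispersion: float = 0.05
    mean_expression: float = 500.0
    library_size_factor: float = 1.5
    partner_latent_sd: float = 1.0

    # miRNAs and planted interactions
    n_mirnas: int = 5
    mirna_len_range: tuple[int, int] = (20, 24)
    sites_per_class: dict[str, int] = field(
        default_factory=lambda: {cls: 2 for cls in SITE_CLASSES}
    )
    n_mrna_target_sites: int = 2

    # co-expression pairs
    n_cis_pairs: int = 2
    n_trans_pairs: int = 2
    n_decoy_pairs: int = 2

    # precursors
    n_hairpins: int = 3
    hairpin_length: int = 90
    n_precursor_lncrnas: int = 2
    n_precursor_decoys: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_coding_genes",
            "n_lincrna",
            "replicates",
            "n_mirnas",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group (correlation/DE undefined)")
        lo, hi = self.mirna_len_range
        if not 18 <= lo <= hi:
            raise ValueError("miRNA lengths must be >= 18 nt")
        unknown = set(self.sites_per_class) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site classes: {sorted(unknown)}")
        needed = self.required_lincrnas()
        if self.n_lincrna < needed:
            raise ValueError(
                f"n_lincrna={self.n_lincrna} but {needed} are needed to host "
                "planted sites, precursors and co-expression pairs"
            )

    def required_lincrnas(self) -> int:
        return (
            sum(self.sites_per_class.values())
            + self.n_precursor_lncrnas
            + self.n_precursor_decoys
            + self.n_cis_pairs
            + self.n_trans_pairs
            + self.n_decoy_pairs
        )

    @property
    def sample_ids(self) -> list[str]:
        return [f"{self.group_a}_{i + 1}" for i in range(self.replicates)] + [
            f"{self.group_b}_{i + 1}" for i in range(self.replicates)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: (self.group_a if s.startswith(self.group_a + "_") else self.group_b)
            for s in self.sample_ids
        }


def load_config(path: str | Path) -> SimulationConfig:
    """Load a TOML key-value file; unknown keys are rejected."""
    with open(path, "rb") as handle:
        raw = tomllib.load(handle)
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "mirna_len_range" in raw:
        raw["mirna_len_range"] = tuple(raw["mirna_len_range"])
    return SimulationConfig(**raw)
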