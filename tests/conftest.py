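import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncnet.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study shared across the suite (seed-pinned)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Trimmed config for per-seed loops (fewer hosted features)."""
    return dict(
        n_coding_genes=10,
        n_lincrna=14,
        n_antisense=2,
        n_sense=2,
        n_overlapping=1,
        n_decoy_coding=1,
        n_decoy_overlap=1,
        n_decoy_short=1,
        n_decoy_low_expression=1,
        sites_per_class={cls: 1 for cls in
                         ("target", "etm", "near_miss_seed",
                          "near_miss_budget", "near_miss_bulge")},
        n_mrna_target_sites=1,
        n_cis_pairs=2,
        n_trans_pairs=2,
        n_decoy_pairs=2,
        n_precursor_lncrnas=1,
        n_precursor_decoys=1,
        chrom_length=250_000,
    )


def make_expression(values, sample_ids=None, groups=None, unit="count"):
    """Tiny helper to build an ExpressionMatrix from a dict of rows."""
    import pandas as pd

    from lncnet.io.matrix import ExpressionMatrix

    frame = pd.DataFrame.from_dict(values, orient="index")
    if sample_ids is not None:
        frame.columns = sample_ids
    return ExpressionMatrix(frame, unit=unit, groups=groups or {})
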