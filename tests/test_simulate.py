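import numpy as np
import pandas as pd
import pytest

from lncnet.discovery import longest_orf
from lncnet.expression import compute_fpkm
from lncnet.mirna import duplex_scan, etm_scan
from lncnet.simulate import (
    SimulationConfig,
    load_config,
    plant_mirna_sites,
    simulate_genome,
    simulate_study,
)
from lncnet.simulate.counts import nb_draw
from lncnet.simulate.genome import PlacementError, random_seq
from lncnet.simulate.sites import make_mirnas
from lncnet.targets import pearson_r


class TestConfig:
    def test_replicates_floor(self):
        with pytest.raises(ValueError, match="replicates"):
            SimulationConfig(replicates=1)

    def test_lincrna_budget_enforced(self):
        with pytest.raises(ValueError, match="n_lincrna"):
            SimulationConfig(n_lincrna=2)

    def test_unknown_toml_key_rejected(self, tmp_path):
        path = tmp_path / "c.toml"
        path.write_text("seed = 3\nbogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_config(path)

    def test_toml_round_trip(self, tmp_path):
        path = tmp_path / "c.toml"
        path.write_text("seed = 9\nchrom_length = 300000\n")
        config = load_config(path)
        assert config.seed == 9 and config.chrom_length == 300_000


class TestSimulateGenome:
    def test_chromosome_too_short(self):
        with pytest.raises(PlacementError, match="chrom_length"):
            config = SimulationConfig(chrom_length=20_000, n_chromosomes=1)
            simulate_genome(config)

    def test_determinism_byte_identical(self, tmp_path, small_config):
        from lncnet.io.annotation import write_gtf
        from lncnet.io.fasta import write_fasta

        paths = []
        for name in ("one", "two"):
            study = simulate_study(SimulationConfig(seed=5, **small_config))
            fa = tmp_path / f"{name}.fa"
            gtf = tmp_path / f"{name}.gtf"
            write_fasta(study.sim.genome_strings(), fa)
            write_gtf(study.sim.models, gtf)
            paths.append((fa.read_bytes(), gtf.read_bytes()))
        assert paths[0] == paths[1]

    def test_planted_classes_by_construction(self, study):
        feats = study.truth.features
        by_id = {t.id: t for t in study.sim.models}
        genes = study.sim.genes
        for _, row in feats[feats["kind"] == "lncRNA_candidate"].iterrows():
            lnc = by_id[row["id"]]
            overlapping_genes = [
                g for g in genes if g.interval.overlaps(lnc.interval)
            ]
            if row["positional_class"] == "lincRNA":
                assert not overlapping_genes
                # spec example: distance to nearest gene > 0
                same_chrom = [g for g in genes if g.chrom == lnc.chrom]
                assert min(
                    lnc.interval.distance_to(g.interval) for g in same_chrom
                ) > 0
            elif row["positional_class"] == "antisense":
                assert any(g.strand != lnc.strand for g in overlapping_genes)
            elif row["positional_class"] == "overlapping":
                assert any(
                    lnc.interval.contains(g.interval) for g in overlapping_genes
                )
            elif row["positional_class"] == "sense":
                assert any(g.strand == lnc.strand for g in overlapping_genes)

    def test_lengths_span_all_four_bins(self, study):
        lengths = study.truth.features.query(
            "kind == 'lncRNA_candidate'"
        )["length"]
        assert (lengths.between(200, 600)).any()
        assert (lengths.between(601, 1000)).any()
        assert (lengths.between(1001, 1400)).any()
        assert (lengths > 1400).any()

    def test_no_planted_survivor_has_orf(self, study):
        threshold = study.config.orf_codon_threshold
        survivors = study.truth.features.query("expected_fate == 'survivor'")
        for fid in survivors["id"]:
            assert longest_orf(study.transcript_seqs[fid]) < threshold


class TestSimulateCounts:
    def test_zero_dispersion_zero_lfc_poisson_limit(self):
        rng = np.random.default_rng(0)
        mu = np.full((200, 6), 500.0)
        counts = nb_draw(rng, mu, 0.0)
        a, b = counts[:, :3].mean(), counts[:, 3:].mean()
        # Poisson noise on 200x3 cells of mean 500: sem ~ 0.9
        assert abs(a - b) < 5

    def test_planted_lfc_recovered_empirically(self):
        """>= 90% of planted log2FC=2 features land within +-0.5 (spec's
        Monte-Carlo derived bound at mean 500, dispersion 0.05, 3v3)."""
        rng = np.random.default_rng(11)
        n = 250
        mu_a = np.full((n, 3), 500.0 * 2.0)
        mu_b = np.full((n, 3), 500.0 / 2.0)
        a = nb_draw(rng, mu_a, 0.05)
        b = nb_draw(rng, mu_b, 0.05)
        ratio = np.log2(a.mean(axis=1) / b.mean(axis=1))
        assert np.mean(np.abs(ratio - 2.0) <= 0.5) >= 0.90

    def test_partner_correlations_honoured(self, study):
        lengths = dict(
            zip(study.truth.features["id"], study.truth.features["length"])
        )
        fpkm = compute_fpkm(study.transcript_counts, lengths).values
        for _, row in study.truth.pairs.iterrows():
            r = pearson_r(
                fpkm.loc[row["lncrna_id"]].to_numpy(),
                fpkm.loc[row["gene_id"]].to_numpy(),
            )
            assert r == pytest.approx(row["achieved_r"], abs=1e-9)
            if row["pair_kind"] == "decoy":
                assert abs(r) <= 0.5
            else:
                assert r >= 0.97

    def test_identical_seed_identical_matrices(self, small_config):
        a = simulate_study(SimulationConfig(seed=3, **small_config))
        b = simulate_study(SimulationConfig(seed=3, **small_config))
        pd.testing.assert_frame_equal(
            a.transcript_counts.values, b.transcript_counts.values
        )
        pd.testing.assert_frame_equal(a.mirna_counts.values, b.mirna_counts.values)

    def test_low_expression_decoys_below_gate(self, study):
        lengths = dict(
            zip(study.truth.features["id"], study.truth.features["length"])
        )
        fpkm = compute_fpkm(study.transcript_counts, lengths).values
        low = study.truth.features.query("kind == 'decoy_low_expression'")["id"]
        for fid in low:
            assert fpkm.loc[fid].max() < 0.5


class TestPlantSites:
    def test_planted_site_states_verifiable(self, study):
        """Every TruthTable site claim re-checks against the sequences."""
        for _, row in study.truth.sites.iterrows():
            host = study.transcript_seqs[row["host_id"]]
            mirna = study.mirnas[row["mirna_id"]]
            scan = duplex_scan(mirna, host)
            etm = etm_scan(mirna, host)
            in_window = [
                h for h in scan
                if h.start >= row["start"] and h.end <= row["end"]
            ]
            assert bool(in_window) == bool(row["target_expected"])
            assert bool(etm) == bool(row["etm_expected"])

    def test_no_sites_planted_no_etm_calls(self, rng):
        """Zero planted sites -> empty scan (checked against the oracle)."""
        from oracles import duplex_oracle

        mirnas = make_mirnas(SimulationConfig(n_mirnas=2), rng)
        host = random_seq(rng, 800)
        for mid, mseq in mirnas.items():
            hits = duplex_scan(mseq, host)
            assert {
                (h.start, h.end, h.bulge_pos, h.bulge_len, h.states, h.expectation)
                for h in hits
            } == duplex_oracle(mseq, host)
            assert etm_scan(mseq, host) == []

    def test_host_too_short_raises(self, rng):
        mirnas = {"miR1": random_seq(rng, 21)}
        with pytest.raises(ValueError, match="too short"):
            plant_mirna_sites(
                {"h": random_seq(rng, 30)}, {"h": "lncRNA"}, mirnas,
                [("h", "miR1", "target")], rng,
            )

    def test_host_reuse_rejected(self, rng):
        mirnas = {"miR1": random_seq(rng, 21)}
        plan = [("h", "miR1", "target"), ("h", "miR1", "etm")]
        with pytest.raises(ValueError, match="twice"):
            plant_mirna_sites(
                {"h": random_seq(rng, 400)}, {"h": "lncRNA"}, mirnas, plan, rng
            )


class TestTruthSchema:
    def test_schema_stable_across_seeds(self, tmp_path, small_config):
        a = simulate_study(SimulationConfig(seed=1, **small_config))
        b = simulate_study(SimulationConfig(seed=2, **small_config))
        for attr in ("features", "pairs", "sites", "precursors"):
            assert list(getattr(a.truth, attr).columns) == list(
                getattr(b.truth, attr).columns
            )

    def test_truth_round_trip(self, tmp_path, study):
        from lncnet.simulate import TruthTable

        study.truth.write(tmp_path)
        loaded = TruthTable.read(tmp_path)
        assert len(loaded.features) == len(study.truth.features)
        assert set(loaded.sites["rule_class"]) == set(
            study.truth.sites["rule_class"]
        )

    def test_every_truth_id_in_annotation(self, study):
        model_ids = {t.id for t in study.sim.models}
        assert set(study.truth.features["id"]) <= model_ids
        assert set(study.truth.sites["host_id"]) <= model_ids
        assert set(study.truth.precursors["lncrna_id"]) <= model_ids
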