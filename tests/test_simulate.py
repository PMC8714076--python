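import collections
import filecmp
import json
import os

import numpy as np
import pandas as pd
import pytest

from chromlink.de import DEGThresholds, call_degs, filter_expressed
from chromlink.replication import ReplicationConfig, confirm_replicated
from chromlink.simulate import SimulationConfig, emit, simulate, simulate_genome


FAST = dict(with_sequence=False, with_conservation=False)


def call_deg_frame(data, table):
    sample_cols = [c for c in table.columns if c.startswith("s") and c[1:].isdigit()]
    th = DEGThresholds()
    retained = filter_expressed(
        table.set_index("gene_id")[sample_cols], table.set_index("gene_id")["chrom"], th
    )
    return call_degs(table, retained, th)


class TestGenome:
    def test_gene_count_and_no_body_overlap(self):
        genome = simulate_genome(SimulationConfig(seed=4, n_genes=100))
        assert len(genome.genes) == 100
        by_chrom = collections.defaultdict(list)
        for g in genome.genes:
            by_chrom[g.chrom].append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_every_tss_in_exactly_one_tad(self):
        genome = simulate_genome(SimulationConfig(seed=4))
        for g in genome.genes:
            containing = [t for t in genome.tads if t.chrom == g.chrom and t.interval.contains(g.tss)]
            assert len(containing) == 1

    def test_tads_tile_chromosomes(self):
        genome = simulate_genome(SimulationConfig(seed=4))
        by_chrom = collections.defaultdict(list)
        for t in genome.tads:
            by_chrom[t.chrom].append(t.interval)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            assert ivs[0].start == 0
            assert ivs[-1].end == genome.chrom_sizes[chrom]
            assert all(a.end == b.start for a, b in zip(ivs, ivs[1:]))

    def test_same_seed_identical(self):
        a = simulate_genome(SimulationConfig(seed=9))
        b = simulate_genome(SimulationConfig(seed=9))
        assert a.genes == b.genes and a.tads == b.tads


class TestLandscape:
    def test_noise_free_config_recovers_exactly_planted_peaks(self):
        cfg = SimulationConfig(seed=2, n_noise_peaks_per_replicate=0, **FAST)
        data = simulate(cfg)
        confirmed = confirm_replicated(data.replicate_peaks, ReplicationConfig())
        assert len(confirmed) == len(data.truth["true_peaks"])
        summits = sorted((c.chrom, c.summit) for c in confirmed)
        planted = sorted((tp["chrom"], tp["summit"]) for tp in data.truth["true_peaks"])
        # replicate jitter keeps intervals overlapping; the best-p summit
        # stays at the planted position
        assert summits == planted

    def test_true_peaks_inside_open_chromatin_and_within_1mb(self, simdata):
        genes = {g.gene_id: g for g in simdata.genome.genes}
        for tp in simdata.truth["true_peaks"]:
            g = genes[tp["gene"]]
            assert abs(tp["summit"] - g.tss) <= 1_000_000
            assert any(
                iv.chrom == tp["chrom"] and iv.contains(tp["summit"]) for iv in simdata.atac
            )

    def test_conservation_bump_at_true_summits(self, simdata):
        track = simdata.conservation
        cfg = SimulationConfig()
        for tp in simdata.truth["true_peaks"][:10]:
            assert track.scores[tp["chrom"]][tp["summit"]] == pytest.approx(cfg.conservation_peak, abs=1e-5)

    def test_planted_fraction_bookkeeping_is_consistent(self, simdata):
        bins = collections.Counter(tp["realized_bin"] for tp in simdata.truth["true_peaks"])
        assert sum(bins.values()) == len(simdata.truth["true_peaks"])


class TestDETables:
    def test_full_concordance_yields_zero_discordant(self):
        from chromlink.crosstalk import shared_degs

        cfg = SimulationConfig(seed=5, concordance_frac=1.0, **FAST)
        data = simulate(cfg)
        degs_a = call_deg_frame(data, data.de_table_a)
        degs_b = call_deg_frame(data, data.de_table_b)
        shared = shared_degs(degs_a, degs_b)
        planted_shared = set(data.truth["shared_planted"])
        among_planted = shared[shared["gene_id"].isin(planted_shared)]
        assert (among_planted["concordance"] == "concordant").all()

    def test_planted_genes_recovered_as_degs(self):
        hits = total = 0
        for seed in range(5):
            data = simulate(SimulationConfig(seed=seed, **FAST))
            degs = call_deg_frame(data, data.de_table_a)
            called = set(degs[degs["direction"] != "unchanged"]["gene_id"])
            planted = set(data.truth["planted_de_a"])
            hits += len(called & planted)
            total += len(planted)
        assert hits / total >= 0.95

    def test_null_only_table_yields_no_degs(self):
        cfg = SimulationConfig(seed=6, n_true_targets=0, n_de_genes=0, n_shared_planted=0, **FAST)
        data = simulate(cfg)
        degs = call_deg_frame(data, data.de_table_a)
        assert (degs["direction"] == "unchanged").all()

    def test_low_expressed_genes_filtered(self, simdata):
        table = simdata.de_table_a
        sample_cols = [c for c in table.columns if c.startswith("s")]
        retained = filter_expressed(
            table.set_index("gene_id")[sample_cols], table.set_index("gene_id")["chrom"], DEGThresholds()
        )
        assert retained.isdisjoint(simdata.truth["low_expressed"])


class TestEmission:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=3, **FAST)
        emit(simulate(cfg), str(tmp_path / "a"))
        emit(simulate(cfg), str(tmp_path / "b"))
        files = sorted(os.listdir(tmp_path / "a"))
        assert files
        for f in files:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f

    def test_truth_manifest_written_with_targets(self, tmp_path):
        cfg = SimulationConfig(seed=3, **FAST)
        data = simulate(cfg)
        emit(data, str(tmp_path))
        truth = json.load(open(tmp_path / "truth.json"))
        assert truth["target_genes"] == data.truth["target_genes"]
        assert len(truth["true_peaks"]) == len(data.truth["true_peaks"])

    def test_emitted_files_parse_back(self, emitted_dataset):
        from chromlink import io as cio

        data, paths = emitted_dataset
        peaks = cio.read_narrowpeak(paths["chip_rep1.narrowPeak"])
        assert len(peaks) == len(data.replicate_peaks[0])
        genes = cio.read_gene_models(paths["genes.tsv"], format="tsv")
        assert genes == data.genome.genes
        tads = cio.read_tads(paths["tads.bed"])
        assert len(tads) == len(data.genome.tads)
        pwms = cio.read_pwms(paths["motifs.txt"])
        assert [p.motif_id for p in pwms] == [p.motif_id for p in data.pwms]
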