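import numpy as np
import pandas as pd
import pytest

from polvel.genes import GeneModel
from polvel.sim import (ConditionSpec, KineticsSpec, PolTrajectory,
                        emit_chip, emit_dataset, emit_spikeins,
                        engaged_positions, fragment_intervals,
                        labeled_interval, labeled_intervals, make_genome,
                        positions_at, simulate_trajectories, SpikeInSpec,
                        SamplingSpec, write_dataset)

CTRL = ConditionSpec("control", 1.0, 0.0)


def const_kin(rate, v, length):
    return KineticsSpec.constant(rate, v, length)


class TestTrajectories:
    def test_linear_motion_at_constant_velocity(self):
        kin = const_kin(1.0, 1.0, 60_000)
        inits = np.array([0.0, 10.0, 20.0])
        offs = positions_at(inits, 25.0, kin, CTRL)
        assert offs.tolist() == [25_000.0, 15_000.0, 5_000.0]

    def test_piecewise_integration_across_onset(self):
        kin = const_kin(1.0, 1.0, 60_000)
        cond = ConditionSpec("slow", 0.5, 20.0)
        off = positions_at(np.array([10.0]), 30.0, kin, cond)[0]
        assert off == pytest.approx((20 - 10) * 1000 + (30 - 20) * 500)

    def test_multi_piece_velocity_profile(self):
        # 1 kb/min over first 10 kb, then 2 kb/min: 10 min + 5 min to reach 20 kb
        kin = KineticsSpec(1.0, (0.0, 10_000.0, 60_000.0), (1.0, 2.0))
        off = positions_at(np.array([0.0]), 15.0, kin, CTRL)[0]
        assert off == pytest.approx(20_000.0)

    def test_zero_initiation_rate_gives_no_trajectories(self):
        gene = GeneModel("g", "chr1", 0, 60_000, "+")
        trajs = simulate_trajectories(gene, const_kin(0.0, 1.0, 60_000), CTRL,
                                      horizon=100.0, seed=1)
        assert trajs == []

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KineticsSpec(1.0, (0.0, 100.0), (0.0,))

    def test_nonpositive_horizon_rejected(self):
        gene = GeneModel("g", "chr1", 0, 1000, "+")
        with pytest.raises(ValueError, match="horizon"):
            simulate_trajectories(gene, const_kin(1.0, 1.0, 1000), CTRL,
                                  horizon=0.0, seed=1)

    def test_initiation_rate_matches_poisson_expectation(self):
        gene = GeneModel("g", "chr1", 0, 10_000, "+")
        kin = const_kin(2.0, 1.0, 10_000)
        counts = [len(simulate_trajectories(gene, kin, CTRL, horizon=50.0, seed=s))
                  for s in range(200)]
        mean = np.mean(counts)  # expected 100, SE = 10/sqrt(200)
        assert abs(mean - 100) < 3 * 10 / np.sqrt(200)


class TestEngagedPositions:
    def test_plus_strand_coordinate_map(self, plus_gene):
        kin = const_kin(1.0, 1.0, plus_gene.length)
        trajs = [PolTrajectory(0.0, kin, CTRL)]
        tags = engaged_positions(trajs, plus_gene, t=25.0)
        assert tags.iloc[0]["start"] == 26_000 and tags.iloc[0]["end"] == 26_001
        assert tags.iloc[0]["strand"] == "+"

    def test_minus_strand_reflection(self, minus_gene):
        kin = const_kin(1.0, 1.0, minus_gene.length)
        tags = engaged_positions([PolTrajectory(0.0, kin, CTRL)], minus_gene, t=25.0)
        assert tags.iloc[0]["start"] == 60_999 - 25_000

    def test_terminated_trajectory_emits_nothing(self, plus_gene):
        kin = const_kin(1.0, 1.0, plus_gene.length)  # 60 kb at 1 kb/min -> 60 min
        tags = engaged_positions([PolTrajectory(0.0, kin, CTRL)], plus_gene, t=61.0)
        assert len(tags) == 0


class TestLabeledIntervals:
    def test_window_mid_transcription(self, plus_gene):
        kin = const_kin(1.0, 1.0, plus_gene.length)
        got = labeled_interval(PolTrajectory(58.0, kin, CTRL), plus_gene, (60.0, 65.0))
        assert got == ("chr1", 1000 + 2000, 1000 + 7000, "+")

    def test_initiation_after_window_is_empty(self, plus_gene):
        kin = const_kin(1.0, 1.0, plus_gene.length)
        assert labeled_interval(PolTrajectory(66.0, kin, CTRL), plus_gene, (60.0, 65.0)) is None

    def test_clip_at_initiation(self, plus_gene):
        kin = const_kin(1.0, 1.0, plus_gene.length)
        got = labeled_interval(PolTrajectory(62.0, kin, CTRL), plus_gene, (60.0, 65.0))
        assert got == ("chr1", 1000, 1000 + 3000, "+")

    def test_minus_strand_interval_orientation(self, minus_gene):
        kin = const_kin(1.0, 1.0, minus_gene.length)
        df = labeled_intervals(np.array([58.0]), minus_gene, kin, CTRL, 60.0, 65.0)
        # offsets [2000, 7000) map to genomic [end-7000, end-2000)
        assert df.iloc[0]["start"] == 61_000 - 7000
        assert df.iloc[0]["end"] == 61_000 - 2000


class TestFragmentSampling:
    def test_empty_interval_set(self):
        from polvel.io import empty_records
        out = fragment_intervals(empty_records(), 150, 300, 10.0, seed=0)
        assert len(out) == 0

    def test_expected_count_matches_poisson_rate(self):
        # one 5 kb interval at 10 fragments/kb -> expected 50 per draw
        from conftest import records
        ivl = records([("chr1", 0, 5000, "i", "+")])
        ns = [len(fragment_intervals(ivl, 100, 200, 10.0, seed=s)) for s in range(1000)]
        se = np.sqrt(50 / 1000)
        assert abs(np.mean(ns) - 50) < 3 * se

    def test_fragments_contained_in_source_intervals(self):
        from conftest import records
        ivl = records([("chr1", 100, 600, "a", "+"), ("chr2", 50, 1050, "b", "-")])
        frags = fragment_intervals(ivl, 150, 300, 50.0, seed=3)
        assert len(frags) > 0
        for row in frags.itertuples(index=False):
            src = ivl[ivl["chrom"] == row.chrom].iloc[0]
            assert src["start"] <= row.start < row.end <= src["end"]
            assert row.strand == src["strand"]

    def test_bad_fragment_bounds_rejected(self):
        from conftest import records
        ivl = records([("chr1", 0, 1000, "i", "+")])
        with pytest.raises(ValueError, match="fragment_min"):
            fragment_intervals(ivl, 300, 150, 10.0, seed=0)


class TestSpikeIns:
    def test_labeled_counts_scale_with_library(self):
        sp = [SpikeInSpec("s1", 1000, 1000.0, True)]
        ns = [len(emit_spikeins(sp, 2.0, seed=s)) for s in range(500)]
        se = np.sqrt(2000 / 500)
        assert abs(np.mean(ns) - 2000) < 3 * se

    def test_unlabeled_without_leakage_yield_nothing(self):
        sp = [SpikeInSpec("u1", 1000, 5000.0, False)]
        assert len(emit_spikeins(sp, 1.0, seed=0, leakage=0.0)) == 0

    def test_count_ratio_tracks_scale_ratio(self):
        sp = [SpikeInSpec("s1", 1000, 5000.0, True)]
        n1 = np.mean([len(emit_spikeins(sp, 1.0, seed=s)) for s in range(200)])
        n2 = np.mean([len(emit_spikeins(sp, 2.0, seed=1000 + s)) for s in range(200)])
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="library_scale"):
            emit_spikeins([SpikeInSpec("s", 100, 10.0, True)], 0.0, seed=0)


class TestChip:
    def test_background_counts_follow_scales(self):
        nt = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        n1 = np.mean([len(emit_chip(None, 10.0, nt, seed=s, library_scale=1.0))
                      for s in range(100)])
        n3 = np.mean([len(emit_chip(None, 10.0, nt, seed=500 + s, library_scale=3.0))
                      for s in range(100)])
        assert n3 / n1 == pytest.approx(3.0, rel=0.05)

    def test_zero_everything_rejected(self):
        with pytest.raises(ValueError, match="signal block or background"):
            emit_chip(None, 0.0, pd.DataFrame(), seed=0)

    def test_block_signal_lands_in_gene_bodies(self):
        blocks = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [40_000],
                               "rate_per_kb": [20.0]})
        nt = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [60_000]})
        frags = emit_chip(blocks, 0.0, nt, seed=2)
        inside = ((frags["start"] >= 10_000) & (frags["end"] <= 40_000)).mean()
        assert inside >= 0.95
        assert (frags["strand"] == ".").all()


@pytest.fixture(scope="module")
def tiny():
    genome = make_genome(4, 5000, 20_000, 10_000, 1, seed=5)
    kin = {g.gene_id: const_kin(2.0, 2.0, g.length) for g in genome.genes}
    conds = [ConditionSpec("control", 1.0), ConditionSpec("depleted", 0.5)]
    samp = SamplingSpec(replicates=1, warmup=30.0)
    return genome, kin, conds, samp


class TestDataset:

    def test_rerun_is_byte_identical(self, tiny, tmp_path):
        genome, kin, conds, samp = tiny
        for sub in ("a", "b"):
            ds = emit_dataset(genome, kin, conds, samp, seed=9)
            write_dataset(ds, tmp_path / sub)
        a, b = tmp_path / "a", tmp_path / "b"
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_truth_velocity_ratio_matches_condition_factor(self, tiny):
        genome, kin, conds, samp = tiny
        ds = emit_dataset(genome, kin, conds, samp, seed=9)
        t = ds.truth.genes.pivot(index="gene_id", columns="condition",
                                 values="mean_velocity_kb_min")
        assert np.allclose(t["depleted"] / t["control"], 0.5)

    def test_empty_genome_produces_valid_empty_files(self, tmp_path):
        genome = make_genome(0, seed=1)
        ds = emit_dataset(genome, {}, [ConditionSpec("control", 1.0)],
                          SamplingSpec(replicates=1, warmup=1.0,
                                       chip_background_per_kb=0.0), seed=4,
                          assays=("ttseq", "mnet"))
        write_dataset(ds, tmp_path)
        from polvel.io import read_bed6
        tt = read_bed6(tmp_path / "control_rep1.ttseq.bed")
        # only spike-in fragments, no genomic ones
        assert set(tt["chrom"]).issubset({s.spike_id for s in genome.spikeins})


class TestKineticLaws:
    """Steady-state occupancy and pulse laws, against brute-force expectation."""

    def _steady_tags_per_bin(self, v, seed, n_genes=100, rate=4.0):
        genome = make_genome(n_genes, 30_000, 30_001, 10_000, 1, seed=7)
        kin = {g.gene_id: const_kin(rate, v, g.length) for g in genome.genes}
        cond = ConditionSpec("c", 1.0, 0.0)
        samp = SamplingSpec(replicates=1, mnet_tags_per_pol=2.0, warmup=None)
        ds = emit_dataset(genome, kin, [cond], samp, seed=seed, assays=("mnet",))
        tags = ds.mnet["c_rep1"]
        tags = tags[tags["end"] - tags["start"] == 1]
        n_bins = sum(g.length // 50 for g in genome.genes)
        genomic = tags[tags["chrom"].str.startswith("chr")]
        return len(genomic) / n_bins

    def test_halving_velocity_doubles_bin_occupancy(self):
        fast = self._steady_tags_per_bin(2.0, seed=21)
        slow = self._steady_tags_per_bin(1.0, seed=22)
        # expectation: I * (50 bp / v) * tags_per_pol; ratio 2 within 5%
        assert slow / fast == pytest.approx(2.0, rel=0.05)
        assert fast == pytest.approx(4.0 * 50 / 2000 * 2.0, rel=0.05)

    def test_labeled_bases_independent_of_velocity(self):
        def labeled_bases(v, seed):
            genome = make_genome(40, 30_000, 30_001, 10_000, 1, seed=7)
            kin = {g.gene_id: const_kin(1.0, v, g.length) for g in genome.genes}
            cond = ConditionSpec("c", 1.0, 0.0)
            total = 0.0
            rng = np.random.default_rng(seed)
            for g in genome.genes:
                k = kin[g.gene_id]
                from polvel.sim import _initiation_times
                init = _initiation_times(rng, k.initiation_rate, -60.0, 65.0)
                ivls = labeled_intervals(init, g, k, cond, 60.0, 65.0)
                total += float((ivls["end"] - ivls["start"]).sum()) if len(ivls) else 0.0
            return total

        b_fast = np.mean([labeled_bases(2.0, s) for s in range(8)])
        b_slow = np.mean([labeled_bases(1.0, 100 + s) for s in range(8)])
        # expectation: I * duration per position -> equal totals within 5%
        assert b_fast / b_slow == pytest.approx(1.0, abs=0.05)
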