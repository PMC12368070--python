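import numpy as np
import pandas as pd
import pytest

from polvel.genes import GeneModel
from polvel.quantify import (count_features, count_in_regions,
                             fragment_midpoints, last_base_positions,
                             rpk_and_filter)
from polvel.tracks import StrandedTrack, bin_track, coverage_track

from conftest import records


class TestTagConventions:
    def test_last_base_is_three_prime_end(self):
        frags = records([("chr1", 100, 110, "s", "+"), ("chr1", 100, 110, "s", "-")])
        tags = last_base_positions(frags)
        assert tags["start"].tolist() == [109, 100]
        assert (tags["end"] - tags["start"] == 1).all()

    def test_width_one_fragment_maps_to_itself(self):
        frags = records([("chr1", 55, 56, "s", "+")])
        assert last_base_positions(frags)["start"].tolist() == [55]

    def test_unstranded_fragment_rejected(self):
        with pytest.raises(ValueError, match="stranded"):
            last_base_positions(records([("chr1", 0, 10, "s", ".")]))

    def test_midpoint_convention(self):
        frags = records([("chr1", 100, 110, "s", "+"), ("chr1", 100, 105, "s", "-")])
        tags = fragment_midpoints(frags)
        assert tags["start"].tolist() == [105, 102]
        assert len(tags) == len(frags)
        assert tags["strand"].tolist() == ["+", "-"]


class TestCoverage:
    sizes = {"chr1": 400}

    def test_tags_accumulate(self):
        tags = records([("chr1", 105, 106, "s", "+")] * 2)
        t = coverage_track(tags, self.sizes)
        assert t.get("chr1", "+")[105] == 2

    def test_fragment_mass_conserved(self):
        frags = records([("chr1", 0, 50, "s", "+"), ("chr1", 100, 250, "s", "+")])
        t = coverage_track(frags, self.sizes)
        assert t.get("chr1", "+").sum() == 200

    def test_empty_input_empty_track(self):
        from polvel.io import empty_records
        t = coverage_track(empty_records(), self.sizes)
        assert t.total() == 0

    def test_binning_conserves_mass_and_places_bins(self):
        tags = records([("chr1", 105, 106, "s", "+")])
        per_base = coverage_track(tags, self.sizes)
        binned = bin_track(per_base, 50)
        assert binned.get("chr1", "+")[2] == 1
        assert binned.get("chr1", "+").sum() == per_base.get("chr1", "+").sum()

    def test_direct_binned_equals_bin_of_per_base(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 350, 200)
        frags = records([("chr1", int(s), int(s) + int(w), "s", "+")
                         for s, w in zip(starts, rng.integers(1, 40, 200))])
        frags["end"] = frags["end"].clip(upper=400)
        direct = coverage_track(frags, self.sizes, bin_width=50, per_base=False)
        indirect = bin_track(coverage_track(frags, self.sizes), 50)
        assert direct.allclose(indirect)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin width"):
            bin_track(StrandedTrack(resolution=1, chrom_sizes=self.sizes), 0)


def brute_force_intersection_not_empty(rec_start, rec_end, rec_strand, genes,
                                       strand_specific=True):
    """Literal per-base implementation of the assignment mode: collect the
    feature set of every base, drop empty sets, intersect."""
    sets = []
    for pos in range(rec_start, rec_end):
        s = {g.gene_id for g in genes
             if g.start <= pos < g.end
             and (not strand_specific or g.strand == rec_strand)}
        if s:
            sets.append(s)
    if not sets:
        return None  # unassigned
    inter = set.intersection(*sets)
    return inter.pop() if len(inter) == 1 else "__ambiguous__"


class TestIntersectionNotEmpty:
    def test_simple_tag_in_gene(self, toy_genes):
        tags = records([("chr1", 109, 110, "s1", "+")])
        ct = count_features(tags, toy_genes)
        assert ct.counts.loc["gA", "s1"] == 1

    def test_wrong_strand_not_counted(self, toy_genes):
        tags = records([("chr1", 109, 110, "s1", "-")])
        ct = count_features(tags, toy_genes)
        assert ct.counts["s1"].sum() == 0
        assert ct.unassigned["s1"] == 1

    def test_tag_in_shared_region_is_ambiguous(self, toy_genes):
        tags = records([("chr1", 450, 451, "s1", "+")])  # inside both gA and gB
        ct = count_features(tags, toy_genes)
        assert ct.counts["s1"].sum() == 0
        assert ct.ambiguous["s1"] == 1

    def test_fragment_rescued_by_unique_base(self, toy_genes):
        # spans shared [400,500) and gA-only [300,400): unique overlap -> gA
        frags = records([("chr1", 350, 450, "s1", "+")])
        ct = count_features(frags, toy_genes)
        assert ct.counts.loc["gA", "s1"] == 1

    def test_matches_brute_force_on_overlapping_toy_set(self, toy_genes):
        rng = np.random.default_rng(42)
        rows = []
        for _ in range(300):
            s = int(rng.integers(0, 1600))
            w = int(rng.integers(1, 200))
            strand = rng.choice(["+", "-"])
            rows.append(("chr1", s, s + w, "s1", strand))
        recs = records(rows)
        ct = count_features(recs, toy_genes)
        exp_counts = {g.gene_id: 0 for g in toy_genes}
        exp_amb = exp_unas = 0
        for r in rows:
            got = brute_force_intersection_not_empty(r[1], r[2], r[4], toy_genes)
            if got is None:
                exp_unas += 1
            elif got == "__ambiguous__":
                exp_amb += 1
            else:
                exp_counts[got] += 1
        assert ct.counts["s1"].to_dict() == exp_counts
        assert ct.ambiguous["s1"] == exp_amb
        assert ct.unassigned["s1"] == exp_unas

    def test_record_conservation(self, toy_genes):
        rng = np.random.default_rng(7)
        rows = [("chr1", int(s), int(s) + int(w), f"s{i % 2}", rng.choice(["+", "-"]))
                for i, (s, w) in enumerate(zip(rng.integers(0, 1500, 500),
                                               rng.integers(1, 100, 500)))]
        recs = records(rows)
        ct = count_features(recs, toy_genes)
        assert ct.conservation_ok(recs["name"].value_counts().to_dict())

    def test_equals_naive_counting_on_nonoverlapping_genes(self):
        genes = [GeneModel("g1", "chr1", 0, 500, "+"),
                 GeneModel("g2", "chr1", 600, 1200, "+"),
                 GeneModel("g3", "chr1", 300, 800, "-")]
        rng = np.random.default_rng(11)
        rows = [("chr1", int(s), int(s) + int(w), "s1", rng.choice(["+", "-"]))
                for s, w in zip(rng.integers(0, 1300, 400), rng.integers(1, 150, 400))]
        recs = records(rows)
        ct = count_features(recs, genes)
        for g in genes:
            naive = 0
            for r in rows:
                if r[4] != g.strand:
                    continue
                hits = [h for h in genes
                        if h.strand == r[4] and r[1] < h.end and r[2] > h.start]
                if len(hits) == 1 and hits[0].gene_id == g.gene_id:
                    naive += 1
            assert ct.counts.loc[g.gene_id, "s1"] == naive


class TestRegionCounting:
    def test_counts_tags_inside_region_same_strand(self):
        tags = records([("chr1", 150, 151, "s1", "+"), ("chr1", 150, 151, "s1", "-"),
                        ("chr1", 99, 100, "s1", "+")])
        out = count_in_regions(tags, [("r1", "chr1", 100, 200, "+")])
        assert out.loc["r1", "s1"] == 1


class TestExpressionFilter:
    genes = [GeneModel("g1", "chr1", 0, 5000, "+"),
             GeneModel("g2", "chr1", 10_000, 12_000, "+"),
             GeneModel("g3", "chr1", 11_000, 14_000, "-")]  # overlaps g2

    def test_rpk_threshold_strict(self):
        counts = pd.DataFrame({"s1": [100, 20, 30], "s2": [100, 20, 30]},
                              index=["g1", "g2", "g3"])
        kept = rpk_and_filter(counts, self.genes, threshold=10.0)
        # g1: RPK 20 > 10 kept; g2/g3 overlap -> dropped regardless
        assert kept.gene_ids == ["g1"]
        assert kept.rpk["g1"] == pytest.approx(20.0)

    def test_rpk_exactly_threshold_dropped(self):
        counts = pd.DataFrame({"s1": [50], "s2": [50]}, index=["g1"])
        # 50 / 5 kb = RPK 10, strict > -> dropped
        assert rpk_and_filter(counts, self.genes[:1], threshold=10.0).gene_ids == []

    def test_median_across_samples(self):
        counts = pd.DataFrame({"s1": [100], "s2": [25]}, index=["g1"])
        # RPK {20, 5}, median 12.5 -> kept
        kept = rpk_and_filter(counts, self.genes[:1], threshold=10.0)
        assert kept.gene_ids == ["g1"]
        assert kept.rpk["g1"] == pytest.approx(12.5)
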