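"""Parameter-recovery experiments: simulate under known kinetics, run the
full analysis path, and compare estimates to the simulation truth.

Each experiment is a pure function of its seed and returns a small dict of
summary numbers. These are the package's end-to-end validation: the
velocity contrast recovers a known global slowdown, the metagene tilt
deepens with gene length under a non-steady-state slowdown, spike-in
factors recover library scales, and the occupancy/pulse laws hold at
steady state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genes import Genome
from .normalize import background_size_factors, spikein_size_factors
from .profiles import bootstrap_mean_ci, center_aligned_matrix, length_quartile_groups
from .quantify import (count_features, count_in_regions, fragment_midpoints,
                       rpk_and_filter)
from .sim import (ConditionSpec, KineticsSpec, SamplingSpec, SpikeInSpec,
                  emit_chip, emit_dataset, make_genome)
from .tracks import coverage_track
from .velocity import (ElongationVelocityModel, combine_normalized,
                       tilt_statistic, tss_aligned_bins)

STEADY = -1.0e9  # onset far in the past: the condition is at steady state


def _spike_counts(frames: dict[str, pd.DataFrame], spikes: list[SpikeInSpec]) -> pd.DataFrame:
    regions = [(s.spike_id, s.spike_id, 0, s.length, "+") for s in spikes]
    pooled = []
    for sample, df in frames.items():
        sub = df[df["chrom"].isin([s.spike_id for s in spikes])].copy()
        sub["name"] = sample
        pooled.append(sub)
    pooled = pd.concat(pooled, ignore_index=True)
    mids = fragment_midpoints(pooled)
    out = count_in_regions(mids, regions)
    for sample in frames:
        if sample not in out.columns:
            out[sample] = 0
    return out[list(frames)]


def _pool(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    out = []
    for sample, df in frames.items():
        df = df.copy()
        df["name"] = sample
        out.append(df)
    return pd.concat(out, ignore_index=True)


def velocity_recovery(seed: int, n_genes: int = 200, v_control: float = 2.0,
                      factor: float = 0.5, initiation_rate: float = 2.0,
                      replicates: int = 2) -> dict:
    """Steady-state slowdown recovery (the velocity-contrast experiment).

    Control elongates at ``v_control`` kb/min, the depleted condition at
    ``factor`` times that, both at steady state; spike-ins anchor the
    normalization across unequal library scales. Returns the median
    per-gene log2 velocity change (truth: log2(factor)) and its one-sample
    Wilcoxon p-value.
    """
    ss = np.random.SeedSequence([seed, 1])
    s_genome, s_data = ss.spawn(2)
    genome = make_genome(n_genes, 10_000, 100_000, 20_000, 4, seed=s_genome)
    kin = {g.gene_id: KineticsSpec.constant(initiation_rate, v_control, g.length)
           for g in genome.genes}
    conds = [ConditionSpec("control", 1.0, STEADY),
             ConditionSpec("depleted", factor, STEADY)]
    samp = SamplingSpec(replicates=replicates,
                        ttseq_depth_per_kb=2.0, mnet_tags_per_pol=20.0,
                        library_scales=[1.0, 1.2, 0.9, 1.1][: 2 * replicates])
    ds = emit_dataset(genome, kin, conds, samp,
                      seed=int(s_data.generate_state(1)[0] % (2**31)),
                      assays=("ttseq", "mnet"))

    labeled = [s.spike_id for s in genome.spikeins if s.labeled]
    sf_tt = spikein_size_factors(_spike_counts(ds.ttseq, genome.spikeins), labeled)
    sf_mn = spikein_size_factors(_spike_counts(ds.mnet, genome.spikeins), labeled)

    tt = _pool(ds.ttseq)
    tt_counts = count_features(tt, genome.genes).counts
    expressed = rpk_and_filter(tt_counts, genome.genes, threshold=10.0)
    genes = [g for g in genome.genes if g.gene_id in set(expressed.gene_ids)]

    mn = _pool(ds.mnet)
    mn_tags = mn[mn["end"] - mn["start"] == 1].reset_index(drop=True)
    model = ElongationVelocityModel(
        tt_midpoints=fragment_midpoints(tt), mnet_tags=mn_tags, genes=genes,
        design=ds.samples[["sample", "condition"]], sf_tt=sf_tt, sf_mnet=sf_mn,
        control="control")
    res = model.fit()
    return {
        "median_log2_change": res.median_log2_change,
        "true_log2_change": float(np.log2(factor)),
        "wilcoxon_p": res.wilcoxon.p_value,
        "n_genes": res.n_genes,
        "results": res,
    }


def tilt_recovery(seed: int, n_genes: int = 200, v_control: float = 2.0,
                  factor: float = 0.5) -> dict:
    """Non-steady-state tilt recovery (the metagene-tilt experiment).

    Velocity halves at t=0 and labeling covers [60, 65] min. Synthesis
    recovers behind the slow-density wave (reaching v_new * 60 kb into the
    body by the pulse) but stays halved beyond it, so the log2 TT-seq
    change profile tilts down only in genes long enough to have distal
    regions beyond the wave — the length-quartile contrast.
    """
    ss = np.random.SeedSequence([seed, 2])
    s_genome, s_data = ss.spawn(2)
    genome = make_genome(n_genes, 10_000, 100_000, 20_000, 4, seed=s_genome)
    kin = {g.gene_id: KineticsSpec.constant(2.0, v_control, g.length)
           for g in genome.genes}
    conds = [ConditionSpec("control", 1.0, 0.0),
             ConditionSpec("depleted", factor, 0.0)]
    samp = SamplingSpec(replicates=2, ttseq_depth_per_kb=8.0,
                        library_scales=[1.0, 1.1, 0.95, 1.05])
    ds = emit_dataset(genome, kin, conds, samp,
                      seed=int(s_data.generate_state(1)[0] % (2**31)),
                      assays=("ttseq",))
    labeled = [s.spike_id for s in genome.spikeins if s.labeled]
    sf_tt = spikein_size_factors(_spike_counts(ds.ttseq, genome.spikeins), labeled)

    tt_mid = fragment_midpoints(_pool(ds.ttseq))
    design = ds.samples[["sample", "condition"]]
    bin_w = 50
    combined = {}
    for cond in ("control", "depleted"):
        names = list(design.loc[design["condition"] == cond, "sample"])
        tracks = {s: coverage_track(tt_mid[tt_mid["name"] == s], genome.chrom_sizes,
                                    bin_width=bin_w, per_base=False) for s in names}
        combined[cond] = combine_normalized(tracks, sf_tt, names)
    n_bins = 100_000 // bin_w
    mat_c = tss_aligned_bins(combined["control"], genome.genes, bin_w, n_bins)
    mat_t = tss_aligned_bins(combined["depleted"], genome.genes, bin_w, n_bins)
    change = np.log2(mat_t.values + 1.0) - np.log2(mat_c.values + 1.0)

    tilts = {}
    for i, g in enumerate(genome.genes):
        body = change[i, : g.length // bin_w]
        tilts[g.gene_id] = tilt_statistic(body)
    tilt = pd.Series(tilts)
    quartiles = length_quartile_groups(genome.genes)
    mean_tilt = [float(tilt[ids].mean()) for ids in quartiles]
    return {
        "tilt_shortest_quartile": mean_tilt[0],
        "tilt_q2": mean_tilt[1],
        "tilt_q3": mean_tilt[2],
        "tilt_longest_quartile": mean_tilt[3],
        "n_genes": n_genes,
    }


def spikein_recovery(seed: int, scales=(0.5, 1.0, 2.0),
                     total_labeled_copies: float = 10_000.0) -> dict:
    """Library-scale recovery from labeled spike-ins alone.

    Three samples at known relative depths; the recovered median-of-ratios
    factors are compared (up to overall scale) with the true scales.
    Returns the maximum relative error in percent.
    """
    from .sim import emit_spikeins

    copies = np.array([0.3, 0.3, 0.4]) * total_labeled_copies
    spikes = [SpikeInSpec(f"L{i}", 1000 * (i + 1), float(c), True)
              for i, c in enumerate(copies)]
    spikes += [SpikeInSpec(f"U{i}", 1500, float(copies[0]), False) for i in range(3)]
    ss = np.random.SeedSequence([seed, 3]).spawn(len(scales))
    frames = {}
    for j, sc in enumerate(scales):
        frames[f"s{j}"] = emit_spikeins(spikes, sc, seed=np.random.default_rng(ss[j]))
    counts = _spike_counts(frames, spikes)
    sf = spikein_size_factors(counts, [s.spike_id for s in spikes if s.labeled])
    est = sf.to_numpy()
    truth = np.asarray(scales, dtype=float)
    est_rel = est / np.exp(np.mean(np.log(est)))
    truth_rel = truth / np.exp(np.mean(np.log(truth)))
    max_err = float(np.max(np.abs(est_rel / truth_rel - 1.0)))
    return {"max_rel_error_pct": 100.0 * max_err,
            "factors": dict(zip(counts.columns, est)),
            "n_spike_reads": int(counts.sum().sum())}


def occupancy_law(seed: int, n_genes: int = 200, initiation_rate: float = 4.0) -> dict:
    """Steady-state occupancy and pulse laws.

    Occupancy: mean mNET tags per 50-bp gene-body bin is I * (50/v) *
    tags_per_pol, so halving velocity doubles it. Pulse: labeled TT-seq
    output per gene is I * pulse * L, independent of velocity. Both ratios
    are measured between a v and a v/2 condition at equal library scale.
    """
    ss = np.random.SeedSequence([seed, 4])
    s_genome, s_data = ss.spawn(2)
    genome = make_genome(n_genes, 10_000, 100_000, 20_000, 4, seed=s_genome)
    kin = {g.gene_id: KineticsSpec.constant(initiation_rate, 2.0, g.length)
           for g in genome.genes}
    conds = [ConditionSpec("fast", 1.0, STEADY), ConditionSpec("slow", 0.5, STEADY)]
    samp = SamplingSpec(replicates=1, ttseq_depth_per_kb=2.0, mnet_tags_per_pol=2.0)
    ds = emit_dataset(genome, kin, conds, samp,
                      seed=int(s_data.generate_state(1)[0] % (2**31)),
                      assays=("ttseq", "mnet"))
    regions = [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genome.genes]
    n_bins = sum(g.length // 50 for g in genome.genes)

    out = {}
    for cond in ("fast", "slow"):
        sample = f"{cond}_rep1"
        mn = ds.mnet[sample].copy()
        mn = mn[mn["end"] - mn["start"] == 1]
        mn["name"] = sample
        tags_in = count_in_regions(mn, regions)[sample].sum()
        out[f"mnet_{cond}"] = tags_in / n_bins
        tt = ds.ttseq[sample].copy()
        tt["name"] = sample
        mids = fragment_midpoints(tt)
        out[f"tt_{cond}"] = count_in_regions(mids, regions)[sample].sum()
    return {
        "mnet_bin_ratio_slow_over_fast": out["mnet_slow"] / out["mnet_fast"],
        "tt_ratio_slow_over_fast": out["tt_slow"] / out["tt_fast"],
        "n_genes": n_genes,
    }


def bootstrap_coverage(seed: int, n_datasets: int = 1000, n_genes: int = 100,
                       iters: int = 10_000, mu: float = 3.0) -> dict:
    """Coverage of the 95% percentile-bootstrap CI of a column mean over
    i.i.d. Normal(mu, 1) gene rows."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    hits = 0
    for i in range(n_datasets):
        data = rng.normal(mu, 1.0, size=(n_genes, 1))
        prof = bootstrap_mean_ci(data, iters=iters,
                                 seed=np.random.SeedSequence([seed, 5, i]))
        hits += int(prof.ci_lo[0] <= mu <= prof.ci_hi[0])
    return {"coverage_pct": 100.0 * hits / n_datasets, "n_datasets": n_datasets}


def chip_background_recovery(seed: int, scales=(1.0, 3.0),
                             background_per_kb: float = 100.0) -> dict:
    """ChIP background normalization: factors from non-transcribed-region
    counts recover the library-scale ratio, and normalized background
    coverage agrees across samples."""
    ss = np.random.SeedSequence([seed, 6])
    s_genome, *s_samples = ss.spawn(1 + len(scales))
    genome = make_genome(20, 10_000, 60_000, 20_000, 2, seed=s_genome)
    blocks = pd.DataFrame({
        "chrom": [g.chrom for g in genome.genes],
        "start": [g.start for g in genome.genes],
        "end": [g.end for g in genome.genes],
        "rate_per_kb": 4.0,
    })
    frames = {}
    for j, sc in enumerate(scales):
        frames[f"s{j}"] = emit_chip(blocks, background_per_kb,
                                    genome.non_transcribed,
                                    seed=np.random.default_rng(s_samples[j]),
                                    library_scale=sc)
    nt = genome.non_transcribed
    regions = [(f"nt{i}", r.chrom, int(r.start), int(r.end), ".")
               for i, r in enumerate(nt.itertuples(index=False))]
    pooled = _pool(frames)
    mids = fragment_midpoints_unstranded(pooled)
    counts = count_in_regions(mids, regions, strand_specific=False)
    sf = background_size_factors(counts)
    norm_totals = counts.sum() / sf
    rel_spread = float(norm_totals.max() / norm_totals.min() - 1.0)
    factor_ratio = float(sf["s1"] / sf["s0"])
    # gene-center matrix mask: NaN outside gene bodies, exactly
    track = coverage_track(frames["s0"], genome.chrom_sizes, bin_width=500,
                           per_base=False)
    cmat = center_aligned_matrix(track, genome.genes, bin_width=500, window_bins=41)
    mask_ok = True
    for i, g in enumerate(genome.genes):
        center_bin = ((g.start + g.end) // 2) // 500
        for j in range(41):
            b = center_bin - 20 + j
            inside = (b * 500 >= g.start) and ((b + 1) * 500 <= g.end)
            if inside != np.isfinite(cmat.values[i, j]):
                mask_ok = False
    return {
        "factor_ratio": factor_ratio,
        "true_ratio": float(scales[1] / scales[0]),
        "normalized_background_spread_pct": 100.0 * rel_spread,
        "center_matrix_mask_exact": bool(mask_ok),
    }


def fragment_midpoints_unstranded(fragments: pd.DataFrame) -> pd.DataFrame:
    mid = (fragments["start"].to_numpy(np.int64) + fragments["end"].to_numpy(np.int64)) // 2
    out = fragments.copy()
    out["start"] = mid
    out["end"] = mid + 1
    return out
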