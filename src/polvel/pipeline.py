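"""Orchestration: simulate -> quantify -> normalize -> velocity -> profiles
-> report, each stage re-runnable from its on-disk intermediates.

Every output file carries a provenance header (package version, config
hash, seed); identical (config, seed) reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genes import Genome, genes_to_frame
from .io import (read_bed6, read_count_tsv, read_gene_bed, read_size_factors,
                 write_bed6, write_count_tsv, write_matrix_tsv, write_size_factors)
from .normalize import (apply_size_factors, background_size_factors,
                        spikein_size_factors, validate_regions_outside_genes)
from .profiles import (bootstrap_mean_ci, center_aligned_matrix,
                       length_quartile_groups, log_transform, scaled_profile,
                       tss_aligned_change_matrix)
from .quantify import (count_features, count_in_regions, fragment_midpoints,
                       last_base_positions, rpk_and_filter)
from .sim import KineticsSpec, emit_dataset, make_genome, write_dataset
from .stats import boxplot_summary, ma_table, wilcoxon_rank_sum, wilcoxon_signed_rank
from .tracks import StrandedTrack, coverage_track
from .velocity import (ElongationVelocityModel, combine_normalized,
                       tilt_statistic, tss_aligned_bins, velocity_bins)

log = logging.getLogger("polvel")


def _float_fmt(x: float) -> str:
    return f"{x:.6g}"


def _write_tsv(df: pd.DataFrame, path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format="%.6g", index=index)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, seed: int | None = None) -> Path:
    """Simulate the dataset described by the config; write it under
    <outdir>/sim and return that path."""
    seed = config.seed if seed is None else seed
    outdir = Path(config.outdir)
    simdir = outdir / "sim"
    gs = config.genome_spec
    if "genes_bed" in gs:
        raise NotImplementedError(
            "simulation from an external gene BED is not supported; "
            "use the synthetic genome block")
    genome = make_genome(
        n_genes=int(gs["n_genes"]), length_min=int(gs["length_min"]),
        length_max=int(gs["length_max"]), intergenic_gap=int(gs["intergenic_gap"]),
        n_chroms=int(gs["n_chroms"]), seed=np.random.SeedSequence([seed, 0xA]),
        spikeins=config.spikeins())
    ks = config.kinetics_spec
    kinetics = {g.gene_id: KineticsSpec.constant(float(ks["initiation_rate"]),
                                                 float(ks["velocity_kb_min"]),
                                                 g.length)
                for g in genome.genes}
    ds = emit_dataset(genome, kinetics, config.conditions(), config.sampling(),
                      seed=seed)
    write_dataset(ds, simdir, header=config.provenance(seed))
    log.info("simulated %d genes x %d samples -> %s",
             len(genome.genes), len(ds.samples), simdir)
    return simdir


# ---------------------------------------------------------------------------
# loading intermediates
# ---------------------------------------------------------------------------

def load_sim(simdir) -> dict:
    """Load a simulated dataset directory back into memory."""
    simdir = Path(simdir)
    genes = read_gene_bed(simdir / "genes.bed")
    sizes = pd.read_csv(simdir / "chrom_sizes.tsv", sep="\t", comment="#")
    chrom_sizes = dict(zip(sizes["chrom"], sizes["size"]))
    nt = read_bed6(simdir / "nontranscribed.bed")
    spikes = pd.read_csv(simdir / "spikeins.tsv", sep="\t", comment="#")
    samples = pd.read_csv(simdir / "truth_samples.tsv", sep="\t", comment="#")
    genome = Genome(genes=genes, chrom_sizes=chrom_sizes,
                    non_transcribed=nt[["chrom", "start", "end"]])
    records = {}
    for assay in ("ttseq", "mnet", "chip"):
        store = {}
        for sample in samples["sample"]:
            path = simdir / f"{sample}.{assay}.bed"
            if path.exists():
                store[sample] = read_bed6(path)
        records[assay] = store
    truth_genes = None
    tg = simdir / "truth_genes.tsv"
    if tg.exists():
        truth_genes = pd.read_csv(tg, sep="\t", comment="#")
    return {"genome": genome, "samples": samples, "records": records,
            "spikes": spikes, "truth_genes": truth_genes}


def _pool(records: dict[str, pd.DataFrame], samples) -> pd.DataFrame:
    frames = []
    for s in samples:
        df = records[s].copy()
        df["name"] = s
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

def run_quantify(config: PipelineConfig, simdir, seed: int | None = None) -> Path:
    """Gene-body count tables (IntersectionNotEmpty on last-base tags for
    mNET, whole fragments for TT-seq), spike-in counts, non-transcribed
    region ChIP counts, and the expressed-gene set."""
    seed = config.seed if seed is None else seed
    header = config.provenance(seed)
    sim = load_sim(simdir)
    outdir = Path(config.outdir) / "quant"
    outdir.mkdir(parents=True, exist_ok=True)
    genome: Genome = sim["genome"]
    samples = list(sim["samples"]["sample"])
    spike_frame = sim["spikes"]

    tt = _pool(sim["records"]["ttseq"], samples)
    mn = _pool(sim["records"]["mnet"], samples)
    tt_counts = count_features(tt, genome.genes).counts
    mn_tags = mn[mn["end"] - mn["start"] == 1]
    mn_body = mn[mn["end"] - mn["start"] > 1]
    if len(mn_body):  # spike fragments in mNET libraries keep their width
        mn_tags = pd.concat([mn_tags, last_base_positions(mn_body)], ignore_index=True)
    mn_counts = count_features(mn_tags, genome.genes).counts

    spike_regions = [(r.spike_id, r.spike_id, 0, int(r.length), "+")
                     for r in spike_frame.itertuples(index=False)]
    tt_spike = count_in_regions(tt, spike_regions)
    mn_spike = count_in_regions(fragment_midpoints(mn), spike_regions)
    for df in (tt_spike, mn_spike):
        for s in samples:
            if s not in df.columns:
                df[s] = 0
    tt_spike = tt_spike[samples]
    mn_spike = mn_spike[samples]

    chip = _pool(sim["records"]["chip"], samples) if sim["records"]["chip"] else None
    write_count_tsv(tt_counts, outdir / "ttseq_gene_counts.tsv", header=header)
    write_count_tsv(mn_counts, outdir / "mnet_gene_counts.tsv", header=header)
    write_count_tsv(tt_spike, outdir / "ttseq_spike_counts.tsv", header=header)
    write_count_tsv(mn_spike, outdir / "mnet_spike_counts.tsv", header=header)
    if chip is not None and len(chip):
        nt = genome.non_transcribed
        validate_regions_outside_genes(nt, genome.genes)
        regions = [(f"nt{i}", r.chrom, int(r.start), int(r.end), ".")
                   for i, r in enumerate(nt.itertuples(index=False))]
        chip_nt = count_in_regions(fragment_midpoints_unstranded(chip), regions,
                                   strand_specific=False)
        write_count_tsv(chip_nt, outdir / "chip_nt_counts.tsv", header=header)

    expressed = rpk_and_filter(tt_counts, genome.genes,
                               threshold=float(config.analysis["rpk_threshold"]))
    with open(outdir / "expressed_genes.txt", "w") as fh:
        for line in header.splitlines():
            fh.write(f"#{line}\n")
        for gid in expressed.gene_ids:
            fh.write(gid + "\n")
    log.info("quantified %d samples; %d expressed genes", len(samples),
             len(expressed.gene_ids))
    return outdir


def fragment_midpoints_unstranded(fragments: pd.DataFrame) -> pd.DataFrame:
    mid = (fragments["start"].to_numpy(np.int64) + fragments["end"].to_numpy(np.int64)) // 2
    out = fragments.copy()
    out["start"] = mid
    out["end"] = mid + 1
    return out


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

def run_normalize(config: PipelineConfig, seed: int | None = None) -> Path:
    seed = config.seed if seed is None else seed
    header = config.provenance(seed)
    outdir = Path(config.outdir)
    quant = outdir / "quant"
    norm = outdir / "norm"
    norm.mkdir(parents=True, exist_ok=True)
    spikes = pd.read_csv(Path(outdir) / "sim" / "spikeins.tsv", sep="\t", comment="#")
    labeled = list(spikes.loc[spikes["labeled"], "spike_id"])
    for assay in ("ttseq", "mnet"):
        counts = read_count_tsv(quant / f"{assay}_spike_counts.tsv")
        sf = spikein_size_factors(counts, labeled)
        write_size_factors(sf, norm / f"{assay}_size_factors.tsv", header=header)
    chip_nt = quant / "chip_nt_counts.tsv"
    if chip_nt.exists():
        sf = background_size_factors(read_count_tsv(chip_nt))
        write_size_factors(sf, norm / "chip_size_factors.tsv", header=header)
    return norm


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def _expressed_genes(config: PipelineConfig, genome: Genome) -> list:
    path = Path(config.outdir) / "quant" / "expressed_genes.txt"
    with open(path) as fh:
        keep = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    return [g for g in genome.genes if g.gene_id in keep]


def run_velocity(config: PipelineConfig, simdir, seed: int | None = None) -> Path:
    """Per-gene velocity contrast plus the 50-bp bin velocity heatmap."""
    seed = config.seed if seed is None else seed
    header = config.provenance(seed)
    outdir = Path(config.outdir)
    veldir = outdir / "velocity"
    veldir.mkdir(parents=True, exist_ok=True)
    sim = load_sim(simdir)
    genome: Genome = sim["genome"]
    design = sim["samples"][["sample", "condition"]]
    genes = _expressed_genes(config, genome)
    sf_tt = read_size_factors(outdir / "norm" / "ttseq_size_factors.tsv")
    sf_mn = read_size_factors(outdir / "norm" / "mnet_size_factors.tsv")
    samples = list(sim["samples"]["sample"])

    tt_mid = fragment_midpoints(_pool(sim["records"]["ttseq"], samples))
    mn = _pool(sim["records"]["mnet"], samples)
    mn_tags = mn[mn["end"] - mn["start"] == 1].reset_index(drop=True)

    control = str(config.analysis["control"])
    model = ElongationVelocityModel(
        tt_midpoints=tt_mid, mnet_tags=mn_tags, genes=genes, design=design,
        sf_tt=sf_tt, sf_mnet=sf_mn, control=control,
        exclude_first=int(config.analysis["exclude_first"]),
        bin_width=int(config.analysis["velocity_bin"]))
    res = model.fit()
    res.to_tsv(veldir / "per_gene_velocity.tsv", header=header)
    with open(veldir / "summary.txt", "w") as fh:
        for line in header.splitlines():
            fh.write(f"#{line}\n")
        fh.write(res.summary() + "\n")

    # 50-bp bin ratio tracks per condition, then TSS-aligned log2-change matrix
    bin_w = int(config.analysis["velocity_bin"])
    n_bins = int(config.analysis["heatmap_window_bp"]) // bin_w
    cond_ratio = {}
    for cond in (control, model.treated):
        cond_samples = list(design.loc[design["condition"] == cond, "sample"])
        tt_tracks = {s: coverage_track(tt_mid[tt_mid["name"] == s],
                                       genome.chrom_sizes, bin_width=bin_w,
                                       per_base=False) for s in cond_samples}
        mn_tracks = {s: coverage_track(mn_tags[mn_tags["name"] == s],
                                       genome.chrom_sizes, bin_width=bin_w,
                                       per_base=False) for s in cond_samples}
        tt_comb = combine_normalized(tt_tracks, sf_tt, cond_samples)
        mn_comb = combine_normalized(mn_tracks, sf_mn, cond_samples)
        cond_ratio[cond] = velocity_bins(tt_comb, mn_comb)
    mat_c = tss_aligned_bins(cond_ratio[control], genes, bin_w, n_bins)
    mat_t = tss_aligned_bins(cond_ratio[model.treated], genes, bin_w, n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.log2(mat_t.values / mat_c.values)
    change[~np.isfinite(change)] = np.nan
    cols = [f"bin{b}" for b in range(n_bins)]
    write_matrix_tsv(change, mat_c.gene_ids, cols,
                     veldir / "velocity_change_matrix.tsv", header=header)
    ends = pd.DataFrame({"gene_end_bin": mat_c.gene_end_bin}, index=mat_c.gene_ids)
    ends.index.name = "gene_id"
    _write_tsv(ends, veldir / "gene_end_bins.tsv", header)
    return veldir


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def run_metagene(config: PipelineConfig, simdir, seed: int | None = None) -> Path:
    """Scaled TT-seq metagene profiles (all genes + length quartiles) with
    bootstrap confidence bands, for each condition."""
    seed = config.seed if seed is None else seed
    header = config.provenance(seed)
    outdir = Path(config.outdir)
    metadir = outdir / "metagene"
    metadir.mkdir(parents=True, exist_ok=True)
    sim = load_sim(simdir)
    genome: Genome = sim["genome"]
    design = sim["samples"][["sample", "condition"]]
    genes = _expressed_genes(config, genome)
    sf_tt = read_size_factors(outdir / "norm" / "ttseq_size_factors.tsv")
    a = config.analysis
    n_body, flank_bp, flank_bins = int(a["n_body_bins"]), int(a["flank_bp"]), int(a["flank_bins"])
    iters, pseudo = int(a["bootstrap_iters"]), float(a["pseudo_count"])

    samples = list(sim["samples"]["sample"])
    tt = _pool(sim["records"]["ttseq"], samples)
    groups = {"all": [g.gene_id for g in genes]}
    quartiles = length_quartile_groups(genes)
    for qi, ids in enumerate(quartiles, start=1):
        groups[f"length_q{qi}"] = list(ids)

    rows_out = []
    for cond in dict.fromkeys(design["condition"]):
        cond_samples = list(design.loc[design["condition"] == cond, "sample"])
        tracks = {s: coverage_track(tt[tt["name"] == s], genome.chrom_sizes,
                                    bin_width=1) for s in cond_samples}
        combined = combine_normalized(tracks, sf_tt, cond_samples)
        prof_by_gene = {}
        for g in genes:
            p = scaled_profile(combined, g, n_body_bins=n_body,
                               flank_bp=flank_bp, flank_bins=flank_bins)
            if p is not None:
                prof_by_gene[g.gene_id] = p
        for gname, ids in groups.items():
            mat = np.array([prof_by_gene[i] for i in ids if i in prof_by_gene])
            if len(mat) == 0:
                continue
            prof = bootstrap_mean_ci(log_transform(mat, pseudo), iters=iters,
                                     seed=np.random.SeedSequence([seed, 0xB]))
            for pos in range(mat.shape[1]):
                rows_out.append((cond, gname, pos, prof.mean[pos],
                                 prof.ci_lo[pos], prof.ci_hi[pos], prof.n_genes))
    out = pd.DataFrame(rows_out, columns=["condition", "group", "position",
                                          "mean", "ci_lo", "ci_hi", "n_genes"])
    _write_tsv(out, metadir / "metagene_ttseq.tsv", header, index=False)
    return metadir


# ---------------------------------------------------------------------------
# report (heatmaps, MA, figure statistics, truth recovery)
# ---------------------------------------------------------------------------

def run_report(config: PipelineConfig, simdir, seed: int | None = None) -> Path:
    seed = config.seed if seed is None else seed
    header = config.provenance(seed)
    outdir = Path(config.outdir)
    repdir = outdir / "report"
    repdir.mkdir(parents=True, exist_ok=True)
    sim = load_sim(simdir)
    genome: Genome = sim["genome"]
    design = sim["samples"][["sample", "condition"]]
    genes = _expressed_genes(config, genome)
    samples = list(sim["samples"]["sample"])
    a = config.analysis
    control = str(a["control"])
    conds = list(dict.fromkeys(design["condition"]))
    treated = [c for c in conds if c != control][0]
    c_samples = list(design.loc[design["condition"] == control, "sample"])
    t_samples = list(design.loc[design["condition"] == treated, "sample"])
    sf_tt = read_size_factors(outdir / "norm" / "ttseq_size_factors.tsv")
    sf_mn = read_size_factors(outdir / "norm" / "mnet_size_factors.tsv")

    # MA table from TT-seq gene-body counts
    tt_counts = read_count_tsv(outdir / "quant" / "ttseq_gene_counts.tsv")
    gene_ids = [g.gene_id for g in genes]
    ma = ma_table(tt_counts.loc[gene_ids], sf_tt, c_samples, t_samples,
                  pseudo=float(a["pseudo_count"]))
    _write_tsv(ma, repdir / "ma_ttseq.tsv", header)

    # figure statistics: synthesis / occupancy fold-change boxes + tests
    mn_counts = read_count_tsv(outdir / "quant" / "mnet_gene_counts.tsv")
    stats_rows = []
    for label, counts, sf in (("ttseq", tt_counts, sf_tt), ("mnet", mn_counts, sf_mn)):
        norm = apply_size_factors(counts.loc[gene_ids], sf)
        fc = np.log2((norm[t_samples].mean(axis=1) + float(a["pseudo_count"])) /
                     (norm[c_samples].mean(axis=1) + float(a["pseudo_count"])))
        box = boxplot_summary(fc.to_numpy())
        test = wilcoxon_signed_rank(fc.dropna().to_numpy())
        stats_rows.append((label, "log2_fc", box.n, box.median, box.hinge_lo,
                           box.hinge_hi, box.notch_lo, box.notch_hi,
                           box.whisker_lo, box.whisker_hi,
                           test.method, test.statistic, test.p_value))
    # per-gene velocity two-sample comparison (control vs treated ratios)
    vel = pd.read_csv(outdir / "velocity" / "per_gene_velocity.tsv",
                      sep="\t", comment="#", index_col=0)
    vc = vel[f"velocity_{control}"].dropna()
    vt = vel[f"velocity_{treated}"].dropna()
    if len(vc) and len(vt):
        test = wilcoxon_rank_sum(vt.to_numpy(), vc.to_numpy())
        box = boxplot_summary(np.concatenate([vc.to_numpy(), vt.to_numpy()]))
        stats_rows.append(("velocity_ratio", f"{treated}_vs_{control}", box.n,
                           box.median, box.hinge_lo, box.hinge_hi, box.notch_lo,
                           box.notch_hi, box.whisker_lo, box.whisker_hi,
                           test.method, test.statistic, test.p_value))
    stats = pd.DataFrame(stats_rows, columns=[
        "assay", "quantity", "n", "median", "hinge_lo", "hinge_hi", "notch_lo",
        "notch_hi", "whisker_lo", "whisker_hi", "test_method", "test_statistic",
        "p_value"])
    _write_tsv(stats, repdir / "figure_stats.tsv", header, index=False)

    # mNET TSS-aligned change heatmap
    bin_w = int(a["velocity_bin"])
    window = int(a["heatmap_window_bp"])
    mn = _pool(sim["records"]["mnet"], samples)
    mn_tags = mn[mn["end"] - mn["start"] == 1]
    tracks_c = {s: coverage_track(mn_tags[mn_tags["name"] == s], genome.chrom_sizes,
                                  bin_width=bin_w, per_base=False) for s in c_samples}
    tracks_t = {s: coverage_track(mn_tags[mn_tags["name"] == s], genome.chrom_sizes,
                                  bin_width=bin_w, per_base=False) for s in t_samples}
    comb_c = combine_normalized(tracks_c, sf_mn, c_samples)
    comb_t = combine_normalized(tracks_t, sf_mn, t_samples)
    mat = tss_aligned_change_matrix(comb_c, comb_t, genes, bin_width=bin_w,
                                    window_bp=window,
                                    pseudo_count=float(a["pseudo_count"]))
    cols = [f"bin{b}" for b in range(mat.values.shape[1])]
    write_matrix_tsv(mat.values, mat.gene_ids, cols,
                     repdir / "mnet_change_matrix.tsv", header=header)

    # ChIP center-aligned matrix (normalized to non-transcribed background)
    if sim["records"]["chip"]:
        sf_chip = read_size_factors(outdir / "norm" / "chip_size_factors.tsv")
        chip = _pool(sim["records"]["chip"], samples)
        chip_bin = int(a["chip_bin"])
        for cond, cond_samples in ((control, c_samples), (treated, t_samples)):
            tracks = {s: coverage_track(chip[chip["name"] == s], genome.chrom_sizes,
                                        bin_width=chip_bin, per_base=False)
                      for s in cond_samples}
            comb = combine_normalized(tracks, sf_chip, cond_samples)
            cmat = center_aligned_matrix(comb, genes, bin_width=chip_bin,
                                         window_bins=41)
            cols = [f"bin{b}" for b in range(cmat.values.shape[1])]
            write_matrix_tsv(cmat.values, cmat.gene_ids, cols,
                             repdir / f"chip_center_matrix_{cond}.tsv", header=header)

    # recovery vs simulation truth
    if sim["truth_genes"] is not None:
        truth = sim["truth_genes"].pivot(index="gene_id", columns="condition",
                                         values="mean_velocity_kb_min")
        est = vel["log2_change"].dropna()
        common = [g for g in est.index if g in truth.index]
        true_change = np.log2(truth.loc[common, treated] / truth.loc[common, control])
        rec = pd.DataFrame({
            "estimated_log2_change": est.loc[common],
            "true_log2_change": true_change,
            "error": est.loc[common] - true_change,
        })
        rec.index.name = "gene_id"
        _write_tsv(rec, repdir / "recovery_velocity.tsv", header)
        summary = pd.DataFrame({
            "metric": ["median_estimated_log2_change", "median_true_log2_change",
                       "median_abs_error", "n_genes"],
            "value": [float(np.median(est.loc[common])),
                      float(np.median(true_change)),
                      float(np.median(np.abs(rec["error"]))), len(common)],
        })
        _write_tsv(summary, repdir / "recovery_summary.tsv", header, index=False)
    return repdir


def run_analyze(config: PipelineConfig, simdir, seed: int | None = None) -> Path:
    run_quantify(config, simdir, seed=seed)
    run_normalize(config, seed=seed)
    run_velocity(config, simdir, seed=seed)
    run_metagene(config, simdir, seed=seed)
    run_report(config, simdir, seed=seed)
    return Path(config.outdir)


def run_all(config: PipelineConfig, seed: int | None = None) -> Path:
    simdir = run_simulate(config, seed=seed)
    return run_analyze(config, simdir, seed=seed)
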