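"""Stochastic simulator of nascent transcription with known ground truth.

The kinetic model: polymerases initiate at a gene's TSS as a Poisson
process with rate I (polymerases/minute) and move along the gene body with
a piecewise-constant velocity profile v(x) (kb/minute). An acute depletion
is modelled as a global multiplicative velocity factor applied from a
condition-specific onset time. Polymerases disappear at the TES; there is
no pausing, backtracking or RNA degradation in the default model.

From trajectories the simulator emits the three assays:

* TT-seq — fragments sampled from the RNA synthesized during a short 4sU
  pulse (the gene-body segment each polymerase traversed during the
  labeling window), plus synthetic spike-in fragments of constant
  abundance that anchor cross-sample normalization;
* mNET-seq — single-base tags at the last incorporated base (the active
  site) of each engaged polymerase at the sampling time;
* ChIP-seq — unstranded fragments from an occupancy-proportional signal
  over gene bodies plus a uniform background over non-transcribed regions.

Depth noise is Poisson everywhere; one master seed expands into per-sample
/ per-assay substreams in a fixed order, so a dataset is a pure function
of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel, Genome, genes_to_frame
from .io import empty_records

ASSAYS = ("ttseq", "mnet", "chip")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSpec:
    """Initiation rate (pol/min) and a piecewise-constant velocity profile.

    ``velocity_edges`` are gene-body offsets in bp, from 0 to the gene
    length; piece i has velocity ``velocity_values[i]`` (kb/min) over
    [edges[i], edges[i+1]). The profile is pulse-independent.
    """

    initiation_rate: float
    velocity_edges: tuple
    velocity_values: tuple

    def __post_init__(self):
        edges = np.asarray(self.velocity_edges, dtype=float)
        vals = np.asarray(self.velocity_values, dtype=float)
        if self.initiation_rate < 0 or not np.isfinite(self.initiation_rate):
            raise ValueError(f"initiation_rate must be finite and >= 0, got {self.initiation_rate}")
        if len(edges) != len(vals) + 1:
            raise ValueError("velocity_edges must have one more entry than velocity_values")
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("velocity_edges must start at 0 and be strictly increasing")
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("all velocity pieces must be positive and finite")

    @classmethod
    def constant(cls, initiation_rate: float, velocity_kb_min: float, length: int) -> "KineticsSpec":
        return cls(initiation_rate, (0.0, float(length)), (float(velocity_kb_min),))

    @property
    def length(self) -> float:
        return float(self.velocity_edges[-1])

    def mean_velocity(self) -> float:
        """Length-weighted mean velocity (kb/min)."""
        edges = np.asarray(self.velocity_edges, dtype=float)
        vals = np.asarray(self.velocity_values, dtype=float)
        w = np.diff(edges)
        return float((vals * w).sum() / w.sum())


@dataclass(frozen=True)
class ConditionSpec:
    """Named condition; velocity is multiplied by ``velocity_factor`` for
    t >= onset_time (minutes). The control has factor 1."""

    name: str
    velocity_factor: float = 1.0
    onset_time: float = 0.0

    def __post_init__(self):
        if self.velocity_factor <= 0:
            raise ValueError(f"velocity_factor must be > 0, got {self.velocity_factor}")


@dataclass(frozen=True)
class SpikeInSpec:
    """Synthetic spike-in RNA of constant abundance across samples."""

    spike_id: str
    length: int
    copies: float
    labeled: bool

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"spike {self.spike_id}: length must be > 0")
        if self.copies <= 0:
            raise ValueError(f"spike {self.spike_id}: copies must be > 0")


def default_spikeins(copies: float = 10000.0) -> list[SpikeInSpec]:
    """Three labeled and three unlabeled spike-ins, as in the assay design."""
    out = []
    for i, length in enumerate((1000, 2000, 4000), start=1):
        out.append(SpikeInSpec(f"spike_L{i}", length, copies, True))
    for i, length in enumerate((1500, 2500, 3500), start=1):
        out.append(SpikeInSpec(f"spike_U{i}", length, copies, False))
    return out


@dataclass
class SamplingSpec:
    """Labeling window, sequencing depths and library scales.

    label_start/label_duration are minutes; the sample is taken at
    label_start + label_duration. Depth parameters: ``ttseq_depth_per_kb``
    = expected TT-seq fragments per kb of labeled RNA; ``mnet_tags_per_pol``
    = expected mNET-seq tags per engaged polymerase; ``chip_reads_per_pol_kb``
    = expected ChIP fragments per kb of gene body per (pol/kb) of occupancy;
    ``chip_background_per_kb`` = background fragments per kb of
    non-transcribed region. ``library_scales`` multiplies all expected
    counts of a sample (sequencing-depth variation), keyed by sample name
    or given as a list in sample order.
    """

    label_start: float = 60.0
    label_duration: float = 5.0
    replicates: int = 2
    ttseq_depth_per_kb: float = 2.0
    mnet_tags_per_pol: float = 20.0
    chip_reads_per_pol_kb: float = 1.0
    chip_background_per_kb: float = 2.0
    fragment_min: int = 150
    fragment_max: int = 300
    library_scales: dict | list | None = None
    warmup: float | None = None

    def __post_init__(self):
        if self.label_duration <= 0:
            raise ValueError("label_duration must be > 0")
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment_min must be <= fragment_max")
        if min(self.ttseq_depth_per_kb, self.mnet_tags_per_pol,
               self.chip_reads_per_pol_kb, self.chip_background_per_kb) < 0:
            raise ValueError("depths must be >= 0")

    @property
    def sample_time(self) -> float:
        return self.label_start + self.label_duration


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _advance(x: np.ndarray, duration: np.ndarray, edges: np.ndarray,
             vals_bp_min: np.ndarray, scale: float) -> np.ndarray:
    """Move positions ``x`` (bp) forward for ``duration`` minutes along a
    piecewise-constant velocity profile scaled by ``scale``. Vectorized;
    iterates at most once per profile piece crossed."""
    x = x.copy()
    remaining = duration.astype(float).copy()
    L = edges[-1]
    max_iter = 4 * len(vals_bp_min) + 16
    for _ in range(max_iter):
        active = (x < L) & (remaining > 1e-12)
        if not active.any():
            break
        xi = x[active]
        idx = np.clip(np.searchsorted(edges, xi, side="right") - 1, 0, len(vals_bp_min) - 1)
        v = vals_bp_min[idx] * scale
        to_edge = (edges[idx + 1] - xi) / v
        step = np.minimum(remaining[active], to_edge)
        x[active] = np.minimum(xi + v * step, edges[idx + 1])
        rem = remaining[active] - step
        remaining[active] = rem
    return np.minimum(x, L)


def positions_at(init_times: np.ndarray, t: float, kin: KineticsSpec,
                 cond: ConditionSpec) -> np.ndarray:
    """Gene-body offsets (bp) at time ``t`` for polymerases with the given
    initiation times. Positions are clipped to the gene length (terminated
    polymerases sit at L); trajectories with init_time > t return 0."""
    init_times = np.asarray(init_times, dtype=float)
    edges = np.asarray(kin.velocity_edges, dtype=float)
    vals_bp = np.asarray(kin.velocity_values, dtype=float) * 1000.0
    x = np.zeros(len(init_times), dtype=float)
    onset = cond.onset_time
    # phase 1: native velocity, from init to min(t, onset)
    dur1 = np.clip(np.minimum(t, onset) - init_times, 0.0, None)
    if dur1.any():
        x = _advance(x, dur1, edges, vals_bp, 1.0)
    # phase 2: scaled velocity, from max(init, onset) to t
    dur2 = np.clip(t - np.maximum(init_times, onset), 0.0, None)
    if dur2.any():
        x = _advance(x, dur2, edges, vals_bp, cond.velocity_factor)
    return x


@dataclass
class PolTrajectory:
    """One polymerase: initiation time plus the kinetic context that
    determines its piecewise-linear, non-decreasing position(t)."""

    init_time: float
    kin: KineticsSpec
    cond: ConditionSpec

    def position(self, t: float) -> float:
        return float(positions_at(np.array([self.init_time]), t, self.kin, self.cond)[0])

    def terminated(self, t: float) -> bool:
        return self.position(t) >= self.kin.length


def simulate_trajectories(gene: GeneModel, kin: KineticsSpec, cond: ConditionSpec,
                          horizon: float, seed, warmup: float = 0.0) -> list[PolTrajectory]:
    """Poisson initiations on [-warmup, horizon] at ``kin.initiation_rate``,
    each integrated through the velocity profile (times the condition factor
    after onset). Deterministic given the seed."""
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    init = _initiation_times(_as_rng(seed), kin.initiation_rate, -warmup, horizon)
    return [PolTrajectory(float(t), kin, cond) for t in init]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _initiation_times(rng: np.random.Generator, rate: float,
                      t_lo: float, t_hi: float) -> np.ndarray:
    if rate == 0 or t_hi <= t_lo:
        return np.empty(0)
    n = rng.poisson(rate * (t_hi - t_lo))
    return np.sort(rng.uniform(t_lo, t_hi, n))


def engaged_positions(trajectories, gene: GeneModel, t: float) -> pd.DataFrame:
    """Width-1 tag records at the active-site base of every engaged
    (initiated, non-terminated) polymerase at time ``t``."""
    if isinstance(trajectories, list):
        init = np.array([tr.init_time for tr in trajectories])
        if len(trajectories):
            kin, cond = trajectories[0].kin, trajectories[0].cond
        else:
            return empty_records()
    else:
        raise TypeError("expected a list of PolTrajectory")
    offs = positions_at(init, t, kin, cond)
    keep = (init <= t) & (offs < kin.length)
    return tags_from_offsets(np.floor(offs[keep]).astype(np.int64), gene)


def tags_from_offsets(offsets: np.ndarray, gene: GeneModel,
                      sample: str = "sim") -> pd.DataFrame:
    """Map integer gene-body offsets to single-base genomic tag records."""
    if len(offsets) == 0:
        return empty_records()
    base = np.asarray(gene.offset_to_genome(offsets), dtype=np.int64)
    return pd.DataFrame(
        {"chrom": gene.chrom, "start": base, "end": base + 1,
         "name": sample, "score": 0, "strand": gene.strand}
    )


def labeled_interval(trajectory: PolTrajectory, gene: GeneModel, window) -> tuple | None:
    """Genomic interval transcribed by one polymerase during [t0, t1],
    or None when it initiates after t1 / terminated before t0."""
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must have t0 < t1")
    df = labeled_intervals(np.array([trajectory.init_time]), gene,
                           trajectory.kin, trajectory.cond, t0, t1)
    if len(df) == 0:
        return None
    row = df.iloc[0]
    return (row["chrom"], int(row["start"]), int(row["end"]), row["strand"])


def labeled_intervals(init_times: np.ndarray, gene: GeneModel, kin: KineticsSpec,
                      cond: ConditionSpec, t0: float, t1: float) -> pd.DataFrame:
    """Gene-body segments transcribed during the labeling window [t0, t1],
    one genomic interval per contributing polymerase, clipped to the gene."""
    init_times = np.asarray(init_times, dtype=float)
    x0 = positions_at(init_times, t0, kin, cond)
    x0[init_times > t0] = 0.0
    x1 = positions_at(init_times, t1, kin, cond)
    keep = (init_times < t1) & (x0 < kin.length)
    o0 = np.floor(x0[keep]).astype(np.int64)
    o1 = np.floor(np.minimum(x1[keep], kin.length)).astype(np.int64)
    nonempty = o1 > o0
    o0, o1 = o0[nonempty], o1[nonempty]
    if len(o0) == 0:
        return empty_records()
    if gene.strand == "+":
        gs, ge = gene.start + o0, gene.start + o1
    else:
        gs, ge = gene.end - o1, gene.end - o0
    return pd.DataFrame(
        {"chrom": gene.chrom, "start": gs, "end": ge,
         "name": gene.gene_id, "score": 0, "strand": gene.strand}
    )


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def fragment_intervals(intervals: pd.DataFrame, fragment_min: int, fragment_max: int,
                       depth_per_kb: float, seed, library_scale: float = 1.0,
                       name: str = "frag") -> pd.DataFrame:
    """Sample sequencing fragments from source intervals.

    The expected fragment count is total_bases/1000 * depth_per_kb *
    library_scale with Poisson noise; each fragment picks a source interval
    with probability proportional to its length, a length uniform in
    [fragment_min, fragment_max] truncated to the interval, and a uniform
    start within it. Strand is inherited.
    """
    if fragment_min > fragment_max:
        raise ValueError("fragment_min must be <= fragment_max")
    if depth_per_kb < 0:
        raise ValueError("depth_per_kb must be >= 0")
    rng = _as_rng(seed)
    if len(intervals) == 0:
        return empty_records()
    starts = intervals["start"].to_numpy(np.int64)
    ends = intervals["end"].to_numpy(np.int64)
    lens = ends - starts
    total = lens.sum()
    n = rng.poisson(total / 1000.0 * depth_per_kb * library_scale)
    if n == 0:
        return empty_records()
    idx = rng.choice(len(intervals), size=n, p=lens / total)
    flen = rng.integers(fragment_min, fragment_max + 1, size=n)
    flen = np.minimum(flen, lens[idx])
    offset = np.floor(rng.random(n) * (lens[idx] - flen + 1)).astype(np.int64)
    fs = starts[idx] + offset
    return pd.DataFrame(
        {"chrom": intervals["chrom"].to_numpy()[idx], "start": fs, "end": fs + flen,
         "name": name, "score": 0, "strand": intervals["strand"].to_numpy()[idx]}
    )


def emit_spikeins(spikes: list[SpikeInSpec], library_scale: float, seed,
                  leakage: float = 0.0, fragment_min: int = 150,
                  fragment_max: int = 300, name: str = "spike") -> pd.DataFrame:
    """Spike-in fragments on dedicated spike 'chromosomes'.

    A labeled spike-in yields Poisson(copies * library_scale) fragments; an
    unlabeled one yields the configured 4sU-purification leakage fraction of
    that (default 0). Copies are constant across samples — the anchor that
    makes global shifts detectable after normalization.
    """
    if library_scale <= 0:
        raise ValueError(f"library_scale must be > 0, got {library_scale}")
    rng = _as_rng(seed)
    frames = []
    for sp in spikes:
        mean = sp.copies * library_scale * (1.0 if sp.labeled else leakage)
        n = rng.poisson(mean) if mean > 0 else 0
        if n == 0:
            continue
        flen = np.minimum(rng.integers(fragment_min, fragment_max + 1, size=n), sp.length)
        fs = np.floor(rng.random(n) * (sp.length - flen + 1)).astype(np.int64)
        frames.append(pd.DataFrame(
            {"chrom": sp.spike_id, "start": fs, "end": fs + flen,
             "name": name, "score": 0, "strand": "+"}
        ))
    if not frames:
        return empty_records()
    return pd.concat(frames, ignore_index=True)


def emit_chip(signal_blocks: pd.DataFrame, background_rate: float,
              non_transcribed: pd.DataFrame, seed, library_scale: float = 1.0,
              fragment_min: int = 150, fragment_max: int = 300) -> pd.DataFrame:
    """Unstranded ChIP fragments: signal proportional to a block occupancy
    profile (columns chrom/start/end/rate_per_kb) plus a uniform background
    over non-transcribed regions at ``background_rate`` reads/kb."""
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if (signal_blocks is None or len(signal_blocks) == 0) and \
       (non_transcribed is None or len(non_transcribed) == 0):
        raise ValueError("emit_chip needs at least one signal block or background region")
    rng = _as_rng(seed)
    frames = []
    if signal_blocks is not None and len(signal_blocks):
        for row in signal_blocks.itertuples(index=False):
            ivl = pd.DataFrame({"chrom": [row.chrom], "start": [row.start],
                                "end": [row.end], "name": ["sig"], "score": [0],
                                "strand": ["."]})
            frames.append(fragment_intervals(
                ivl, fragment_min, fragment_max, row.rate_per_kb, rng,
                library_scale=library_scale, name="chip_signal"))
    if non_transcribed is not None and len(non_transcribed) and background_rate > 0:
        bg = non_transcribed.copy()
        bg["strand"] = "."
        if "name" not in bg:
            bg["name"] = "bg"
        if "score" not in bg:
            bg["score"] = 0
        frames.append(fragment_intervals(
            bg, fragment_min, fragment_max, background_rate, rng,
            library_scale=library_scale, name="chip_bg"))
    frames = [f for f in frames if len(f)]
    if not frames:
        return empty_records()
    out = pd.concat(frames, ignore_index=True)
    out["strand"] = "."
    return out


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def make_genome(n_genes: int, length_min: int = 10_000, length_max: int = 100_000,
                intergenic_gap: int = 20_000, n_chroms: int = 2, seed=0,
                spikeins: list[SpikeInSpec] | None = None,
                nt_buffer: int = 2_000) -> Genome:
    """Synthetic genome: genes with log-uniform lengths separated by fixed
    intergenic gaps; the gap interiors (minus a buffer) form the
    non-transcribed regions used for ChIP background normalization."""
    rng = _as_rng(seed)
    if spikeins is None:
        spikeins = default_spikeins()
    genes: list[GeneModel] = []
    nt_rows = []
    chrom_sizes: dict[str, int] = {}
    if n_genes > 0:
        lengths = np.exp(rng.uniform(np.log(length_min), np.log(length_max), n_genes))
        lengths = np.round(lengths).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n_genes)
        per_chrom = -(-n_genes // n_chroms)
        g = 0
        for c in range(n_chroms):
            chrom = f"chr{c + 1}"
            pos = intergenic_gap
            first = True
            while g < n_genes and g < (c + 1) * per_chrom:
                if not first:
                    nt_rows.append((chrom, pos - intergenic_gap + nt_buffer, pos - nt_buffer))
                genes.append(GeneModel(f"g{g + 1:04d}", chrom, pos,
                                       pos + int(lengths[g]), str(strands[g])))
                pos += int(lengths[g]) + intergenic_gap
                g += 1
                first = False
            nt_rows.append((chrom, pos - intergenic_gap + nt_buffer, pos - nt_buffer))
            chrom_sizes[chrom] = pos
    else:
        chrom_sizes["chr1"] = intergenic_gap
        nt_rows.append(("chr1", nt_buffer, intergenic_gap - nt_buffer))
    for sp in spikeins:
        chrom_sizes[sp.spike_id] = sp.length
    nt = pd.DataFrame(nt_rows, columns=["chrom", "start", "end"])
    nt = nt[nt["end"] > nt["start"]].reset_index(drop=True)
    return Genome(genes=genes, chrom_sizes=chrom_sizes, non_transcribed=nt,
                  spikeins=list(spikeins))


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth serialized next to every simulated dataset."""

    genes: pd.DataFrame    # gene_id, condition, initiation_rate, mean_velocity_kb_min
    samples: pd.DataFrame  # sample, condition, replicate, library_scale


@dataclass
class SimulatedDataset:
    genome: Genome
    samples: pd.DataFrame  # sample, condition, replicate, library_scale
    ttseq: dict = field(default_factory=dict)
    mnet: dict = field(default_factory=dict)
    chip: dict = field(default_factory=dict)
    truth: SimTruth | None = None


def default_warmup(genome: Genome, kinetics: dict, conditions) -> float:
    """2 * (max gene length / slowest effective velocity): time to flush the
    longest gene twice, enough to reach steady state when requested."""
    if not genome.genes:
        return 0.0
    max_len = max(g.length for g in genome.genes) / 1000.0  # kb
    min_v = min(min(k.velocity_values) for k in kinetics.values())
    min_factor = min(c.velocity_factor for c in conditions)
    return 2.0 * max_len / (min_v * min_factor)


def emit_dataset(genome: Genome, kinetics: dict, conditions: list[ConditionSpec],
                 sampling: SamplingSpec, seed: int,
                 assays: tuple = ASSAYS, spike_leakage: float = 0.0) -> SimulatedDataset:
    """Simulate every sample of a multi-condition, multi-replicate design.

    ``kinetics`` maps gene_id -> KineticsSpec. Sample names are
    '<condition>_rep<k>'. Per-sample/per-assay random substreams are spawned
    from the master seed in a fixed order, so outputs are reproducible from
    (config, seed) alone.
    """
    if not any(c.velocity_factor == 1.0 for c in conditions):
        warnings.warn("no condition has velocity_factor 1 (control)")
    for g in genome.genes:
        if g.gene_id not in kinetics:
            raise ValueError(f"no kinetics for gene {g.gene_id}")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique")

    sample_rows = []
    scales = sampling.library_scales
    flat_scales = []
    i = 0
    for cond in conditions:
        for rep in range(1, sampling.replicates + 1):
            name = f"{cond.name}_rep{rep}"
            if scales is None:
                scale = 1.0
            elif isinstance(scales, dict):
                scale = float(scales.get(name, 1.0))
            else:
                scale = float(scales[i])
            if scale <= 0:
                raise ValueError(f"library scale for {name} must be > 0")
            sample_rows.append((name, cond.name, rep, scale))
            flat_scales.append(scale)
            i += 1
    samples = pd.DataFrame(sample_rows,
                           columns=["sample", "condition", "replicate", "library_scale"])

    warmup = sampling.warmup
    if warmup is None:
        warmup = default_warmup(genome, kinetics, conditions)
    t_sample = sampling.sample_time
    t0, t1 = sampling.label_start, t_sample

    master = np.random.SeedSequence(seed)
    # fixed spawn order: (condition, replicate) x (ttseq, tt-spikes, mnet, chip)
    children = iter(master.spawn(len(sample_rows) * 4))

    ds = SimulatedDataset(genome=genome, samples=samples)
    truth_gene_rows = []
    cond_by_name = {c.name: c for c in conditions}

    for row in sample_rows:
        name, cond_name, rep, scale = row
        cond = cond_by_name[cond_name]
        rng_tt = np.random.default_rng(next(children))
        rng_sp = np.random.default_rng(next(children))
        rng_mn = np.random.default_rng(next(children))
        rng_ch = np.random.default_rng(next(children))

        tt_frames, mn_frames = [], []
        chip_blocks = []
        for g in genome.genes:
            kin = kinetics[g.gene_id]
            if "ttseq" in assays:
                init = _initiation_times(rng_tt, kin.initiation_rate, -warmup, t1)
                ivls = labeled_intervals(init, g, kin, cond, t0, t1)
                tt_frames.append(fragment_intervals(
                    ivls, sampling.fragment_min, sampling.fragment_max,
                    sampling.ttseq_depth_per_kb, rng_tt, library_scale=scale, name=name))
            if "mnet" in assays:
                init = _initiation_times(rng_mn, kin.initiation_rate, -warmup, t_sample)
                offs = positions_at(init, t_sample, kin, cond)
                keep = (init <= t_sample) & (offs < kin.length)
                offs = np.floor(offs[keep]).astype(np.int64)
                tag_n = rng_mn.poisson(sampling.mnet_tags_per_pol * scale, size=len(offs))
                mn_frames.append(tags_from_offsets(np.repeat(offs, tag_n), g, sample=name))
            if "chip" in assays:
                v_eff = kin.mean_velocity() * (
                    cond.velocity_factor if cond.onset_time <= t_sample else 1.0)
                occupancy = kin.initiation_rate / v_eff  # pol per kb
                chip_blocks.append((g.chrom, g.start, g.end,
                                    sampling.chip_reads_per_pol_kb * occupancy))
        if "ttseq" in assays:
            tt = pd.concat([f for f in tt_frames if len(f)], ignore_index=True) \
                if any(len(f) for f in tt_frames) else empty_records()
            sp = emit_spikeins(genome.spikeins, scale, rng_sp, leakage=spike_leakage,
                               fragment_min=sampling.fragment_min,
                               fragment_max=sampling.fragment_max, name=name)
            ds.ttseq[name] = pd.concat([tt, sp], ignore_index=True) if len(sp) else tt
        if "mnet" in assays:
            mn = pd.concat([f for f in mn_frames if len(f)], ignore_index=True) \
                if any(len(f) for f in mn_frames) else empty_records()
            spm = emit_spikeins(genome.spikeins, scale, rng_mn, leakage=spike_leakage,
                                fragment_min=25, fragment_max=110, name=name)
            ds.mnet[name] = pd.concat([mn, spm], ignore_index=True) if len(spm) else mn
        if "chip" in assays:
            blocks = pd.DataFrame(chip_blocks,
                                  columns=["chrom", "start", "end", "rate_per_kb"]) \
                if chip_blocks else None
            ds.chip[name] = emit_chip(blocks, sampling.chip_background_per_kb,
                                      genome.non_transcribed, rng_ch,
                                      library_scale=scale,
                                      fragment_min=sampling.fragment_min,
                                      fragment_max=sampling.fragment_max)

    for cond in conditions:
        eff = cond.velocity_factor if cond.onset_time <= t_sample else 1.0
        for g in genome.genes:
            kin = kinetics[g.gene_id]
            truth_gene_rows.append(
                (g.gene_id, cond.name, kin.initiation_rate, kin.mean_velocity() * eff))
    truth_genes = pd.DataFrame(
        truth_gene_rows,
        columns=["gene_id", "condition", "initiation_rate", "mean_velocity_kb_min"])
    ds.truth = SimTruth(genes=truth_genes, samples=samples.copy())
    return ds


def write_dataset(ds: SimulatedDataset, outdir, header: str | None = None) -> None:
    """Write the bundle: genes.bed, nontranscribed.bed, spikeins.tsv,
    per-sample BED6 files for each assay, and the ground-truth TSVs."""
    from pathlib import Path

    from .io import write_bed6

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed6(genes_to_frame(ds.genome.genes), out / "genes.bed", header=header)
    nt = ds.genome.non_transcribed
    with open(out / "nontranscribed.bed", "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        if nt is not None:
            for r in nt.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tnt\t0\t.\n")
    spikes = pd.DataFrame(
        [(s.spike_id, s.length, s.copies, s.labeled) for s in ds.genome.spikeins],
        columns=["spike_id", "length", "copies", "labeled"])
    _tsv(spikes, out / "spikeins.tsv", header)
    sizes = pd.DataFrame(sorted(ds.genome.chrom_sizes.items()),
                         columns=["chrom", "size"])
    _tsv(sizes, out / "chrom_sizes.tsv", header)
    for assay, store in (("ttseq", ds.ttseq), ("mnet", ds.mnet), ("chip", ds.chip)):
        for sample, df in store.items():
            write_bed6(df, out / f"{sample}.{assay}.bed", header=header)
    if ds.truth is not None:
        _tsv(ds.truth.genes, out / "truth_genes.tsv", header)
        _tsv(ds.truth.samples, out / "truth_samples.tsv", header)


def _tsv(df: pd.DataFrame, path, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
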