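"""The elongation-velocity proxy: spike-in-normalized TT-seq / mNET-seq ratio.

Pol II occupancy (mNET-seq) is proportional to initiation/velocity while
RNA synthesis (TT-seq) is proportional to initiation, so their normalized
ratio tracks elongation velocity up to a global constant. The statistic is
computed per 50-bp genome bin (TT-seq fragment midpoints over mNET-seq
last-base tags) and per gene (counts in the gene body without the first
1 kb), and condition contrasts are reported as log2 changes.

``ElongationVelocityModel`` is the modelling entry point: build it from
tag records plus a design, call :meth:`fit`, and read the per-gene
estimates, the median log2 change and its Wilcoxon test off the returned
:class:`VelocityResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .quantify import count_in_regions
from .stats import TestResult, boxplot_summary, wilcoxon_signed_rank
from .tracks import StrandedTrack


# ---------------------------------------------------------------------------
# Bin-level ratio
# ---------------------------------------------------------------------------

def combine_normalized(tracks: dict[str, StrandedTrack], sf: pd.Series,
                       samples) -> StrandedTrack:
    """Sum size-factor-normalized tracks over replicate samples."""
    out = None
    for s in samples:
        t = tracks[s].scaled(float(sf[s]))
        if out is None:
            out = StrandedTrack(resolution=t.resolution, chrom_sizes=dict(t.chrom_sizes))
        out.add_track(t)
    if out is None:
        raise ValueError("no samples to combine")
    return out


def velocity_bins(tt_mid_binned: StrandedTrack, mnet_binned: StrandedTrack) -> dict:
    """Per-bin velocity ratio (normalized TT midpoints / normalized mNET).

    Inputs are the replicate-combined, normalized binned tracks of one
    condition. Returns (chrom, strand) -> float array with NaN exactly
    where the mNET bin is zero (the 'no signal' gray bins).
    """
    if tt_mid_binned.resolution != mnet_binned.resolution:
        raise ValueError("bin grids mismatch between TT-seq and mNET-seq tracks")
    out = {}
    keys = set(tt_mid_binned.data) | set(mnet_binned.data)
    for chrom, strand in keys:
        tt = tt_mid_binned.get(chrom, strand)
        mn = mnet_binned.get(chrom, strand)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mn > 0, tt / np.where(mn > 0, mn, 1.0), np.nan)
        out[(chrom, strand)] = ratio
    return out


@dataclass
class VelocityMatrix:
    """Genes x TSS-anchored bins of velocity ratios (or log2 changes).

    NaN marks bins without mNET signal; ``gene_end_bin`` is the per-gene
    body length in bins (bins at or beyond it lie outside the gene).
    """

    values: np.ndarray
    gene_ids: list[str]
    bin_width: int
    gene_end_bin: np.ndarray
    anchor: str = "TSS"


def tss_aligned_bins(binned: dict | StrandedTrack, genes: list[GeneModel],
                     bin_width: int, n_bins: int) -> VelocityMatrix:
    """Extract genome-grid bin values along each gene from its TSS-containing
    bin, oriented in the transcription direction (minus-strand genes read
    right-to-left); positions past the chromosome are NaN."""
    vals = np.full((len(genes), n_bins), np.nan)
    ends = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        if isinstance(binned, StrandedTrack):
            arr = binned.get(g.chrom, g.strand)
        else:
            arr = binned.get((g.chrom, g.strand))
            if arr is None:
                arr = np.full(0, np.nan)
        nb = len(arr)
        if g.strand == "+":
            b0 = g.start // bin_width
            take = min(n_bins, nb - b0)
            if take > 0:
                vals[i, :take] = arr[b0:b0 + take]
        else:
            b0 = (g.end - 1) // bin_width
            take = min(n_bins, b0 + 1)
            if take > 0:
                vals[i, :take] = arr[b0 - take + 1:b0 + 1][::-1]
        ends[i] = -(-g.length // bin_width)
    return VelocityMatrix(vals, [g.gene_id for g in genes], bin_width, ends)


def velocity_log2_change(treated, control):
    """log2(treated / control), propagating NaN and mapping zero/zero to NaN."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(t / c)
    out[~np.isfinite(out)] = np.nan
    return out


def tilt_statistic(profile) -> float:
    """(mean of the last quartile of the body) - (mean of the first quartile).

    ``profile`` is a per-gene change vector over gene-body bins; NaN bins
    are ignored. Negative values mean the change deepens toward the 3' end
    (the downward tilt of an elongation defect)."""
    v = np.asarray(profile, dtype=float)
    n = len(v)
    q = n // 4
    if q == 0:
        return float("nan")
    first = v[:q]
    last = v[n - q:]
    if np.all(np.isnan(first)) or np.all(np.isnan(last)):
        return float("nan")
    return float(np.nanmean(last) - np.nanmean(first))


# ---------------------------------------------------------------------------
# Per-gene ratio
# ---------------------------------------------------------------------------

def velocity_per_gene(tt_mid_tags: pd.DataFrame, mnet_tags: pd.DataFrame,
                      genes: list[GeneModel], sf_tt: pd.Series, sf_mnet: pd.Series,
                      samples_tt, samples_mnet,
                      exclude_first: int = 1000) -> pd.Series:
    """Per-gene velocity ratio from counts in [TSS + exclude_first, TES].

    Replicates are summed after normalization; the ratio is normalized TT
    midpoint count over normalized mNET count. Genes not longer than
    ``exclude_first`` or with zero mNET signal give NaN (with a warning for
    the too-short case)."""
    regions = []
    short = []
    for g in genes:
        region = g.body_region(exclude_first)
        if region is None:
            short.append(g.gene_id)
            continue
        regions.append((g.gene_id, g.chrom, region[0], region[1], g.strand))
    if short:
        warnings.warn(f"{len(short)} gene(s) not longer than {exclude_first} bp "
                      f"excluded from per-gene velocity: {short[:5]}...")
    tt_counts = count_in_regions(tt_mid_tags, regions)
    mn_counts = count_in_regions(mnet_tags, regions)
    tt_norm = sum(tt_counts[s] / float(sf_tt[s]) for s in samples_tt
                  if s in tt_counts.columns)
    mn_norm = sum(mn_counts[s] / float(sf_mnet[s]) for s in samples_mnet
                  if s in mn_counts.columns)
    if np.isscalar(tt_norm) or np.isscalar(mn_norm):
        raise ValueError("no sample columns found for velocity_per_gene")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tt_norm / mn_norm
    ratio[mn_norm == 0] = np.nan
    out = pd.Series(np.nan, index=[g.gene_id for g in genes], name="velocity_ratio")
    out.loc[ratio.index] = ratio
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class ElongationVelocityModel:
    """Elongation-velocity contrast between two conditions.

    Parameters
    ----------
    tt_midpoints, mnet_tags : DataFrame
        Width-1 tag records (TT-seq fragment midpoints; mNET-seq
        last-incorporated-base tags) pooled over samples, with the sample
        name in the ``name`` column.
    genes : list of GeneModel
        The analysis gene set (already expression-filtered).
    design : DataFrame
        Columns ``sample`` and ``condition``; every sample present in the
        records and size factors.
    sf_tt, sf_mnet : Series
        Spike-in size factors per sample.
    control, treated : str
        Condition names contrasted by :meth:`fit`.
    """

    tt_midpoints: pd.DataFrame
    mnet_tags: pd.DataFrame
    genes: list[GeneModel]
    design: pd.DataFrame
    sf_tt: pd.Series
    sf_mnet: pd.Series
    control: str = "control"
    treated: str | None = None
    exclude_first: int = 1000
    bin_width: int = 50

    def __post_init__(self):
        conds = list(dict.fromkeys(self.design["condition"]))
        if self.control not in conds:
            raise ValueError(f"control condition {self.control!r} not in design")
        if self.treated is None:
            others = [c for c in conds if c != self.control]
            if len(others) != 1:
                raise ValueError("treated condition is ambiguous; pass treated=...")
            self.treated = others[0]

    def _samples(self, condition: str) -> list[str]:
        return list(self.design.loc[self.design["condition"] == condition, "sample"])

    def fit(self) -> "VelocityResults":
        per_cond = {}
        for cond in (self.control, self.treated):
            samples = self._samples(cond)
            per_cond[cond] = velocity_per_gene(
                self.tt_midpoints, self.mnet_tags, self.genes,
                self.sf_tt, self.sf_mnet, samples, samples,
                exclude_first=self.exclude_first)
        v_c = per_cond[self.control]
        v_t = per_cond[self.treated]
        log2_change = pd.Series(velocity_log2_change(v_t.to_numpy(), v_c.to_numpy()),
                                index=v_c.index, name="log2_velocity_change")
        finite = log2_change.dropna()
        test = wilcoxon_signed_rank(finite.to_numpy()) if len(finite) else None
        per_gene = pd.DataFrame({
            "length": [g.length for g in self.genes],
            f"velocity_{self.control}": v_c,
            f"velocity_{self.treated}": v_t,
            "log2_change": log2_change,
        }, index=v_c.index)
        per_gene.index.name = "gene_id"
        return VelocityResults(model=self, per_gene=per_gene, wilcoxon=test)


@dataclass
class VelocityResults:
    """Per-gene velocity estimates and the condition contrast."""

    model: ElongationVelocityModel
    per_gene: pd.DataFrame
    wilcoxon: TestResult | None

    @property
    def log2_change(self) -> pd.Series:
        return self.per_gene["log2_change"]

    @property
    def median_log2_change(self) -> float:
        return float(np.nanmedian(self.per_gene["log2_change"].to_numpy()))

    @property
    def n_genes(self) -> int:
        return int(self.per_gene["log2_change"].notna().sum())

    def boxplot(self):
        """Boxplot summary (hinges, notches, whiskers) of per-gene log2 changes."""
        return boxplot_summary(self.per_gene["log2_change"].dropna().to_numpy())

    def summary(self) -> str:
        m = self.model
        lines = [
            "Elongation velocity contrast (TT-seq / mNET-seq ratio)",
            "=" * 58,
            f"conditions:        {m.treated} vs {m.control}",
            f"genes analysed:    {self.n_genes} (of {len(m.genes)})",
            f"gene-body region:  TSS+{m.exclude_first} bp to TES",
            f"median log2 velocity change: {self.median_log2_change:+.4f}",
        ]
        if self.wilcoxon is not None:
            w = self.wilcoxon
            lines.append(
                f"one-sample Wilcoxon (mu=0):  W={w.statistic:.1f}, "
                f"p={w.p_value:.3g} [{w.method}, n={w.n}]")
        box = self.boxplot()
        lines.append(
            f"log2-change box:   median {box.median:+.3f}, "
            f"hinges [{box.hinge_lo:+.3f}, {box.hinge_hi:+.3f}], "
            f"notch [{box.notch_lo:+.3f}, {box.notch_hi:+.3f}]")
        return "\n".join(lines)

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"#{line}\n")
            self.per_gene.to_csv(fh, sep="\t", na_rep="NA", float_format="%.6g")
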