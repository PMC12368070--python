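"""Per-sample size factors by median-of-ratios and their application.

TT-seq and mNET-seq are anchored on labeled spike-in counts; ChIP-seq on
counts at non-transcribed regions. The factors follow the standard
median-of-ratios definition (ratio of each anchor row to its across-sample
geometric mean, median over rows); they are deliberately not rescaled to
geometric mean 1 — only ratios between samples matter downstream, and
normalized values are raw values divided by the factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def size_factors_median_of_ratios(anchor_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from an anchor count matrix.

    Per row the pseudo-reference is the geometric mean across samples; rows
    containing any zero are excluded; the factor of sample j is the median
    over usable rows of count_ij / reference_i.
    """
    if len(anchor_counts) == 0:
        raise ValueError("no anchor rows for size-factor estimation")
    mat = anchor_counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("anchor counts must be non-negative")
    usable = np.all(mat > 0, axis=1)
    if not usable.any():
        raise ValueError("no anchor row with all-positive counts")
    mat = mat[usable]
    log_ref = np.mean(np.log(mat), axis=1, keepdims=True)
    ratios = np.exp(np.log(mat) - log_ref)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=anchor_counts.columns, name="size_factor")


def spikein_size_factors(counts: pd.DataFrame, spike_ids) -> pd.Series:
    """Median-of-ratios on labeled spike-in rows only (4sU purification
    retains the labeled spikes; unlabeled ones are not usable anchors)."""
    rows = [s for s in spike_ids if s in counts.index]
    if len(rows) < 1:
        raise ValueError("no labeled spike-in rows present in the count table")
    return size_factors_median_of_ratios(counts.loc[rows])


def background_size_factors(region_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios over non-transcribed-region count rows (ChIP-seq)."""
    return size_factors_median_of_ratios(region_counts)


def apply_size_factors(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Normalized counts: value / factor, column-wise."""
    sf = sf.reindex(counts.columns)
    if sf.isna().any():
        missing = list(counts.columns[sf.isna()])
        raise ValueError(f"missing size factors for samples: {missing}")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / sf


def validate_regions_outside_genes(regions: pd.DataFrame, genes) -> None:
    """Reject background regions that overlap any gene body."""
    for r in regions.itertuples(index=False):
        for g in genes:
            if g.chrom == r.chrom and r.start < g.end and r.end > g.start:
                raise ValueError(
                    f"non-transcribed region {r.chrom}:{r.start}-{r.end} "
                    f"overlaps gene {g.gene_id}")
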