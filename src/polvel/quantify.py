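"""From records to tracks and gene-level counts.

Conventions: mNET-seq signal is the last incorporated base (the 3'-most
base of the nascent RNA); TT-seq velocity input is fragment midpoints;
gene-body counts use whole fragments assigned strand-specifically with the
IntersectionNotEmpty rule; expressed genes are the non-overlapping genes
with median TT-seq RPK strictly above 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneModel, overlapping_gene_ids
from .io import empty_records


def last_base_positions(fragments: pd.DataFrame) -> pd.DataFrame:
    """Width-1 tags at the last incorporated base of each fragment.

    For a plus-strand fragment [s, e) that base is e-1; for a minus-strand
    fragment it is s. Unstranded records are rejected.
    """
    if len(fragments) == 0:
        return empty_records()
    strand = fragments["strand"].to_numpy()
    if np.any(strand == "."):
        raise ValueError("last_base_positions requires stranded fragments")
    plus = strand == "+"
    base = np.where(plus, fragments["end"].to_numpy(np.int64) - 1,
                    fragments["start"].to_numpy(np.int64))
    out = fragments.copy()
    out["start"] = base
    out["end"] = base + 1
    return out


def fragment_midpoints(fragments: pd.DataFrame) -> pd.DataFrame:
    """Width-1 tags at the fragment midpoint (s+e)//2; strand preserved."""
    if len(fragments) == 0:
        return empty_records()
    mid = (fragments["start"].to_numpy(np.int64) + fragments["end"].to_numpy(np.int64)) // 2
    out = fragments.copy()
    out["start"] = mid
    out["end"] = mid + 1
    return out


# ---------------------------------------------------------------------------
# Feature counting (IntersectionNotEmpty)
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Features x samples non-negative integer counts plus the per-sample
    ambiguous and unassigned tallies (records resolvable to no single
    feature, and records overlapping no feature)."""

    counts: pd.DataFrame
    ambiguous: pd.Series
    unassigned: pd.Series

    def conservation_ok(self, n_records: dict[str, int]) -> bool:
        for sample, n in n_records.items():
            tot = int(self.counts[sample].sum() + self.ambiguous[sample]
                      + self.unassigned[sample])
            if tot != n:
                return False
        return True


def _assign_sorted(starts, ends, rec_s, rec_e):
    """Assignment against sorted non-overlapping features: returns the
    feature index, -1 for unassigned, -2 for ambiguous (>=2 overlapped)."""
    js = np.searchsorted(ends, rec_s, side="right")
    je = np.searchsorted(starts, rec_e, side="left")
    n_hit = je - js
    out = np.where(n_hit == 1, js, np.where(n_hit == 0, -1, -2))
    return out


def _assign_tree(tree: IntervalTree, ids, rec_s, rec_e, starts, ends):
    """General IntersectionNotEmpty against possibly-overlapping features.

    Per record: the candidate features; a feature is kept when it covers
    every base (within the record) covered by any feature — the
    intersection of the non-empty per-base feature sets. Exactly one
    survivor assigns the record; zero or several is ambiguous."""
    out = np.empty(len(rec_s), dtype=np.int64)
    for i, (s, e) in enumerate(zip(rec_s, rec_e)):
        hits = tree.overlap(s, e)
        if not hits:
            out[i] = -1
            continue
        if len(hits) == 1:
            out[i] = next(iter(hits)).data
            continue
        cov_lo = min(max(h.begin, s) for h in hits)
        cov_hi = max(min(h.end, e) for h in hits)
        winners = [h.data for h in hits if h.begin <= cov_lo and h.end >= cov_hi]
        out[i] = winners[0] if len(winners) == 1 else -2
    return out


def count_features(records: pd.DataFrame, genes: list[GeneModel],
                   sample_col: str = "name", strand_specific: bool = True) -> CountTable:
    """Assign records to genes with the IntersectionNotEmpty mode.

    A record counts for a gene when, after discarding bases shared by
    multiple genes, its remaining covered bases belong to exactly one gene
    (formally: the intersection of the non-empty per-base gene sets has
    size one). Records overlapping features but resolvable to none are
    ambiguous; records overlapping nothing are unassigned. With
    ``strand_specific`` (the default) only same-strand overlap counts and
    unstranded ChIP records match genes on either strand only when
    strand_specific=False.
    """
    gene_ids = [g.gene_id for g in genes]
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    samples = sorted(records[sample_col].unique()) if len(records) else []
    counts = pd.DataFrame(0, index=pd.Index(gene_ids, name="feature_id"),
                          columns=samples, dtype=np.int64)
    ambiguous = pd.Series(0, index=samples, dtype=np.int64)
    unassigned = pd.Series(0, index=samples, dtype=np.int64)
    if len(records) == 0:
        return CountTable(counts, ambiguous, unassigned)

    # group genes by (chrom, strand-key); pre-sort and detect overlap
    groups: dict[tuple, list[GeneModel]] = {}
    for g in genes:
        key = (g.chrom, g.strand if strand_specific else "*")
        groups.setdefault(key, []).append(g)
    prepared = {}
    for key, glist in groups.items():
        glist.sort(key=lambda g: (g.start, g.end))
        starts = np.array([g.start for g in glist], dtype=np.int64)
        ends = np.array([g.end for g in glist], dtype=np.int64)
        overlapping = bool(len(glist) > 1 and np.any(starts[1:] < np.maximum.accumulate(ends)[:-1]))
        tree = None
        if overlapping:
            tree = IntervalTree()
            for g in glist:
                tree.addi(g.start, g.end, gene_index[g.gene_id])
        prepared[key] = (glist, starts, ends, tree)

    rec_strand = records["strand"].to_numpy()
    for (chrom, strand), sub in records.groupby(["chrom", "strand"], sort=True):
        key = (chrom, strand if strand_specific else "*")
        if strand_specific and strand == ".":
            # unstranded records never match in strand-specific mode
            for sample, cnt in sub[sample_col].value_counts().items():
                unassigned[sample] += cnt
            continue
        entry = prepared.get(key)
        if entry is None:
            for sample, cnt in sub[sample_col].value_counts().items():
                unassigned[sample] += cnt
            continue
        glist, starts, ends, tree = entry
        rs = sub["start"].to_numpy(np.int64)
        re_ = sub["end"].to_numpy(np.int64)
        if tree is None:
            idx_local = _assign_sorted(starts, ends, rs, re_)
            gidx = np.array([gene_index[g.gene_id] for g in glist], dtype=np.int64)
            idx = np.where(idx_local >= 0,
                           gidx[np.clip(idx_local, 0, len(glist) - 1)], idx_local)
        else:
            idx = _assign_tree(tree, None, rs, re_, starts, ends)
        sub_samples = sub[sample_col].to_numpy()
        for sample in np.unique(sub_samples):
            m = sub_samples == sample
            vals = idx[m]
            unassigned[sample] += int((vals == -1).sum())
            ambiguous[sample] += int((vals == -2).sum())
            assigned = vals[vals >= 0]
            if len(assigned):
                bc = np.bincount(assigned, minlength=len(gene_ids))
                counts[sample] += bc
    return CountTable(counts, ambiguous, unassigned)


def count_in_regions(tags: pd.DataFrame, regions: list[tuple],
                     sample_col: str = "name", strand_specific: bool = True) -> pd.DataFrame:
    """Simple per-region tag counting (same-strand containment of the tag
    base). ``regions`` is a list of (region_id, chrom, start, end, strand).
    Used for velocity gene-body counts where regions are the filtered,
    non-overlapping gene bodies."""
    ids = [r[0] for r in regions]
    samples = sorted(tags[sample_col].unique()) if len(tags) else []
    out = pd.DataFrame(0, index=pd.Index(ids, name="feature_id"),
                       columns=samples, dtype=np.int64)
    if len(tags) == 0:
        return out
    by_key: dict[tuple, list] = {}
    for i, (rid, chrom, s, e, strand) in enumerate(regions):
        by_key.setdefault((chrom, strand), []).append((s, e, i))
    for (chrom, strand), items in by_key.items():
        items.sort()
        starts = np.array([x[0] for x in items], dtype=np.int64)
        ends = np.array([x[1] for x in items], dtype=np.int64)
        ridx = np.array([x[2] for x in items], dtype=np.int64)
        if strand_specific:
            sub = tags[(tags["chrom"] == chrom) & (tags["strand"] == strand)]
        else:
            sub = tags[tags["chrom"] == chrom]
        if len(sub) == 0:
            continue
        pos = sub["start"].to_numpy(np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        sub_samples = sub[sample_col].to_numpy()
        for sample in np.unique(sub_samples):
            m = (sub_samples == sample) & ok
            if m.any():
                bc = np.bincount(ridx[j[m]], minlength=len(ids))
                out[sample] += bc
    return out


# ---------------------------------------------------------------------------
# Expression filter
# ---------------------------------------------------------------------------

@dataclass
class ExpressedGeneSet:
    """Genes retained for analysis: non-overlapping and with median TT-seq
    RPK strictly above the threshold."""

    gene_ids: list[str]
    rpk: pd.Series            # median RPK per retained gene
    rpk_threshold: float = 10.0


def rpk_and_filter(counts: pd.DataFrame, genes: list[GeneModel],
                   threshold: float = 10.0) -> ExpressedGeneSet:
    """RPK = count / (gene length / 1000); a gene is retained iff its
    median RPK across the TT-seq samples is strictly greater than the
    threshold and it overlaps no other gene in the input set."""
    lengths = {}
    for g in genes:
        if g.length == 0:
            raise ValueError(f"gene {g.gene_id} has zero length")
        lengths[g.gene_id] = g.length
    overlapping = overlapping_gene_ids(genes)
    med = {}
    kept = []
    for g in genes:
        if g.gene_id not in counts.index:
            continue
        rpk = counts.loc[g.gene_id] / (lengths[g.gene_id] / 1000.0)
        m = float(np.median(rpk.to_numpy()))
        med[g.gene_id] = m
        if m > threshold and g.gene_id not in overlapping:
            kept.append(g.gene_id)
    return ExpressedGeneSet(gene_ids=kept,
                            rpk=pd.Series({k: med[k] for k in kept}, dtype=float),
                            rpk_threshold=threshold)
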