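"""Gene models and interval helpers.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion happens only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """One gene: genomic span, strand, and the derived TSS/TES.

    The gene body runs from the transcript start site (TSS) to the
    transcript end site (TES) in the direction of transcription. For a
    plus-strand gene TSS = start; for a minus-strand gene TSS = end - 1
    (the last base of the half-open span).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def offset_to_genome(self, offset: int | np.ndarray) -> int | np.ndarray:
        """Map a gene-body offset (0 = TSS) to a genomic base."""
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset

    def body_region(self, exclude_first: int = 0):
        """Genomic (start, end) of the body with the first ``exclude_first``
        bases (in transcription direction) removed. Returns None when the
        gene is not longer than the excluded prefix."""
        if self.length <= exclude_first:
            return None
        if self.strand == "+":
            return (self.start + exclude_first, self.end)
        return (self.start, self.end - exclude_first)


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """BED6-style frame (score column carries 0; name = gene_id)."""
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": np.array([g.start for g in genes], dtype=np.int64),
            "end": np.array([g.end for g in genes], dtype=np.int64),
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )


def overlapping_gene_ids(genes: list[GeneModel]) -> set[str]:
    """Gene ids that overlap at least one other gene on the same chromosome
    (either strand), mirroring curated-annotation practice of dropping
    ambiguous loci before expression filtering."""
    flagged: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end))
        max_end = -1
        max_gene: GeneModel | None = None
        for g in glist:
            if max_gene is not None and g.start < max_end:
                flagged.add(g.gene_id)
                flagged.add(max_gene.gene_id)
            if g.end > max_end:
                max_end = g.end
                max_gene = g
    return flagged


@dataclass
class Genome:
    """A gene annotation plus chromosome sizes and (optionally) the
    non-transcribed regions used for ChIP-seq background normalization."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    non_transcribed: pd.DataFrame | None = None
    spikeins: list = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)
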