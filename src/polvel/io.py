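"""Readers and writers for the plain-text formats the pipeline touches.

BED6 for fragments/tags and gene annotations, two-file stranded bedGraph
for coverage tracks, TSV for count matrices and size factors, YAML for
configuration. Every reader validates and reports the offending line; every
writer/reader pair round-trips losslessly on valid data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genes import GeneModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _parse_bed6_line(line: str, path, lineno: int, width_one: bool = False):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}")
    chrom, start_s, end_s, name, score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
    if start < 0:
        raise FormatError(f"{path}:{lineno}: negative start {start}")
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start ({start}) must be < end ({end})")
    if strand not in ("+", "-", "."):
        raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
    if width_one and end - start != 1:
        raise FormatError(f"{path}:{lineno}: tag records must have width 1, got {end - start}")
    return chrom, start, end, name, score, strand


def read_bed6(path, width_one: bool = False) -> pd.DataFrame:
    """Read a BED6 file into a frame with columns chrom/start/end/name/score/strand.

    Lines starting with '#' or 'track' are skipped. ``width_one=True``
    additionally enforces single-base (tag) records.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            rows.append(_parse_bed6_line(line, path, lineno, width_one=width_one))
    if not rows:
        return empty_records()
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=object),
            "strand": pd.Series(dtype=str),
        }
    )


def write_bed6(records: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for chrom, start, end, name, score, strand in zip(
            records["chrom"], records["start"], records["end"],
            records["name"], records["score"], records["strand"],
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_gene_bed(path) -> list[GeneModel]:
    """Read a gene annotation BED6. Genes must be stranded (+/-) and ids unique."""
    df = read_bed6(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand == ".":
            raise FormatError(f"{path}: gene {row.name!r} has strand '.'; genes must be stranded")
        if row.name in seen:
            raise FormatError(f"{path}: duplicate gene_id {row.name!r}")
        seen.add(row.name)
        genes.append(
            GeneModel(
                gene_id=row.name, chrom=row.chrom, start=int(row.start),
                end=int(row.end), strand=row.strand,
                biotype=str(row.score) if not str(row.score).isdigit() else "protein_coding",
            )
        )
    return genes


def write_gene_bed(genes: list[GeneModel], path, header: str | None = None) -> None:
    from .genes import genes_to_frame

    write_bed6(genes_to_frame(genes), path, header=header)


# ---------------------------------------------------------------------------
# bedGraph (two files, one per strand)
# ---------------------------------------------------------------------------

def write_bedgraph(track, path_plus, path_minus) -> None:
    """Write a StrandedTrack as two bedGraph files (+ and - strand).

    Runs of equal value are merged; zero runs are omitted. Negative values
    are rejected. Coordinates are in bases (track resolution is expanded).
    """
    for path, strand in ((path_plus, "+"), (path_minus, "-")):
        with open(path, "w") as fh:
            for (chrom, s), values in sorted(track.data.items()):
                if s != strand:
                    continue
                if np.any(values < 0):
                    raise ValueError(f"negative coverage value on {chrom}{s}")
                _write_bedgraph_chrom(fh, chrom, values, track.resolution)


def _write_bedgraph_chrom(fh, chrom: str, values: np.ndarray, resolution: int) -> None:
    n = len(values)
    if n == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for b0, b1 in zip(starts, ends):
        v = values[b0]
        if v == 0:
            continue
        v_out = int(v) if float(v).is_integer() else float(v)
        fh.write(f"{chrom}\t{b0 * resolution}\t{b1 * resolution}\t{v_out}\n")


def read_bedgraph(path_plus, path_minus, chrom_sizes: dict[str, int]):
    """Read a two-file stranded bedGraph back into a per-base StrandedTrack."""
    from .tracks import StrandedTrack

    track = StrandedTrack(resolution=1, chrom_sizes=dict(chrom_sizes))
    for path, strand in ((path_plus, "+"), (path_minus, "-")):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 fields")
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if v < 0:
                    raise FormatError(f"{path}:{lineno}: negative value {v}")
                arr = track.ensure(chrom, strand)
                arr[s:e] += v
    return track


# ---------------------------------------------------------------------------
# count / size-factor TSVs
# ---------------------------------------------------------------------------

def write_count_tsv(counts: pd.DataFrame, path, header: str | None = None) -> None:
    """genes x samples integer matrix; first column 'feature_id'."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        out = counts.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")


def read_count_tsv(path, integer: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.columns.empty:
        raise FormatError(f"{path}: no sample columns in count table")
    if integer:
        for col in df.columns:
            vals = df[col]
            if not np.allclose(vals, np.round(vals)):
                raise FormatError(f"{path}: non-integer count in column {col!r}")
        df = df.round().astype(np.int64)
    return df


def write_size_factors(sf: dict[str, float] | pd.Series, path, header: str | None = None) -> None:
    series = pd.Series(sf, name="size_factor")
    series.index.name = "sample"
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        series.to_csv(fh, sep="\t")


def read_size_factors(path) -> pd.Series:
    series = pd.read_csv(path, sep="\t", comment="#", index_col=0)["size_factor"]
    if (series <= 0).any():
        raise FormatError(f"{path}: size factors must be positive")
    return series


def write_matrix_tsv(values: np.ndarray, row_ids, col_ids, path,
                     header: str | None = None, na_token: str = "NA") -> None:
    """Write a genes x bins matrix with NA tokens for masked cells."""
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.index.name = "gene_id"
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", na_rep=na_token, float_format="%.6g")
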