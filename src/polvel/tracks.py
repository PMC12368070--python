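"""Stranded coverage tracks at base-pair or binned resolution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StrandedTrack:
    """Non-negative coverage keyed by (chrom, strand).

    ``resolution`` is the bin width in bp (1 = per-base). Arrays span the
    whole chromosome from origin 0 so that genome-anchored bin grids line
    up across samples and assays. Unstranded data lives on strand '.'.
    """

    resolution: int = 1
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.resolution)

    def ensure(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.data:
            if chrom not in self.chrom_sizes:
                raise KeyError(f"unknown chromosome {chrom!r}")
            self.data[key] = np.zeros(self.n_bins(chrom), dtype=np.float64)
        return self.data[key]

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key in self.data:
            return self.data[key]
        return np.zeros(self.n_bins(chrom), dtype=np.float64)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def scaled(self, factor: float) -> "StrandedTrack":
        """Divide every value by ``factor`` (size-factor normalization)."""
        if factor <= 0:
            raise ValueError(f"size factor must be positive, got {factor}")
        out = StrandedTrack(resolution=self.resolution, chrom_sizes=dict(self.chrom_sizes))
        for key, arr in self.data.items():
            out.data[key] = arr / factor
        return out

    def add_track(self, other: "StrandedTrack") -> None:
        if other.resolution != self.resolution:
            raise ValueError("cannot add tracks with different resolutions")
        for key, arr in other.data.items():
            chrom, strand = key
            self.ensure(chrom, strand)
            self.data[key] += arr

    def allclose(self, other: "StrandedTrack", **kw) -> bool:
        if self.resolution != other.resolution:
            return False
        keys = set(self.data) | set(other.data)
        for chrom, strand in keys:
            if not np.allclose(self.get(chrom, strand), other.get(chrom, strand), **kw):
                return False
        return True


def coverage_track(records: pd.DataFrame, chrom_sizes: dict[str, int],
                   bin_width: int = 1, per_base: bool = True) -> StrandedTrack:
    """Per-base (or directly binned) occupancy from BED6-style records.

    Tags (width 1) add 1 at their base; fragments add 1 over every base of
    [start, end). With ``bin_width > 1`` the value of bin b is the sum of
    per-base values over [b*w, (b+1)*w) — identical to building the
    per-base track and then binning it, but without materialising the
    per-base array for wide genomes.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if not per_base and bin_width == 1:
        per_base = True
    track = StrandedTrack(resolution=bin_width, chrom_sizes=dict(chrom_sizes))
    if len(records) == 0:
        return track
    for (chrom, strand), sub in records.groupby(["chrom", "strand"], sort=True):
        arr = track.ensure(chrom, strand)
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        size = track.chrom_sizes[chrom]
        if starts.min() < 0 or ends.max() > size:
            raise ValueError(f"record out of bounds on {chrom} (size {size})")
        if bin_width == 1:
            diff = np.zeros(size + 1, dtype=np.float64)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
            arr += np.cumsum(diff[:-1])
        else:
            widths = ends - starts
            if np.all(widths == 1):
                np.add.at(arr, starts // bin_width, 1.0)
            else:
                # exact partial-overlap accumulation via a per-base diff array
                diff = np.zeros(size + 1, dtype=np.float64)
                np.add.at(diff, starts, 1.0)
                np.add.at(diff, ends, -1.0)
                per = np.cumsum(diff[:-1])
                nb = track.n_bins(chrom)
                pad = nb * bin_width - size
                if pad:
                    per = np.concatenate([per, np.zeros(pad)])
                arr += per.reshape(nb, bin_width).sum(axis=1)
    return track


def bin_track(track: StrandedTrack, bin_width: int) -> StrandedTrack:
    """Aggregate a per-base track into genome-anchored bins of ``bin_width``.

    Bin b covers [b*w, (b+1)*w); its value is the sum of per-base values.
    ``bin_width=1`` on a per-base track is the identity.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if track.resolution != 1:
        raise ValueError("bin_track expects a per-base (resolution 1) track")
    out = StrandedTrack(resolution=bin_width, chrom_sizes=dict(track.chrom_sizes))
    for (chrom, strand), arr in track.data.items():
        nb = out.n_bins(chrom)
        pad = nb * bin_width - len(arr)
        padded = np.concatenate([arr, np.zeros(pad)]) if pad else arr
        out.data[(chrom, strand)] = padded.reshape(nb, bin_width).sum(axis=1)
    return out
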