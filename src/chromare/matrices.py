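"""Anchor-centred binned signal matrices and meta-profiles.

A signal matrix has one row per anchor (a peak summit or a TSS) and one
column per bin over [-flank, +flank).  Cell values are the mean per-bp
density over the bin so changing the bin size does not rescale values.
Rows for minus-strand anchors are column-reversed, so "upstream" is always
to the left.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, IntervalSet, TssRecord

__all__ = [
    "AnchorSet",
    "SignalMatrix",
    "MetaProfile",
    "compute_matrix",
    "meta_profile",
    "normalize_matrix",
    "plot_profile",
]


@dataclass(frozen=True)
class AnchorSet:
    """Ordered strand-aware genomic points (summits or TSS)."""

    ids: tuple[str, ...]
    chroms: tuple[str, ...]
    positions: tuple[int, ...]
    strands: tuple[str, ...]
    provenance: str = "summits"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.chroms) == len(self.positions) == len(self.strands) == n):
            raise ValueError("anchor fields must have equal length")
        if any(s not in ("+", "-", ".") for s in self.strands):
            raise ValueError("anchor strands must be +, - or .")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_intervals(cls, intervals: IntervalSet) -> "AnchorSet":
        """Anchor at each interval's summit, or its midpoint when absent."""
        ids = tuple(intervals.ids())
        return cls(
            ids,
            tuple(iv.chrom for iv in intervals),
            tuple(iv.summit_pos for iv in intervals),
            tuple(iv.strand for iv in intervals),
            provenance="summits",
        )

    @classmethod
    def from_tss(cls, records: Sequence[TssRecord]) -> "AnchorSet":
        return cls(
            tuple(r.gene_id for r in records),
            tuple(r.chrom for r in records),
            tuple(r.pos for r in records),
            tuple(r.strand for r in records),
            provenance="tss",
        )


@dataclass(frozen=True)
class SignalMatrix:
    """Per-anchor binned mean density over [-flank, +flank)."""

    values: np.ndarray  # n_anchors x n_bins
    anchor_ids: tuple[str, ...]
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("matrix values must be 2-D")
        if values.shape[0] != len(self.anchor_ids):
            raise ValueError("one anchor id per row required")
        if 2 * self.flank % self.bin_size or self.bin_size <= 0 or self.flank <= 0:
            raise ValueError("bin size must divide 2 * flank")
        if values.shape[1] != 2 * self.flank // self.bin_size:
            raise ValueError("column count must equal 2 * flank / bin")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bp offset of each bin centre relative to the anchor."""
        edges = -self.flank + self.bin_size * np.arange(self.n_bins)
        return edges + self.bin_size / 2.0

    def subset(self, row_index: np.ndarray) -> "SignalMatrix":
        return replace(
            self,
            values=self.values[row_index],
            anchor_ids=tuple(np.asarray(self.anchor_ids)[row_index]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[f"{c:.1f}" for c in self.bin_centers],
        )
        df.insert(0, "anchor_id", list(self.anchor_ids))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = tuple(df["anchor_id"].astype(str))
        centers = np.array([float(c) for c in df.columns[1:]])
        bin_size = int(round(centers[1] - centers[0]))
        flank = int(round(-(centers[0] - bin_size / 2.0)))
        return cls(df.iloc[:, 1:].to_numpy(float), ids, flank, bin_size)


@dataclass(frozen=True)
class MetaProfile:
    """Column-wise mean of a signal matrix."""

    bin_centers: np.ndarray
    values: np.ndarray
    n: int
    bin_size: int

    def __len__(self) -> int:
        return len(self.values)


def compute_matrix(
    track: CoverageTrack, anchors: AnchorSet, flank: int = 1000, bin_size: int = 10
) -> SignalMatrix:
    """Anchor-centred binned density; the seqMINER-style aggregation step.

    Bases beyond chromosome ends contribute 0 to their bin's mean.  The
    anchor base itself falls in the first downstream bin.
    """
    if flank <= 0 or bin_size <= 0 or (2 * flank) % bin_size:
        raise ValueError("bin size must divide 2 * flank")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_bins), dtype=float)
    for i in range(len(anchors)):
        chrom, pos = anchors.chroms[i], anchors.positions[i]
        window = track.window(chrom, pos - flank, pos + flank)
        row = window.reshape(n_bins, bin_size).mean(axis=1)
        if anchors.strands[i] == "-":
            row = row[::-1]
        values[i] = row
    return SignalMatrix(values, anchors.ids, flank, bin_size)


def meta_profile(matrix: SignalMatrix) -> MetaProfile:
    """Column-wise mean profile; undefined (error) for an empty matrix."""
    if matrix.values.shape[0] == 0:
        raise ValueError("meta-profile of an empty matrix is undefined")
    return MetaProfile(
        matrix.bin_centers, matrix.values.mean(axis=0),
        matrix.values.shape[0], matrix.bin_size,
    )


def normalize_matrix(
    matrix: SignalMatrix, mode: str = "none", track_total: float | None = None
) -> SignalMatrix:
    """Explicit normalisation modes.

    ``per_row_max`` divides each row by its own maximum (all-zero rows are
    left untouched); ``library_size`` scales by 1e6 / total track signal,
    the usual counts-per-million convention.
    """
    if mode == "none":
        return matrix
    if mode == "per_row_max":
        maxima = matrix.values.max(axis=1, keepdims=True)
        scale = np.where(maxima > 0, maxima, 1.0)
        return replace(matrix, values=matrix.values / scale)
    if mode == "library_size":
        if track_total is None or track_total <= 0:
            raise ValueError("library_size mode requires a positive track total")
        return replace(matrix, values=matrix.values * 1e6 / track_total)
    raise ValueError(f"unknown normalization mode {mode!r}")


def plot_profile(profiles, labels=None, ax=None, xlabel="distance from anchor (bp)"):
    """Basic meta-profile plot helper (lazy matplotlib import)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    if isinstance(profiles, MetaProfile):
        profiles = [profiles]
    for k, prof in enumerate(profiles):
        label = labels[k] if labels else None
        ax.plot(prof.bin_centers, prof.values, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean density")
    if labels:
        ax.legend(frameon=False)
    return ax
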