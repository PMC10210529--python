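"""Meta-analysis of a genome track over region sets.

Two modes mirror the standard computeMatrix layouts: ``scale_regions``
(each region rescaled to a common length, e.g. gene bodies to 15 kb in
300 bp bins) and ``reference_point`` (fixed flanks around an anchor such as
a peak center).  Gene groups are stratified by expression: the top-TPM
stratum versus genes with zero TPM.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GenomeInterval, GenomeTrack

__all__ = [
    "MetaMatrix",
    "group_genes_by_expression",
    "scale_regions_matrix",
    "reference_point_matrix",
    "summarize_matrix",
]


@dataclass
class MetaMatrix:
    """Regions x bins signal matrix (NaN = missing)."""

    region_ids: list
    bin_labels: list
    values: np.ndarray
    mode: str  # 'scale_regions' or 'reference_point'
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.bin_labels)


def group_genes_by_expression(
    tpm: Mapping[str, float] | pd.Series,
    genes: Sequence[GenomeInterval],
    top_fraction: float = 0.25,
    n_per_group: int = 5000,
) -> tuple[list[GenomeInterval], list[GenomeInterval]]:
    """Split genes into an expressed and an unexpressed group.

    Expressed: up to ``n_per_group`` genes from the top-``top_fraction`` TPM
    stratum, highest first; unexpressed: up to ``n_per_group`` genes with TPM
    exactly 0.  Ordering is deterministic (TPM descending, ties by gene id).
    """
    if isinstance(tpm, pd.Series):
        tpm = tpm.to_dict()
    if any(v < 0 for v in tpm.values()):
        raise ValueError("TPM values must be >= 0")
    by_id = {}
    for g in genes:
        if g.name is None:
            raise ValueError("genes must carry ids (BED name column)")
        by_id[g.name] = g
    scored = sorted(
        ((gid, tpm[gid]) for gid in by_id if gid in tpm),
        key=lambda t: (-t[1], t[0]),
    )
    k = int(round(top_fraction * len(scored)))
    expressed = [by_id[gid] for gid, v in scored[:k] if v > 0][:n_per_group]
    zeros = sorted(gid for gid, v in scored if v == 0.0)
    if not zeros:
        warnings.warn("no zero-TPM genes; unexpressed group is empty")
    unexpressed = [by_id[gid] for gid in zeros[:n_per_group]]
    return expressed, unexpressed


def _per_bp_column_means(
    chrom_values: np.ndarray,
    track_bin: int,
    bp_positions: np.ndarray,
    columns: np.ndarray,
    n_columns: int,
) -> np.ndarray:
    """Mean track value per column over base pairs (NaN bins are skipped)."""
    vals = np.full(bp_positions.size, np.nan)
    ok = (bp_positions >= 0) & (bp_positions < chrom_values.size * track_bin)
    vals[ok] = chrom_values[bp_positions[ok] // track_bin]
    good = ~np.isnan(vals)
    sums = np.bincount(columns[good], weights=vals[good], minlength=n_columns)
    cnts = np.bincount(columns[good], minlength=n_columns)
    with np.errstate(invalid="ignore"):
        out = sums / cnts
    out[cnts == 0] = np.nan
    return out


def scale_regions_matrix(
    track: GenomeTrack,
    regions: Sequence[GenomeInterval],
    target_length: int = 15_000,
    bin_size: int = 300,
) -> MetaMatrix:
    """Rescale each region to ``target_length`` and average into bins.

    Each output column covers a proportional slice of the source region
    (per-bp averaging); minus-strand regions are reversed so column 0 is the
    region's 5' end.
    """
    if target_length % bin_size != 0:
        raise ValueError("bin_size must divide target_length")
    ncol = target_length // bin_size
    rows, ids = [], []
    for idx, reg in enumerate(regions):
        if reg.length == 0:
            warnings.warn(f"skipping zero-length region {reg.name or idx}")
            continue
        if reg.chromosome not in track.values:
            warnings.warn(f"skipping region on absent chromosome {reg.chromosome}")
            continue
        bp = np.arange(reg.start, reg.end)
        cols = ((bp - reg.start) * ncol) // reg.length
        row = _per_bp_column_means(track.values[reg.chromosome], track.bin_size,
                                   bp, cols.astype(np.int64), ncol)
        if reg.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(reg.name if reg.name is not None else f"region_{idx}")
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    return MetaMatrix(
        region_ids=ids,
        bin_labels=[i * bin_size for i in range(ncol)],
        values=values,
        mode="scale_regions",
        metadata={"target_length": target_length, "bin_size": bin_size},
    )


def reference_point_matrix(
    track: GenomeTrack,
    points: Sequence[GenomeInterval],
    flank_bp: int = 1500,
    bin_size: int = 300,
) -> MetaMatrix:
    """Signal in ``[-flank, +flank)`` around each interval's midpoint.

    Cells reaching past a chromosome edge are missing; minus-strand points
    are flipped so negative offsets are 5' of the anchor.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    ncol = int(np.ceil(2 * flank_bp / bin_size))
    rows, ids = [], []
    for idx, pt in enumerate(points):
        if pt.chromosome not in track.values:
            warnings.warn(f"skipping point on absent chromosome {pt.chromosome}")
            continue
        anchor = pt.midpoint
        bp = np.arange(anchor - flank_bp, anchor + flank_bp)
        cols = (bp - (anchor - flank_bp)) // bin_size
        row = _per_bp_column_means(track.values[pt.chromosome], track.bin_size,
                                   bp, cols.astype(np.int64), ncol)
        if pt.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(pt.name if pt.name is not None else f"point_{idx}")
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    return MetaMatrix(
        region_ids=ids,
        bin_labels=[-flank_bp + i * bin_size for i in range(ncol)],
        values=values,
        mode="reference_point",
        metadata={"flank_bp": flank_bp, "bin_size": bin_size},
    )


def summarize_matrix(matrix: MetaMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-column mean, standard deviation (sample by default) and n.

    Missing cells are ignored per column; an all-missing column has missing
    mean and sd.
    """
    v = matrix.values
    good = ~np.isnan(v)
    n = good.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(good, v, np.nan), axis=0)
        sd = np.nanstd(v, axis=0, ddof=ddof)
    mean = np.where(n == 0, np.nan, mean)
    sd = np.where((n >= 1) & (n <= ddof), 0.0, sd)  # a single observation has no spread
    sd = np.where(n == 0, np.nan, sd)
    return pd.DataFrame({"bin": matrix.bin_labels, "mean": mean, "std": sd, "n": n})
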