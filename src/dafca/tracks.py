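"""Project per-molecule intensity profiles onto the genome; bin and smooth.

Projection maps each camera pixel to reference coordinates by linear
interpolation between paired genetic labels (the flanking pair's scale is
extrapolated past the outermost pairs), then averages pixel intensities per
genomic bin so molecule count does not inflate the signal; a separate
coverage track counts contributing molecules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import Alignment
from .types import GenomeTrack, Molecule, n_bins

__all__ = ["SmoothingParams", "project_profiles", "bin_track", "smooth_track"]


@dataclass
class SmoothingParams:
    """Gaussian smoothing on a fixed genomic grid.

    The defaults (4000 bp window, 2000 bp sd, 500 bp step) are the values
    used to match a theoretical site-density track to the effective optical
    resolution of a Saphyr run; the kernel is evaluated on the ``step`` grid
    and truncated to ``window`` total width (+-4 bins at the defaults).
    """

    window: float = 4000.0
    std: float = 2000.0
    step: float = 500.0

    def __post_init__(self) -> None:
        if not self.window >= self.step > 0:
            raise ValueError("need window >= step > 0")
        if self.std <= 0:
            raise ValueError("std must be positive")

    @property
    def radius_bins(self) -> int:
        return int(round(self.window / (2.0 * self.step)))


def _map_pixels_to_reference(mol: Molecule, aln: Alignment) -> np.ndarray:
    """Reference bp of each pixel center, via the alignment's label pairs."""
    xp = aln.pair_mol_pos
    fp = aln.pair_ref_pos
    if xp is None or xp.size < 2:
        raise ValueError(f"alignment of molecule {aln.molecule_id} has < 2 label pairs")
    x = (np.arange(mol.profile.size) + 0.5) * mol.pixel_size
    ref = np.interp(x, xp, fp)
    # np.interp clamps outside [xp[0], xp[-1]]; extrapolate with the flanking
    # pair's scale (falling back to the overall scale if the edge pair is
    # degenerate, e.g. two labels clipped to the same coordinate)
    overall = (fp[-1] - fp[0]) / (xp[-1] - xp[0])
    left = x < xp[0]
    if np.any(left):
        s = (fp[1] - fp[0]) / (xp[1] - xp[0]) if xp[1] > xp[0] else overall
        ref[left] = fp[0] + (x[left] - xp[0]) * s
    right = x > xp[-1]
    if np.any(right):
        s = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2]) if xp[-1] > xp[-2] else overall
        ref[right] = fp[-1] + (x[right] - xp[-1]) * s
    return ref


def project_profiles(
    molecules: Iterable[Molecule],
    alignments: Sequence[Alignment],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 500,
    min_coverage: int = 1,
) -> tuple[GenomeTrack, GenomeTrack]:
    """Accumulate aligned molecule profiles into a genome-wide raw track.

    Returns ``(raw, coverage)``: per-bin mean of all pixel intensities mapped
    into the bin across molecules (NaN where no pixel lands or coverage is
    below ``min_coverage``), and the number of contributing molecules per bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    by_id = {m.id: m for m in molecules}
    sums = {c: np.zeros(n_bins(length, bin_size)) for c, length in chrom_lengths.items()}
    counts = {c: np.zeros(n_bins(length, bin_size)) for c, length in chrom_lengths.items()}
    cover = {c: np.zeros(n_bins(length, bin_size)) for c, length in chrom_lengths.items()}
    for aln in alignments:
        if aln.chromosome not in sums:
            raise ValueError(f"alignment to unknown chromosome {aln.chromosome!r}")
        mol = by_id.get(aln.molecule_id)
        if mol is None:
            raise ValueError(f"alignment references unknown molecule {aln.molecule_id!r}")
        ref = _map_pixels_to_reference(mol, aln)
        ok = np.isfinite(ref)
        bins = np.full(ref.size, -1, dtype=np.int64)
        bins[ok] = np.floor(ref[ok] / bin_size).astype(np.int64)
        ok &= (bins >= 0) & (bins < sums[aln.chromosome].size)
        bins = bins[ok]
        np.add.at(sums[aln.chromosome], bins, mol.profile[ok])
        np.add.at(counts[aln.chromosome], bins, 1.0)
        cover[aln.chromosome][np.unique(bins)] += 1.0
    values = {}
    for chrom in sums:
        with np.errstate(invalid="ignore"):
            v = sums[chrom] / counts[chrom]
        v[cover[chrom] < min_coverage] = np.nan
        values[chrom] = v
    raw = GenomeTrack(bin_size=bin_size, values=values, label="raw",
                      chrom_lengths=dict(chrom_lengths))
    coverage = GenomeTrack(bin_size=bin_size, values=cover, label="coverage",
                           chrom_lengths=dict(chrom_lengths))
    return raw, coverage


def bin_track(track: GenomeTrack, bin_size: int = 500, stat: str = "mean") -> GenomeTrack:
    """Re-bin a track to a coarser non-overlapping grid starting at 0.

    ``bin_size`` must be a positive multiple of the input resolution; the
    statistic is taken over non-missing fine bins, the last partial bin is
    included, and an all-missing coarse bin stays missing.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if bin_size % track.bin_size != 0:
        raise ValueError(f"bin_size {bin_size} is not a multiple of input resolution {track.bin_size}")
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    factor = bin_size // track.bin_size
    values = {}
    for chrom, v in track.values.items():
        nb = math.ceil(v.size / factor)
        padded = np.full(nb * factor, np.nan)
        padded[: v.size] = v
        grid = padded.reshape(nb, factor)
        good = ~np.isnan(grid)
        cnt = good.sum(axis=1)
        tot = np.where(good, grid, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = tot / cnt if stat == "mean" else tot.astype(float)
        out = np.where(cnt == 0, np.nan, out)
        values[chrom] = out
    return GenomeTrack(bin_size=bin_size, values=values, label=track.label,
                       chrom_lengths=track.chrom_lengths)


def smooth_track(track: GenomeTrack, params: SmoothingParams | None = None) -> GenomeTrack:
    """Gaussian-smooth a binned track on its own grid.

    The kernel has sd ``std/step`` bins, is truncated to ``window/step`` bins
    total, and is renormalized over non-missing neighbors, so a constant
    track is reproduced exactly and isolated missing bins are interpolated
    from their neighborhood; fully missing neighborhoods stay missing.
    The track's bin size must equal ``params.step`` (resample first if not).
    """
    params = params or SmoothingParams()
    if track.bin_size != params.step:
        raise ValueError(
            f"track bin_size {track.bin_size} != smoothing step {params.step}; resample first"
        )
    r = params.radius_bins
    offs = np.arange(-r, r + 1, dtype=np.float64)
    sd_bins = params.std / params.step
    kernel = np.exp(-0.5 * (offs / sd_bins) ** 2)
    kernel /= kernel.sum()
    values = {}
    for chrom, v in track.values.items():
        good = ~np.isnan(v)
        filled = np.where(good, v, 0.0)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(good.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            out = num / den
        out[den <= 0] = np.nan
        values[chrom] = out
    return GenomeTrack(bin_size=track.bin_size, values=values,
                       label=(track.label + "_smoothed").lstrip("_"),
                       chrom_lengths=track.chrom_lengths)
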