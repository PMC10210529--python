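"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the
Bionano text formats (CMAP/XMAP, 1-based) are converted at the IO boundary.
Missing signal is represented as NaN and is distinct from a measured 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MotifSiteTrack",
    "GenomeInterval",
    "GenomeTrack",
    "Molecule",
    "MoleculeSet",
    "n_bins",
]


def n_bins(length: int, bin_size: int) -> int:
    """Number of fixed-size bins tiling a chromosome (last bin may be partial)."""
    return int(math.ceil(length / bin_size))


@dataclass
class MotifSiteTrack:
    """Per-chromosome sorted motif start coordinates for one recognition sequence.

    The theoretical site maps of the labeling enzymes: GATC for the
    accessibility channel (Dam methyltransferase) and CTTAAG for the genetic
    barcode channel (DLE-1).  Both motifs are reverse-complement palindromes,
    so forward-strand occurrences describe both strands.
    """

    motif: str
    sites: dict[str, np.ndarray]
    genome_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be non-empty and ACGT-only, got {self.motif!r}")
        self.sites = {c: np.asarray(p, dtype=np.int64) for c, p in self.sites.items()}
        for chrom, pos in self.sites.items():
            if chrom not in self.genome_lengths:
                raise ValueError(f"no genome length for chromosome {chrom!r}")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"motif positions not strictly increasing on {chrom}")
            if pos.size and (pos[0] < 0 or pos[-1] + len(self.motif) > self.genome_lengths[chrom]):
                raise ValueError(f"motif position out of range on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sites)

    def total_sites(self) -> int:
        return int(sum(p.size for p in self.sites.values()))


@dataclass
class GenomeInterval:
    """A genomic interval (BED semantics: 0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeTrack:
    """Per-chromosome signal at fixed bin resolution; NaN marks missing bins."""

    bin_size: int
    values: dict[str, np.ndarray]
    label: str = ""
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in self.values.items()}
        if self.chrom_lengths is not None:
            for chrom, v in self.values.items():
                expect = n_bins(self.chrom_lengths[chrom], self.bin_size)
                if v.size != expect:
                    raise ValueError(
                        f"{chrom}: {v.size} bins but length {self.chrom_lengths[chrom]} "
                        f"needs {expect} at bin_size {self.bin_size}"
                    )

    @classmethod
    def empty(
        cls, chrom_lengths: Mapping[str, int], bin_size: int, label: str = ""
    ) -> "GenomeTrack":
        """All-missing track tiling the given chromosome lengths."""
        values = {
            c: np.full(n_bins(length, bin_size), np.nan) for c, length in chrom_lengths.items()
        }
        return cls(bin_size=bin_size, values=values, label=label, chrom_lengths=dict(chrom_lengths))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def copy(self, label: str | None = None) -> "GenomeTrack":
        return GenomeTrack(
            bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            label=self.label if label is None else label,
            chrom_lengths=None if self.chrom_lengths is None else dict(self.chrom_lengths),
        )


@dataclass
class Molecule:
    """One nanochannel read.

    ``genetic_labels`` are barcode (CTTAAG) label positions in bp from the
    molecule start; ``profile`` is the continuous accessibility-channel
    intensity sampled once per camera pixel (``pixel_size`` bp per pixel).
    Simulated molecules retain their hidden ground-truth ``origin``
    (chromosome, start, orientation) for validation; real molecules carry None.
    """

    id: str
    length: float
    genetic_labels: np.ndarray
    profile: np.ndarray
    pixel_size: float
    origin: tuple[str, float, int] | None = None

    def __post_init__(self) -> None:
        self.genetic_labels = np.asarray(self.genetic_labels, dtype=np.float64)
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.length <= 0 or self.pixel_size <= 0:
            raise ValueError("length and pixel_size must be positive")
        if self.genetic_labels.size and (
            np.any(np.diff(self.genetic_labels) < 0)
            or self.genetic_labels[0] < 0
            or self.genetic_labels[-1] >= self.length
        ):
            raise ValueError(f"molecule {self.id}: labels must be sorted within [0, length)")
        expect = n_bins(int(math.ceil(self.length)), int(self.pixel_size))
        if self.profile.size != expect:
            raise ValueError(
                f"molecule {self.id}: profile has {self.profile.size} pixels, "
                f"expected ceil(length/pixel_size) = {expect}"
            )

    @property
    def n_labels(self) -> int:
        return int(self.genetic_labels.size)


@dataclass
class MoleculeSet:
    """A set of molecules from one sample (chromatin or deproteinized 'naked')."""

    molecules: list[Molecule]
    sample_type: str = "chromatin"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_type not in ("chromatin", "naked"):
            raise ValueError("sample_type must be 'chromatin' or 'naked'")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)
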