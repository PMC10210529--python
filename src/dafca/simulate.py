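"""Synthetic optical-genome-mapping data with known ground truth.

The generator emulates the two-channel single-molecule assay: a genetic
barcode channel (CTTAAG labels used for alignment) and an accessibility
channel in which a Dam methyltransferase deposits a fluorophore at a GATC
site with probability ``openness x labeling efficiency``.  A deproteinized
"naked" control is the openness == 1 special case of the same generator.
Optics are modelled as a Gaussian point-spread function sampled at camera
pixel centers, on top of additive background noise; label positions carry
multiplicative sizing noise on inter-label distances (stretch variation).

Ground-truth accessibility is a two-state piecewise-constant function with
exponential segment lengths: open segments at a high labeling probability,
closed segments at a low one.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats import find_motif_sites
from .types import GenomeTrack, Molecule, MoleculeSet, MotifSiteTrack

GATC = "GATC"
BARCODE_MOTIF = "CTTAAG"

__all__ = [
    "GATC",
    "BARCODE_MOTIF",
    "AccessibilityGroundTruth",
    "SimulationParams",
    "DiploidSim",
    "simulate_genome",
    "simulate_accessibility",
    "simulate_molecules",
    "simulate_diploid",
]


class AccessibilityGroundTruth:
    """Piecewise-constant openness per chromosome.

    ``openness`` is the probability that a GATC site in the segment is
    enzymatically labeled.  Segments tile each chromosome without overlap.
    """

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        # segments: chrom -> (boundaries of length k+1 starting at 0, openness of length k)
        self.segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bounds, open_) in segments.items():
            bounds = np.asarray(bounds, dtype=np.int64)
            open_ = np.asarray(open_, dtype=np.float64)
            if bounds.size != open_.size + 1 or bounds[0] != 0:
                raise ValueError(f"{chrom}: malformed segment arrays")
            if np.any(np.diff(bounds) <= 0):
                raise ValueError(f"{chrom}: segment boundaries must increase")
            if np.any((open_ < 0) | (open_ > 1)):
                raise ValueError(f"{chrom}: openness must lie in [0, 1]")
            self.segments[chrom] = (bounds, open_)

    @classmethod
    def from_per_bp(cls, per_bp: Mapping[str, np.ndarray]) -> "AccessibilityGroundTruth":
        segs = {}
        for chrom, arr in per_bp.items():
            arr = np.asarray(arr, dtype=np.float64)
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [arr.size]))
            segs[chrom] = (bounds, arr[bounds[:-1]])
        return cls(segs)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(b[-1]) for c, (b, _) in self.segments.items()}

    def per_bp(self, chrom: str) -> np.ndarray:
        bounds, open_ = self.segments[chrom]
        return np.repeat(open_, np.diff(bounds))

    def openness_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        bounds, open_ = self.segments[chrom]
        idx = np.searchsorted(bounds, np.asarray(positions), side="right") - 1
        return open_[np.clip(idx, 0, open_.size - 1)]

    def open_base_fraction(self, open_threshold: float = 0.5) -> float:
        """Fraction of genome bp whose openness exceeds the threshold."""
        tot = opened = 0
        for bounds, open_ in self.segments.values():
            seglen = np.diff(bounds)
            tot += seglen.sum()
            opened += seglen[open_ > open_threshold].sum()
        return float(opened / tot)

    def mean_binned(self, bin_size: int) -> GenomeTrack:
        """Exact per-bin mean openness (the recovery target for normalization)."""
        values = {}
        for chrom in self.segments:
            arr = self.per_bp(chrom)
            nb = math.ceil(arr.size / bin_size)
            padded = np.full(nb * bin_size, np.nan)
            padded[: arr.size] = arr
            values[chrom] = np.nanmean(padded.reshape(nb, bin_size), axis=1)
        return GenomeTrack(bin_size=bin_size, values=values, label="ground_truth_openness",
                           chrom_lengths=self.chrom_lengths)


@dataclass
class SimulationParams:
    """Instrument and sample model parameters.

    Intensities are in arbitrary fluorescence units; the defaults put the
    naked-control calibration on the same scale as a typical Saphyr run
    (per-bin slope ~59 units/site, background ~216 units/bin).
    """

    median_molecule_len: float = 200_000.0  # log-normal median, bp
    molecule_len_sigma: float = 0.35  # log-scale sd
    min_molecule_len: float = 150_000.0  # reads below this are not reported
    pixel_size: float = 500.0  # bp per camera pixel
    psf_sigma: float = 350.0  # optical blur sd, bp (FWHM ~820 bp)
    genetic_label_efficiency: float = 0.85  # barcode (CTTAAG) labeling probability
    spurious_label_rate_per_100kb: float = 1.0
    sizing_noise_sd: float = 0.02  # multiplicative, on inter-label distances
    access_label_efficiency: float = 0.8  # accessibility-channel labeling probability at openness 1
    label_intensity_mean: float = 73.66  # per labeled GATC site, a.u.
    label_intensity_sd: float = 15.0
    background_mean: float = 216.18  # per pixel, a.u.
    background_sd: float = 25.0
    coverage: float = 50.0  # fold genome coverage of reported molecules
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genetic_label_efficiency", "access_label_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "median_molecule_len", "pixel_size", "coverage",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "molecule_len_sigma", "min_molecule_len", "psf_sigma",
            "spurious_label_rate_per_100kb", "sizing_noise_sd",
            "label_intensity_sd", "background_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_genome(
    n_chromosomes: int,
    lengths: Sequence[int],
    gc: float = 0.41,
    seed: int = 0,
    name_prefix: str = "chr",
) -> dict[str, str]:
    """I.i.d. random genome at the given GC content (human-like default 0.41)."""
    if n_chromosomes != len(lengths):
        raise ValueError("n_chromosomes must match len(lengths)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if any(length <= 0 for length in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"{name_prefix}{i + 1}": rng.choice(alphabet, size=int(L), p=probs).tobytes().decode()
        for i, L in enumerate(lengths)
    }


def simulate_accessibility(
    genome_lengths: Mapping[str, int],
    open_fraction: float = 0.5,
    mean_open_len: float = 20_000.0,
    mean_closed_len: float = 20_000.0,
    open_level: float = 0.9,
    closed_level: float = 0.1,
    seed: int = 0,
) -> AccessibilityGroundTruth:
    """Alternating open/closed segments with exponential lengths.

    Segment-length means are rescaled (keeping the open+closed cycle length)
    so the stationary open-base fraction equals ``open_fraction``.
    """
    if mean_open_len <= 0 or mean_closed_len <= 0:
        raise ValueError("mean segment lengths must be positive")
    if not 0.0 <= closed_level < open_level <= 1.0:
        raise ValueError("need 0 <= closed_level < open_level <= 1")
    if not 0.0 < open_fraction < 1.0:
        raise ValueError("open_fraction must be in (0, 1)")
    cycle = mean_open_len + mean_closed_len
    mo, mc = open_fraction * cycle, (1.0 - open_fraction) * cycle
    rng = np.random.default_rng(seed)
    segs = {}
    for chrom, length in genome_lengths.items():
        bounds = [0]
        opens = []
        state_open = bool(rng.random() < open_fraction)
        pos = 0
        while pos < length:
            seg = max(1, int(rng.exponential(mo if state_open else mc)))
            pos = min(length, pos + seg)
            bounds.append(pos)
            opens.append(open_level if state_open else closed_level)
            state_open = not state_open
        segs[chrom] = (np.asarray(bounds), np.asarray(opens))
    return AccessibilityGroundTruth(segs)


def _render_profile(
    rel_positions: np.ndarray,
    intensities: np.ndarray,
    n_pixels: int,
    pixel_size: float,
    psf_sigma: float,
) -> np.ndarray:
    """Sum of per-label Gaussian point spreads sampled at pixel centers.

    Each label of total intensity ``a`` contributes
    ``a * pixel_size * N(center; pos, sigma)`` so its mass over pixels is ~a.
    """
    profile = np.zeros(n_pixels)
    if rel_positions.size == 0:
        return profile
    if psf_sigma < 1e-9:  # delta limit: all mass in the containing pixel
        idx = np.clip((rel_positions // pixel_size).astype(int), 0, n_pixels - 1)
        np.add.at(profile, idx, intensities)
        return profile
    half = int(math.ceil(4.0 * psf_sigma / pixel_size))
    base = np.floor(rel_positions / pixel_size).astype(int)
    norm = pixel_size / (psf_sigma * math.sqrt(2.0 * math.pi))
    for k in range(-half, half + 1):
        idx = base + k
        ok = (idx >= 0) & (idx < n_pixels)
        if not np.any(ok):
            continue
        centers = (idx[ok] + 0.5) * pixel_size
        z = (centers - rel_positions[ok]) / psf_sigma
        # add.at: several sites may hit the same pixel at this offset
        np.add.at(profile, idx[ok], intensities[ok] * norm * np.exp(-0.5 * z * z))
    return profile


def simulate_molecules(
    sequences: Mapping[str, str],
    ground_truth: AccessibilityGroundTruth | None,
    params: SimulationParams,
    sample_type: str = "chromatin",
    gatc_sites: MotifSiteTrack | None = None,
    barcode_sites: MotifSiteTrack | None = None,
) -> MoleculeSet:
    """Draw molecules uniformly from the genome and render both channels.

    Naked mode ignores the ground truth (every GATC site is labelable at the
    accessibility-channel efficiency); chromatin mode labels each site with
    probability ``openness x access_label_efficiency``.  Molecules shorter
    than ``min_molecule_len`` are discarded; generation stops once reported
    molecules total ``coverage x genome size`` bp.
    """
    if params.coverage <= 0:
        raise ValueError("coverage must be positive")
    if sample_type not in ("chromatin", "naked"):
        raise ValueError("sample_type must be 'chromatin' or 'naked'")
    if sample_type == "chromatin" and ground_truth is None:
        raise ValueError("chromatin mode requires a ground truth")
    if gatc_sites is None:
        gatc_sites = find_motif_sites(sequences, GATC)
    if barcode_sites is None:
        barcode_sites = find_motif_sites(sequences, BARCODE_MOTIF)

    rng = np.random.default_rng(params.seed)
    chroms = list(sequences)
    chrom_lens = np.array([len(sequences[c]) for c in chroms], dtype=np.float64)
    genome_size = chrom_lens.sum()
    target_bp = params.coverage * genome_size
    mu_log = math.log(params.median_molecule_len)

    molecules: list[Molecule] = []
    total_bp = 0.0
    mol_id = 0
    while total_bp < target_bp:
        length = float(np.exp(rng.normal(mu_log, params.molecule_len_sigma)))
        ci = int(rng.choice(len(chroms), p=chrom_lens / genome_size))
        chrom = chroms[ci]
        clen = chrom_lens[ci]
        length = min(length, clen)
        if length < params.min_molecule_len:
            continue
        start = float(rng.uniform(0.0, clen - length))
        orientation = 1 if rng.random() < 0.5 else -1

        # --- genetic barcode channel ---
        bsites = barcode_sites.sites[chrom]
        lo, hi = np.searchsorted(bsites, [start, start + length])
        hit = bsites[lo:hi][rng.random(hi - lo) < params.genetic_label_efficiency]
        rel = hit - start
        n_spur = rng.poisson(params.spurious_label_rate_per_100kb * length / 1e5)
        rel = np.sort(np.concatenate([rel, rng.uniform(0.0, length, n_spur)]))
        if orientation == -1:
            rel = np.sort(length - rel)
        if rel.size > 1 and params.sizing_noise_sd > 0:
            gaps = np.diff(rel) * (1.0 + rng.normal(0.0, params.sizing_noise_sd, rel.size - 1))
            rel = np.concatenate(([rel[0]], rel[0] + np.cumsum(np.maximum(gaps, 1.0))))
        rel = np.sort(np.clip(rel, 0.0, np.nextafter(length, 0.0)))

        # --- accessibility channel ---
        asites = gatc_sites.sites[chrom]
        lo, hi = np.searchsorted(asites, [start, start + length])
        span_sites = asites[lo:hi]
        if sample_type == "naked":
            p_label = np.full(span_sites.size, params.access_label_efficiency)
        else:
            p_label = (
                ground_truth.openness_at(chrom, span_sites) * params.access_label_efficiency
            )
        labeled = span_sites[rng.random(span_sites.size) < p_label]
        arel = labeled - start
        if orientation == -1:
            arel = length - arel
        amps = np.maximum(
            rng.normal(params.label_intensity_mean, params.label_intensity_sd, arel.size), 0.0
        )
        n_pixels = math.ceil(length / params.pixel_size)
        profile = _render_profile(arel, amps, n_pixels, params.pixel_size, params.psf_sigma)
        if params.background_mean > 0 or params.background_sd > 0:
            profile += rng.normal(params.background_mean, params.background_sd, n_pixels)
        profile = np.maximum(profile, 0.0)

        molecules.append(
            Molecule(
                id=str(mol_id),
                length=length,
                genetic_labels=rel,
                profile=profile,
                pixel_size=params.pixel_size,
                origin=(chrom, start, orientation),
            )
        )
        mol_id += 1
        total_bp += length

    return MoleculeSet(
        molecules=molecules,
        sample_type=sample_type,
        params={"sample_type": sample_type, **asdict(params)},
    )


# ---------------------------------------------------------------------------
# diploid genomes with heterozygous SVs
# ---------------------------------------------------------------------------

@dataclass
class DiploidSim:
    """Two allele genomes, their accessibility truths, and the het SV table."""

    allele1: dict[str, str]
    allele2: dict[str, str]
    ground_truth1: "AccessibilityGroundTruth"
    ground_truth2: "AccessibilityGroundTruth"
    svs: list  # SVRecord, allele-1 coordinates with allele-2 liftover info
    differential_regions: list = field(default_factory=list)


def simulate_diploid(
    sequences: Mapping[str, str],
    sv_list: Sequence[tuple],
    differential_regions: Sequence[tuple] = (),
    ground_truth: AccessibilityGroundTruth | None = None,
    fold: float = 2.0,
    base_openness: float = 0.4,
    accessibility_kwargs: Mapping | None = None,
    gc: float = 0.41,
    seed: int = 0,
) -> DiploidSim:
    """Build a heterozygous diploid from a haploid genome.

    ``sv_list``: (GenomeInterval, type) with type in {deletion, insertion,
    inversion}; for insertions the interval length is the inserted length and
    the insertion point is the interval start.  SVs must not overlap.
    ``differential_regions``: GenomeInterval list (allele-1 coordinates) where
    allele-1 openness is set to ``base_openness`` and allele-2 to
    ``min(1, base_openness x fold)``; elsewhere the two truths are identical.
    """
    from .allelic import SVRecord

    if ground_truth is None:
        lengths = {c: len(s) for c, s in sequences.items()}
        ground_truth = simulate_accessibility(
            lengths, seed=seed, **(accessibility_kwargs or {})
        )
    svs_sorted = sorted(sv_list, key=lambda x: (x[0].chromosome, x[0].start))
    by_chrom: dict[str, list[tuple]] = {}
    for iv, svtype in svs_sorted:
        if svtype not in ("deletion", "insertion", "inversion"):
            raise ValueError(f"unsupported SV type {svtype!r}")
        prev = by_chrom.setdefault(iv.chromosome, [])
        if prev and iv.start < prev[-1][0].end:
            raise ValueError(f"overlapping SVs on {iv.chromosome}")
        prev.append((iv, svtype))

    # per-bp openness in allele-1 coordinates, with differential regions planted
    open1 = {c: ground_truth.per_bp(c).copy() for c in sequences}
    for item in differential_regions:
        iv = item[0] if isinstance(item, tuple) else item
        open1[iv.chromosome][iv.start : iv.end] = base_openness
    open2 = {c: a.copy() for c, a in open1.items()}
    for item in differential_regions:
        iv = item[0] if isinstance(item, tuple) else item
        open2[iv.chromosome][iv.start : iv.end] = min(1.0, base_openness * fold)

    rng = np.random.default_rng(seed + 1)
    allele2_seqs: dict[str, str] = {}
    records: list[SVRecord] = []
    comp = str.maketrans("ACGT", "TGCA")
    sv_id = 0
    for chrom, seq in sequences.items():
        events = by_chrom.get(chrom, [])
        out_seq: list[str] = []
        out_open: list[np.ndarray] = []
        cursor = 0
        for iv, svtype in events:
            out_seq.append(seq[cursor : iv.start])
            out_open.append(open2[chrom][cursor : iv.start])
            a2_start = sum(len(s) for s in out_seq)
            if svtype == "deletion":
                cursor = iv.end
                a2_end = a2_start + 1
            elif svtype == "insertion":
                ins = simulate_genome(1, [iv.length], gc=gc, seed=int(rng.integers(2**31)))
                ins_seq = ins["chr1"]
                out_seq.append(ins_seq)
                out_open.append(np.full(iv.length, open2[chrom][iv.start]))
                cursor = iv.start
                a2_end = a2_start + iv.length
            else:  # inversion
                out_seq.append(seq[iv.start : iv.end].translate(comp)[::-1])
                out_open.append(open2[chrom][iv.start : iv.end][::-1])
                cursor = iv.end
                a2_end = a2_start + iv.length
            records.append(
                SVRecord(
                    id=f"sv{sv_id}",
                    chromosome=chrom,
                    start=iv.start,
                    end=iv.end if svtype != "insertion" else iv.start + 1,
                    type=svtype,
                    zygosity="het",
                    length=iv.length,
                    allele2_start=a2_start,
                    allele2_end=a2_end,
                )
            )
            sv_id += 1
        out_seq.append(seq[cursor:])
        out_open.append(open2[chrom][cursor:])
        allele2_seqs[chrom] = "".join(out_seq)
        open2[chrom] = np.concatenate(out_open)

    return DiploidSim(
        allele1=dict(sequences),
        allele2=allele2_seqs,
        ground_truth1=AccessibilityGroundTruth.from_per_bp(open1),
        ground_truth2=AccessibilityGroundTruth.from_per_bp(open2),
        svs=records,
        differential_regions=[item[0] if isinstance(item, tuple) else item
                              for item in differential_regions],
    )
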