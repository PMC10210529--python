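"""End-to-end simulated studies: the full pipeline on synthetic data.

Two drivers tie the stages together the way an instrument run would:

* :func:`run_haploid_study` — one genome, a chromatin and a naked sample;
  simulate, align, filter, project, calibrate and normalize, then score the
  result against the simulator's hidden ground truth.
* :func:`run_diploid_study` — a heterozygous diploid with planted
  allele-differential regions next to SVs; molecules are phased blind by
  best-of-two-alleles alignment and the allele-specific differential
  analysis is scored against the planted truth.

Problem sizes default to a 2 Mb genome so a study runs in about a minute on
one core while leaving every stage statistically meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import allelic as _allelic
from . import normalize as _normalize
from . import tracks as _tracks
from .align import Alignment, LabelAligner, filter_alignments
from .formats import find_motif_sites
from .normalize import NormalizationResult
from .simulate import (
    BARCODE_MOTIF,
    GATC,
    AccessibilityGroundTruth,
    DiploidSim,
    SimulationParams,
    simulate_accessibility,
    simulate_diploid,
    simulate_genome,
    simulate_molecules,
)
from .types import GenomeInterval, GenomeTrack, MoleculeSet, MotifSiteTrack

__all__ = [
    "HaploidStudy",
    "DiploidStudy",
    "run_haploid_study",
    "run_diploid_study",
    "default_sv_layout",
    "alignment_recovery_rate",
    "openness_correlation",
    "naked_self_normalization_mean",
]


@dataclass
class HaploidStudy:
    genome: dict
    lengths: dict
    truth: AccessibilityGroundTruth
    gatc: MotifSiteTrack
    barcode: MotifSiteTrack
    aligner: LabelAligner
    chromatin: MoleculeSet
    naked: MoleculeSet
    chromatin_alignments: list  # unfiltered
    naked_alignments: list  # unfiltered
    chromatin_raw: GenomeTrack
    naked_raw: GenomeTrack
    coverage: GenomeTrack
    result: NormalizationResult


def run_haploid_study(
    genome_length: int = 2_000_000,
    chromatin_coverage: float = 100.0,
    naked_coverage: float = 50.0,
    seed: int = 0,
    bin_size: int = 500,
    params: SimulationParams | None = None,
    accessibility_kwargs: dict | None = None,
) -> HaploidStudy:
    """Simulate, align, project and normalize one chromatin + naked pair."""
    genome = simulate_genome(1, [genome_length], seed=seed)
    lengths = {c: len(s) for c, s in genome.items()}
    truth = simulate_accessibility(lengths, seed=seed, **(accessibility_kwargs or {}))
    gatc = find_motif_sites(genome, GATC)
    barcode = find_motif_sites(genome, BARCODE_MOTIF)
    aligner = LabelAligner(barcode, seed=seed)

    base = params or SimulationParams()
    chrom_params = _with(base, coverage=chromatin_coverage, seed=seed * 10 + 1)
    naked_params = _with(base, coverage=naked_coverage, seed=seed * 10 + 2)
    chromatin = simulate_molecules(genome, truth, chrom_params, "chromatin", gatc, barcode)
    naked = simulate_molecules(genome, None, naked_params, "naked", gatc, barcode)

    chrom_alns = aligner.align_set(chromatin)
    naked_alns = aligner.align_set(naked)
    chromatin_raw, coverage = _tracks.project_profiles(
        chromatin, filter_alignments(chrom_alns), lengths, bin_size
    )
    naked_raw, _ = _tracks.project_profiles(
        naked, filter_alignments(naked_alns), lengths, bin_size
    )
    result = _normalize.build_normalized_track(chromatin_raw, naked_raw, gatc)
    return HaploidStudy(
        genome, lengths, truth, gatc, barcode, aligner, chromatin, naked,
        chrom_alns, naked_alns, chromatin_raw, naked_raw, coverage, result,
    )


def _with(params: SimulationParams, **overrides) -> SimulationParams:
    from dataclasses import asdict

    return SimulationParams(**{**asdict(params), **overrides})


def alignment_recovery_rate(
    molecules: MoleculeSet, alignments: list[Alignment], tolerance_bp: float = 2000.0
) -> float:
    """Fraction of aligned molecules placed within ``tolerance_bp`` of their
    true origin (simulated molecules carry it as hidden ground truth)."""
    by_id = {m.id: m for m in molecules}
    errs = []
    for aln in alignments:
        origin = by_id[aln.molecule_id].origin
        errs.append(
            origin is not None
            and aln.chromosome == origin[0]
            and abs(aln.implied_genome_start - origin[1]) <= tolerance_bp
        )
    return float(np.mean(errs)) if errs else 0.0


def openness_correlation(study: HaploidStudy) -> tuple[float, int]:
    """Pearson r between the normalized track and per-bin true openness."""
    gt = study.truth.mean_binned(study.result.normalized.bin_size)
    xs, ys = [], []
    for chrom, x in study.result.normalized.values.items():
        y = gt.values[chrom]
        m = min(x.size, y.size)
        ok = ~np.isnan(x[:m]) & ~np.isnan(y[:m])
        xs.append(x[:m][ok])
        ys.append(y[:m][ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(stats.pearsonr(x, y).statistic), int(x.size)


def naked_self_normalization_mean(study: HaploidStudy) -> tuple[float, int]:
    """Mean of the naked track normalized by its own model (target: 1.0)."""
    self_norm = _normalize.normalize_track(
        study.naked_raw, study.result.model, study.result.predicted_smoothed
    )
    v = np.concatenate([x[~np.isnan(x)] for x in self_norm.values.values()])
    return float(v.mean()), int(v.size)


# ---------------------------------------------------------------------------
# diploid study
# ---------------------------------------------------------------------------

def default_sv_layout(genome_length: int = 2_000_000) -> list[tuple[GenomeInterval, str]]:
    """Ten heterozygous SVs (deletions, insertions, inversions) spread along
    the genome, sized like the events a mapped assembly resolves (4-5 kb
    indels, 40-50 kb inversions)."""
    specs = [
        (0.075, 4_000, "deletion"),
        (0.165, 5_000, "insertion"),
        (0.250, 40_000, "inversion"),
        (0.350, 5_000, "deletion"),
        (0.440, 6_000, "insertion"),
        (0.525, 50_000, "inversion"),
        (0.625, 4_000, "deletion"),
        (0.715, 5_000, "insertion"),
        (0.800, 50_000, "inversion"),
        (0.900, 4_000, "deletion"),
    ]
    out = []
    for frac, size, svtype in specs:
        start = int(frac * genome_length)
        out.append((GenomeInterval("chr1", start, start + size), svtype))
    return out


def default_differential_regions(
    svs: list[tuple[GenomeInterval, str]],
    n_regions: int = 6,
    offset: int = 5_000,
    length: int = 20_000,
) -> list[GenomeInterval]:
    """Differential regions flanking the first ``n_regions`` SVs.

    Each region starts ``offset`` bp past its SV end — allele-specific
    accessibility differences sit right at the variant, where phasing
    coverage from SV-spanning molecules is densest.
    """
    return [
        GenomeInterval(iv.chromosome, iv.end + offset, iv.end + offset + length)
        for iv, _ in svs[:n_regions]
    ]


@dataclass
class DiploidStudy:
    sim: DiploidSim
    bins: list  # AllelicBin, after dropping missing
    flagged: list
    fraction_differential: float
    recall: float
    false_positive_rate: float
    n_planted_bins: int
    n_ambiguous: int
    n_dropped_bins: int
    model: object = None
    overlap: dict = field(default_factory=dict)


def run_diploid_study(
    genome_length: int = 2_000_000,
    coverage_per_allele: float = 50.0,
    seed: int = 0,
    fold: float = 2.0,
    base_openness: float = 0.4,
    window: int = 100_000,
    fold_threshold: float = 1.5,
    score_margin: float = 20.0,
    bin_size: int = 500,
    params: SimulationParams | None = None,
) -> DiploidStudy:
    """Blind allele-specific differential analysis on a simulated diploid.

    Molecules from both alleles are pooled and phased by best-of-two-alleles
    alignment with a score margin; each allele's track is normalized
    with the model fitted on a naked control, the allele-2 track is lifted
    through the SV breakpoints, and 1 kb bins inside 100 kb SV windows are
    classified at the given fold threshold.  Recall and false-positive rate
    are scored against the planted differential regions.
    """
    genome = simulate_genome(1, [genome_length], seed=seed)
    svs_in = default_sv_layout(genome_length)
    diff_regions = default_differential_regions(svs_in)
    dip = simulate_diploid(genome, svs_in, diff_regions, fold=fold,
                           base_openness=base_openness, seed=seed)
    len1 = {c: len(s) for c, s in dip.allele1.items()}
    len2 = {c: len(s) for c, s in dip.allele2.items()}
    gatc1 = find_motif_sites(dip.allele1, GATC)
    gatc2 = find_motif_sites(dip.allele2, GATC)
    bc1 = find_motif_sites(dip.allele1, BARCODE_MOTIF)
    bc2 = find_motif_sites(dip.allele2, BARCODE_MOTIF)

    base = params or SimulationParams()
    m1 = simulate_molecules(dip.allele1, dip.ground_truth1,
                            _with(base, coverage=coverage_per_allele, seed=seed * 10 + 3),
                            "chromatin", gatc1, bc1)
    m2 = simulate_molecules(dip.allele2, dip.ground_truth2,
                            _with(base, coverage=coverage_per_allele, seed=seed * 10 + 4),
                            "chromatin", gatc2, bc2)
    pool = list(m1) + list(m2)
    for i, mol in enumerate(pool):  # unique ids across the pooled sample
        mol.id = f"m{i}"

    al1 = LabelAligner(bc1, seed=seed)
    al2 = LabelAligner(bc2, seed=seed)
    a1, a2, n_ambiguous = _allelic.assign_molecules_to_alleles(
        pool, al1, al2, score_margin=score_margin
    )
    r1, _ = _tracks.project_profiles(pool, filter_alignments(a1), len1, bin_size)
    r2, _ = _tracks.project_profiles(pool, filter_alignments(a2), len2, bin_size)

    naked = simulate_molecules(dip.allele1, None,
                               _with(base, coverage=coverage_per_allele, seed=seed * 10 + 5),
                               "naked", gatc1, bc1)
    naked_raw, _ = _tracks.project_profiles(
        naked, filter_alignments(al1.align_set(naked)), len1, bin_size
    )
    res1 = _normalize.build_normalized_track(r1, naked_raw, gatc1)
    pred2 = _normalize.predicted_site_density(gatc2, bin_size)
    norm2 = _normalize.normalize_track(
        r2, res1.model, _tracks.smooth_track(pred2, res1.smoothing)
    )

    windows = _allelic.extract_sv_windows(dip.svs, window, len1)
    bins, dropped = _allelic.allele_bin_sums(res1.normalized, norm2, windows, svs=dip.svs)
    flagged, fraction = _allelic.classify_differential(bins, fold_threshold=fold_threshold)

    planted = {
        (reg.chromosome, b * 1000)
        for reg in diff_regions
        for b in range(reg.start // 1000, reg.end // 1000)
    }
    inside = [b.differential for b in bins if (b.chromosome, b.start) in planted]
    outside = [b.differential for b in bins if (b.chromosome, b.start) not in planted]
    recall = float(np.mean(inside)) if inside else float("nan")
    fpr = float(np.mean(outside)) if outside else float("nan")

    overlap = _allelic.annotate_overlap(
        flagged, bins, genes=(), promoters=diff_regions, enhancers=(),
    )
    return DiploidStudy(
        sim=dip, bins=bins, flagged=flagged, fraction_differential=fraction,
        recall=recall, false_positive_rate=fpr, n_planted_bins=len(inside),
        n_ambiguous=n_ambiguous, n_dropped_bins=dropped, model=res1.model,
        overlap=overlap,
    )
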