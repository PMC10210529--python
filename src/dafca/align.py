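"""Align molecules to a reference site map by their genetic label pattern.

A dynamic-programming aligner over label pairs stands in for the commercial
OGM pipeline: the match cost is the squared discrepancy between consecutive
inter-label gaps (normalized by an expected sizing error), with affine
penalties for missed reference sites and spurious molecule labels.  Both
orientations are tried; ties between distinct loci are reported as ambiguous
(no alignment).

Confidence is a -log10 p-value proxy: best scores of gap-shuffled null
molecules are collected once per reference, a Gumbel tail is fitted per label
count, and a molecule's confidence is its score's upper-tail -log10 p under
that null.  The scale behaves like the instrument's confidence (long, clean
molecules score in the tens; shuffled molecules near zero), so the standard
filter of confidence >= 17 with >= 60% aligned length and >= 150 kb molecule
length keeps the same kind of molecule it does in practice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .types import Molecule, MotifSiteTrack

__all__ = [
    "ScoringParams",
    "Alignment",
    "LabelAligner",
    "align_molecule",
    "filter_alignments",
]

_LN10 = math.log(10.0)


@dataclass
class ScoringParams:
    match_bonus: float = 4.0  # reward per paired label
    missed_site_penalty: float = 1.0  # per skipped reference site (unlabeled)
    spurious_label_penalty: float = 3.0  # per skipped molecule label
    sizing_sd: float = 0.03  # expected fractional sizing error of a gap
    position_sd: float = 150.0  # bp, label localization floor
    max_skip: int = 4  # max consecutive skips considered on either side
    min_labels: int = 5  # molecules below this are not aligned
    tie_margin_bp: float = 2000.0  # distinct loci closer than this are one locus


@dataclass
class Alignment:
    """Best placement of one molecule on the reference site map."""

    molecule_id: str
    chromosome: str
    ref_start: float
    ref_end: float
    orientation: str  # '+' or '-'
    pairs: list  # (molecule label index, reference site index), original indices
    score: float
    confidence: float
    molecule_length: float
    molecule_start: float  # molecule bp of first paired label
    molecule_end: float  # molecule bp of last paired label
    pair_mol_pos: np.ndarray | None = None  # ascending molecule bp of paired labels
    pair_ref_pos: np.ndarray | None = None  # matching reference bp (descending if '-')
    implied_genome_start: float = float("nan")  # reference bp of molecule coordinate 0/L

    @property
    def aligned_fraction(self) -> float:
        return (self.molecule_end - self.molecule_start) / self.molecule_length

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _dp_best(
    mol: np.ndarray, ref: np.ndarray, p: ScoringParams
) -> tuple[float, list[tuple[int, int]]]:
    """Best-scoring chain of (molecule label, reference site) pairs.

    Returns (score, pairs) with pairs as index tuples into ``mol``/``ref``;
    chains start and end anywhere (unpaired leading/trailing molecule labels
    pay the spurious-label penalty).
    """
    k, n = mol.size, ref.size
    d = p.max_skip
    # precompute reference gaps ref[j] - ref[j-dj]
    gaps = []
    for dj in range(1, d + 1):
        g = np.full(n, np.inf)
        if n > dj:
            g[dj:] = ref[dj:] - ref[:-dj]
        gaps.append(g)

    # local alignment: chains start and end freely (unaligned molecule ends are
    # not penalized; the aligned-fraction filter handles fragmentary hits), so
    # null best scores do not scale with label count and stay comparable.
    S = np.empty((k, n))
    choice = np.zeros((k, n), dtype=np.int8)  # 0 = chain start, else (di-1)*d + dj
    S[0, :] = p.match_bonus
    cand = np.empty((d * d + 1, n))
    for i in range(1, k):
        cand[0, :] = p.match_bonus  # fresh chain starting at label i
        ci = 1
        for di in range(1, min(i, d) + 1):
            gm = mol[i] - mol[i - di]
            denom = p.sizing_sd * gm + p.position_sd
            pen = (
                p.match_bonus
                - p.spurious_label_penalty * (di - 1)
            )
            for dj in range(1, d + 1):
                row = cand[ci]
                row[:dj] = -np.inf
                z = (gaps[dj - 1][dj:] - gm) / denom
                row[dj:] = (
                    S[i - di, : n - dj]
                    + pen
                    - z * z
                    - p.missed_site_penalty * (dj - 1)
                )
                ci += 1
        block = cand[:ci]
        best = np.argmax(block, axis=0)
        S[i] = block[best, np.arange(n)]
        choice[i] = best

    total = S
    i, j = np.unravel_index(int(np.argmax(total)), total.shape)
    best_score = float(total[i, j])

    # ambiguity check: an equal score at a distinct locus means no call
    alt = total.copy()
    lo = np.searchsorted(ref, ref[j] - p.tie_margin_bp)
    hi = np.searchsorted(ref, ref[j] + p.tie_margin_bp)
    alt[:, lo:hi] = -np.inf
    if alt.size and np.max(alt) >= best_score - 1e-9:
        return best_score, []

    pairs = []
    while True:
        pairs.append((int(i), int(j)))
        c = int(choice[i, j])
        if c == 0:
            break
        c -= 1
        di, dj = c // d + 1, c % d + 1
        i, j = i - di, j - dj
    pairs.reverse()
    return best_score, pairs


class LabelAligner:
    """DP label aligner with a permutation-calibrated confidence scale.

    The calibration draws null molecules whose inter-label gaps are sampled
    i.i.d. from the reference's own gap distribution (a gap shuffle destroys
    colinearity while preserving spacing statistics), aligns them, and fits a
    Gumbel right tail to the best null scores for several label counts.
    """

    def __init__(
        self,
        reference: MotifSiteTrack,
        scoring: ScoringParams | None = None,
        calibrate: bool = True,
        n_null: int = 40,
        null_label_counts: Sequence[int] = (8, 16, 32, 64),
        seed: int = 0,
    ):
        if not reference.sites or all(v.size == 0 for v in reference.sites.values()):
            raise ValueError("empty reference site map")
        self.reference = reference
        self.scoring = scoring or ScoringParams()
        self._ref_pos = {c: v.astype(np.float64) for c, v in reference.sites.items()}
        self._null_table: list[tuple[int, float, float]] = []
        if calibrate:
            self._calibrate(n_null, null_label_counts, seed)

    # -- confidence calibration ------------------------------------------------
    def _calibrate(self, n_null: int, label_counts: Sequence[int], seed: int) -> None:
        rng = np.random.default_rng(seed)
        all_gaps = np.concatenate(
            [np.diff(v) for v in self._ref_pos.values() if v.size > 1]
        )
        for k in label_counts:
            scores = []
            for _ in range(n_null):
                gaps = rng.choice(all_gaps, size=k - 1, replace=True)
                mol = np.concatenate(([0.0], np.cumsum(gaps)))
                s, _ = self._best_over_reference(mol)
                scores.append(s)
            loc, scale = _fit_gumbel(np.asarray(scores))
            self._null_table.append((k, loc, scale))
        self._null_table.sort()

    def _null_params(self, k: int) -> tuple[float, float]:
        tab = self._null_table
        if not tab:
            return 0.0, 1.0
        ks = np.array([t[0] for t in tab], dtype=float)
        locs = np.array([t[1] for t in tab])
        scales = np.array([t[2] for t in tab])
        return float(np.interp(k, ks, locs)), float(np.interp(k, ks, scales))

    def confidence(self, score: float, n_labels: int) -> float:
        """-log10 upper-tail p of the score under the shuffled-molecule null."""
        loc, scale = self._null_params(n_labels)
        z = (score - loc) / max(scale, 1e-9)
        # Gumbel sf = 1 - exp(-exp(-z)); for large z this is ~exp(-z)
        if z > 30:
            return z / _LN10
        sf = -np.expm1(-np.exp(-z))
        if sf <= 0:
            return z / _LN10
        return float(-np.log10(sf))

    # -- alignment -------------------------------------------------------------
    def _best_over_reference(self, mol: np.ndarray):
        best_score = -np.inf
        best = None
        for chrom, ref in self._ref_pos.items():
            if ref.size == 0:
                continue
            s, pairs = _dp_best(mol, ref, self.scoring)
            if s > best_score:
                best_score, best = s, (chrom, pairs)
        return best_score, best

    def align(self, molecule: Molecule) -> Alignment | None:
        p = self.scoring
        labels = molecule.genetic_labels.astype(np.float64)
        k = labels.size
        if k < p.min_labels:
            return None
        flipped = np.sort(molecule.length - labels)
        results = []
        for orientation, mol in (("+", labels), ("-", flipped)):
            s, best = self._best_over_reference(mol)
            results.append((s, orientation, mol, best))
        results.sort(key=lambda r: r[0], reverse=True)
        (s1, orientation, mol, best), (s2, *_rest) = results
        if best is None or not best[1]:
            return None
        if s2 >= s1 - 1e-9 and results[1][3] is not None:
            # orientation tie (e.g. a palindromic label pattern): ambiguous
            return None
        chrom, pairs = best
        ref = self._ref_pos[chrom]
        fidx = np.array([i for i, _ in pairs])
        ridx = np.array([j for _, j in pairs])
        fpos = mol[fidx]  # ascending, in the (possibly flipped) molecule frame
        rpos = ref[ridx]
        if orientation == "+":
            mol_idx, mol_pos = fidx, fpos
        else:
            mol_idx = k - 1 - fidx[::-1]
            mol_pos = labels[mol_idx]
        conf = self.confidence(s1, k)
        order = np.argsort(mol_pos)
        return Alignment(
            molecule_id=molecule.id,
            chromosome=chrom,
            ref_start=float(rpos.min()),
            ref_end=float(rpos.max()),
            orientation=orientation,
            pairs=[(int(mi), int(rj)) for mi, rj in zip(
                mol_idx, ridx if orientation == "+" else ridx[::-1]
            )],
            score=float(s1),
            confidence=conf,
            molecule_length=float(molecule.length),
            molecule_start=float(mol_pos.min()),
            molecule_end=float(mol_pos.max()),
            pair_mol_pos=mol_pos[order],
            pair_ref_pos=(rpos if orientation == "+" else rpos[::-1])[order],
            implied_genome_start=float(rpos[0] - fpos[0]),
        )

    def align_set(self, molecules) -> list[Alignment]:
        out = []
        for mol in molecules:
            aln = self.align(mol)
            if aln is not None:
                out.append(aln)
        return out


def _fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(max(scale, 1e-6))


def attach_pair_positions(
    alignments: Sequence[Alignment],
    molecules,
    reference: MotifSiteTrack,
) -> None:
    """Recompute cached pair coordinates (e.g. after reading an XMAP).

    Fills ``pair_mol_pos``/``pair_ref_pos`` in place from the molecule label
    positions and the reference site map, ordered by molecule coordinate.
    """
    by_id = {m.id: m for m in molecules}
    for aln in alignments:
        mol = by_id.get(aln.molecule_id)
        if mol is None:
            raise ValueError(f"alignment references unknown molecule {aln.molecule_id!r}")
        ref = reference.sites[aln.chromosome].astype(np.float64)
        mol_pos = np.array([mol.genetic_labels[i] for i, _ in aln.pairs])
        ref_pos = np.array([ref[j] for _, j in aln.pairs])
        order = np.argsort(mol_pos)
        aln.pair_mol_pos = mol_pos[order]
        aln.pair_ref_pos = ref_pos[order]


def align_molecule(
    molecule: Molecule,
    reference: MotifSiteTrack,
    scoring: ScoringParams | None = None,
    aligner: LabelAligner | None = None,
) -> Alignment | None:
    """One-shot wrapper; build a :class:`LabelAligner` once for many molecules."""
    if aligner is None:
        aligner = LabelAligner(reference, scoring=scoring)
    return aligner.align(molecule)


def filter_alignments(
    alignments: Sequence[Alignment],
    min_confidence: float = 17.0,
    min_aligned_fraction: float = 0.60,
    min_length: float = 150_000.0,
) -> list[Alignment]:
    """Standard molecule filters, inclusive at each bound.

    Defaults: alignment confidence >= 17 (p <= 1e-17), >= 60% of the molecule
    length aligned, molecule length >= 150 kb.
    """
    return [
        a
        for a in alignments
        if a.confidence >= min_confidence
        and a.aligned_fraction >= min_aligned_fraction
        and a.molecule_length >= min_length
    ]
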