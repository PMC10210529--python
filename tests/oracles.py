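"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain per-element Python loops, deliberately
sharing no code path with the package, so agreement is meaningful.
"""
from __future__ import annotations

import math

import numpy as np


def naive_motif_scan(seq: str, motif: str) -> list[int]:
    seq = seq.upper()
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def naive_two_strand_sites(seq: str, motif: str) -> set[int]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(motif))
    fwd = set(naive_motif_scan(seq, motif))
    # a reverse-strand occurrence of the motif covers the same bp as a forward
    # occurrence of its reverse complement
    rev = set(naive_motif_scan(seq, rc))
    return fwd | rev


def naive_bin(values: np.ndarray, factor: int, stat: str) -> list[float]:
    out = []
    for start in range(0, len(values), factor):
        chunk = [v for v in values[start : start + factor] if not math.isnan(v)]
        if not chunk:
            out.append(math.nan)
        elif stat == "mean":
            out.append(sum(chunk) / len(chunk))
        else:
            out.append(sum(chunk))
    return out


def naive_smooth(values: np.ndarray, radius: int, sd_bins: float) -> list[float]:
    weights = [math.exp(-0.5 * (o / sd_bins) ** 2) for o in range(-radius, radius + 1)]
    out = []
    for i in range(len(values)):
        num = den = 0.0
        for o, w in zip(range(-radius, radius + 1), weights):
            j = i + o
            if 0 <= j < len(values) and not math.isnan(values[j]):
                num += w * values[j]
                den += w
        out.append(num / den if den > 0 else math.nan)
    return out


def naive_project(molecules, alignments, chrom_lengths, bin_size):
    """Per-pixel accumulation with explicit loops; mean per bin, coverage."""
    by_id = {m.id: m for m in molecules}
    nb = {c: math.ceil(length / bin_size) for c, length in chrom_lengths.items()}
    sums = {c: [0.0] * n for c, n in nb.items()}
    cnts = {c: [0] * n for c, n in nb.items()}
    cov = {c: [set() for _ in range(n)] for c, n in nb.items()}
    for aln in alignments:
        mol = by_id[aln.molecule_id]
        xp = list(aln.pair_mol_pos)
        fp = list(aln.pair_ref_pos)
        for p in range(len(mol.profile)):
            x = (p + 0.5) * mol.pixel_size
            if x <= xp[0]:
                k = 0
            elif x >= xp[-1]:
                k = len(xp) - 2
            else:
                k = max(i for i in range(len(xp) - 1) if xp[i] <= x)
            if xp[k + 1] == xp[k]:
                continue
            ref = fp[k] + (x - xp[k]) * (fp[k + 1] - fp[k]) / (xp[k + 1] - xp[k])
            b = math.floor(ref / bin_size)
            if 0 <= b < nb[aln.chromosome]:
                sums[aln.chromosome][b] += mol.profile[p]
                cnts[aln.chromosome][b] += 1
                cov[aln.chromosome][b].add(mol.id)
    mean = {
        c: [s / n if n else math.nan for s, n in zip(sums[c], cnts[c])] for c in sums
    }
    coverage = {c: [len(s) for s in cov[c]] for c in cov}
    return mean, coverage


def naive_scale_regions_row(chrom_values, track_bin, start, end, ncol):
    length = end - start
    cols = [[] for _ in range(ncol)]
    for bp in range(start, end):
        col = (bp - start) * ncol // length
        if 0 <= bp < len(chrom_values) * track_bin:
            v = chrom_values[bp // track_bin]
            if not math.isnan(v):
                cols[col].append(v)
    return [sum(c) / len(c) if c else math.nan for c in cols]


def naive_ref_point_row(chrom_values, track_bin, anchor, flank, bin_size):
    ncol = math.ceil(2 * flank / bin_size)
    cols = [[] for _ in range(ncol)]
    for bp in range(anchor - flank, anchor + flank):
        col = (bp - (anchor - flank)) // bin_size
        if 0 <= bp < len(chrom_values) * track_bin:
            v = chrom_values[bp // track_bin]
            if not math.isnan(v):
                cols[col].append(v)
    return [sum(c) / len(c) if c else math.nan for c in cols]


def naive_column_stats(matrix):
    """Per-column mean and sample sd ignoring NaNs."""
    nrow, ncol = matrix.shape
    means, sds, ns = [], [], []
    for c in range(ncol):
        vals = [matrix[r, c] for r in range(nrow) if not math.isnan(matrix[r, c])]
        ns.append(len(vals))
        if not vals:
            means.append(math.nan)
            sds.append(math.nan)
            continue
        m = sum(vals) / len(vals)
        means.append(m)
        if len(vals) < 2:
            sds.append(0.0)
        else:
            sds.append(math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1)))
    return means, sds, ns


def naive_allele_window_sums(vals1, vals2, windows, track_bin, bin_size):
    """Per-1kb-bin sums of two same-frame tracks inside merged windows."""
    out = {}
    for (start, end) in windows:
        first = start // bin_size
        last = math.ceil(end / bin_size)
        for b in range(first, last):
            if b in out:
                continue
            s1 = s2 = 0.0
            any1 = any2 = False
            for t in range(b * bin_size // track_bin, min((b + 1) * bin_size // track_bin,
                                                          len(vals1), len(vals2))):
                if not math.isnan(vals1[t]):
                    s1 += vals1[t]
                    any1 = True
                if not math.isnan(vals2[t]):
                    s2 += vals2[t]
                    any2 = True
            # a 1 kb bin is dropped when either allele has no covered fine bin
            out[b] = (s1, s2) if (any1 and any2) else None
    return out
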