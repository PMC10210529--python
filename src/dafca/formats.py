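"""Readers and writers for the text formats the pipeline touches.

FASTA (reference), CMAP (theoretical label maps), BNX 1.3 plus a profile
sidecar TSV (molecules with continuous accessibility profiles), XMAP
(alignments), BED (annotations) and bedGraph (genome tracks).

Internal coordinates are 0-based half-open; CMAP and XMAP are 1-based and are
converted at this boundary (fractional bp rounded half-to-even).  Standard BNX
has no channel for a continuous per-pixel profile, so profiles travel in a
versioned sidecar table documented in :func:`write_bnx_with_profiles`.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np

from .types import GenomeInterval, GenomeTrack, Molecule, MoleculeSet, MotifSiteTrack, n_bins

__all__ = [
    "FormatError",
    "read_fasta",
    "find_motif_sites",
    "read_cmap",
    "write_cmap",
    "read_bnx_with_profiles",
    "write_bnx_with_profiles",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_xmap",
    "write_xmap",
]

_FLOAT = "%.17g"  # round-trips IEEE doubles exactly


class FormatError(ValueError):
    """Malformed file content; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into {name: upper-cased sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path), build_index=False, rebuild=False) as fa:
        return {name: str(rec[:]).upper() for name, rec in fa.items()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def find_motif_sites(sequences: Mapping[str, str], motif: str) -> MotifSiteTrack:
    """Locate every exact forward-strand occurrence of ``motif``.

    Both labeling motifs used here (GATC for Dam, CTTAAG for DLE-1) are
    reverse-complement palindromes, so the forward strand describes both
    strands.  Overlapping occurrences are all reported; ambiguity codes in the
    sequence never match.
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty and ACGT-only, got {motif!r}")
    if not sequences:
        raise ValueError("empty sequence set")
    sites: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        hits = []
        i = seq.find(motif)
        while i != -1:
            hits.append(i)
            i = seq.find(motif, i + 1)  # step 1 so overlapping hits are kept
        sites[name] = np.asarray(hits, dtype=np.int64)
        lengths[name] = len(seq)
    return MotifSiteTrack(motif=motif, sites=sites, genome_lengths=lengths)


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------

def write_cmap(track: MotifSiteTrack, path) -> None:
    """Write a MotifSiteTrack as a Bionano CMAP v0.1 text file.

    Contigs get integer ids in order; the name mapping is preserved in a
    header comment so :func:`read_cmap` restores chromosome names.
    """
    names = list(track.sites)
    with open(path, "w") as fh:
        fh.write("# CMAP File Version:\t0.1\n")
        fh.write("# Label Channels:\t1\n")
        fh.write(f"# Nickase Recognition Site 1:\t{track.motif}\n")
        fh.write("# Contig Names:\t" + ";".join(f"{i + 1}={n}" for i, n in enumerate(names)) + "\n")
        fh.write(
            "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition"
            "\tStdDev\tCoverage\tOccurrence\n"
        )
        fh.write("#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\n")
        for cid, name in enumerate(names, start=1):
            pos = track.sites[name]
            length = float(track.genome_lengths[name])
            for sid, p in enumerate(pos, start=1):
                # internal 0-based -> CMAP 1-based
                fh.write(
                    f"{cid}\t{length:.1f}\t{pos.size}\t{sid}\t1\t{float(p) + 1.0:.1f}"
                    "\t1.0\t1.0\t1.0\n"
                )
            fh.write(f"{cid}\t{length:.1f}\t{pos.size}\t{pos.size + 1}\t0\t{length:.1f}\t0.0\t1.0\t0.0\n")


def read_cmap(path) -> MotifSiteTrack:
    """Read a CMAP file back into a MotifSiteTrack (positions to 0-based)."""
    motif = "GATC"
    name_map: dict[int, str] = {}
    sites: dict[int, list[int]] = {}
    lengths: dict[int, int] = {}
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# Nickase Recognition Site 1:"):
                    motif = line.split(":", 1)[1].strip()
                elif line.startswith("# Contig Names:"):
                    for item in line.split(":", 1)[1].strip().split(";"):
                        cid, name = item.split("=", 1)
                        name_map[int(cid)] = name
                elif line.startswith("#h"):
                    saw_header = True
                continue
            if not saw_header:
                raise FormatError("data before #h column header", lineno)
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"expected >= 6 columns, got {len(fields)}", lineno)
            try:
                cid = int(fields[0])
                length = float(fields[1])
                channel = int(fields[4])
                position = float(fields[5])
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from None
            lengths[cid] = int(round(length))
            if channel == 0:  # contig-end sentinel record
                sites.setdefault(cid, [])
                continue
            internal = int(np.rint(position - 1.0))  # 1-based float -> 0-based, half-even
            prev = sites.setdefault(cid, [])
            if prev and internal <= prev[-1]:
                raise FormatError(
                    f"non-monotone position {position} on contig {cid}", lineno
                )
            prev.append(internal)
    if not sites:
        raise FormatError("no records found in CMAP")
    names = {cid: name_map.get(cid, str(cid)) for cid in sites}
    return MotifSiteTrack(
        motif=motif,
        sites={names[cid]: np.asarray(v, dtype=np.int64) for cid, v in sites.items()},
        genome_lengths={names[cid]: lengths[cid] for cid in sites},
    )


# ---------------------------------------------------------------------------
# BNX + profile sidecar
# ---------------------------------------------------------------------------

SIDECAR_MAGIC = "#dafca profile sidecar\tv1"


def write_bnx_with_profiles(molecules: MoleculeSet, bnx_path, sidecar_path) -> None:
    """Write molecules as BNX 1.3 plus the continuous-profile sidecar.

    The BNX carries molecule length and genetic label positions (channel 1).
    The sidecar is a tab-separated table, one row per molecule::

        #dafca profile sidecar\tv1
        #sample_type\t<chromatin|naked>
        #molecule_id\tpixel_size_bp\tintensities
        <id>\t<pixel bp>\t<comma-separated per-pixel intensities>

    Floats are printed with 17 significant digits so a write/read round trip
    is bit-exact.
    """
    with open(bnx_path, "w") as fh:
        fh.write("# BNX File Version:\t1.3\n")
        fh.write("# Label Channels:\t1\n")
        fh.write("# Nickase Recognition Site 1:\tCTTAAG\n")
        fh.write("#0h\tLabelChannel\tMoleculeId\tLength\n")
        fh.write("#1h\tLabelChannel\tLabelPositions[N]\n")
        for mol in molecules:
            fh.write(f"0\t{mol.id}\t{_FLOAT % mol.length}\n")
            parts = [_FLOAT % p for p in mol.genetic_labels]
            parts.append(_FLOAT % mol.length)  # BNX convention: molecule end closes the line
            fh.write("1\t" + "\t".join(parts) + "\n")
    with open(sidecar_path, "w") as fh:
        fh.write(SIDECAR_MAGIC + "\n")
        fh.write(f"#sample_type\t{molecules.sample_type}\n")
        fh.write("#molecule_id\tpixel_size_bp\tintensities\n")
        for mol in molecules:
            prof = ",".join(_FLOAT % v for v in mol.profile)
            fh.write(f"{mol.id}\t{_FLOAT % mol.pixel_size}\t{prof}\n")


def _read_sidecar(path) -> tuple[str, dict[str, tuple[float, np.ndarray]]]:
    sample_type = "chromatin"
    profiles: dict[str, tuple[float, np.ndarray]] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SIDECAR_MAGIC:
            raise FormatError(f"not a dafca profile sidecar (got {first!r})", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#sample_type"):
                sample_type = line.split("\t")[1]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"expected 3 columns, got {len(fields)}", lineno)
            vals = (
                np.asarray(fields[2].split(","), dtype=np.float64)
                if fields[2]
                else np.empty(0)
            )
            profiles[fields[0]] = (float(fields[1]), vals)
    return sample_type, profiles


def read_bnx_with_profiles(
    bnx_path, sidecar_path, on_missing_profile: str = "error"
) -> MoleculeSet:
    """Read BNX + sidecar back into a MoleculeSet.

    ``on_missing_profile``: 'error' (default) raises if a BNX molecule has no
    sidecar row; 'skip' drops such molecules.
    """
    if on_missing_profile not in ("error", "skip"):
        raise ValueError("on_missing_profile must be 'error' or 'skip'")
    sample_type, profiles = _read_sidecar(sidecar_path)
    molecules: list[Molecule] = []
    cur_id: str | None = None
    cur_len = 0.0
    with open(bnx_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "0":
                if len(fields) < 3:
                    raise FormatError("molecule header needs id and length", lineno)
                cur_id, cur_len = fields[1], float(fields[2])
            elif fields[0] == "1":
                if cur_id is None:
                    raise FormatError("label line before molecule header", lineno)
                labels = np.asarray([float(x) for x in fields[1:]])
                if labels.size:  # trailing entry is the molecule end marker
                    labels = labels[:-1]
                if labels.size and labels.max() > cur_len:
                    raise FormatError(
                        f"label position {labels.max()} exceeds molecule length {cur_len}", lineno
                    )
                if labels.size and np.any(np.diff(labels) < 0):
                    raise FormatError("label positions not sorted", lineno)
                if cur_id not in profiles:
                    if on_missing_profile == "error":
                        raise FormatError(f"molecule {cur_id} missing from sidecar", lineno)
                    cur_id = None
                    continue
                pixel_size, prof = profiles[cur_id]
                molecules.append(
                    Molecule(
                        id=cur_id,
                        length=cur_len,
                        genetic_labels=labels,
                        profile=prof,
                        pixel_size=pixel_size,
                    )
                )
                cur_id = None
    return MoleculeSet(molecules=molecules, sample_type=sample_type)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, chrom_lengths: Mapping[str, int] | None = None) -> list[GenomeInterval]:
    """Read BED3/4/6 (0-based half-open) into GenomeInterval records."""
    out: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"BED needs >= 3 columns, got {len(f)}", lineno)
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from None
            if start >= end or start < 0:
                raise FormatError(f"invalid BED interval {f[0]}:{start}-{end}", lineno)
            if chrom_lengths is not None and f[0] in chrom_lengths and end > chrom_lengths[f[0]]:
                raise FormatError(
                    f"interval {f[0]}:{start}-{end} beyond chromosome length "
                    f"{chrom_lengths[f[0]]}", lineno
                )
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(GenomeInterval(f[0], start, end, strand=strand, name=name, score=score))
    return out


def write_bed(intervals: Iterable[GenomeInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = _FLOAT % iv.score if iv.score is not None else "."
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: GenomeTrack, path) -> None:
    """Write a binned track as bedGraph, merging adjacent equal-valued bins.

    Missing (NaN) bins are omitted; the final bin is clipped to the chromosome
    length when known.
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            clip = None
            if track.chrom_lengths is not None and chrom in track.chrom_lengths:
                clip = track.chrom_lengths[chrom]
            i = 0
            nb = vals.size
            while i < nb:
                v = vals[i]
                if np.isnan(v):
                    i += 1
                    continue
                j = i + 1
                while j < nb and vals[j] == v:
                    j += 1
                end = j * bs
                if clip is not None:
                    end = min(end, clip)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{_FLOAT % v}\n")
                i = j


def read_bedgraph(
    path, bin_size: int, chrom_lengths: Mapping[str, int] | None = None, label: str = ""
) -> GenomeTrack:
    """Read a bedGraph written on a fixed bin grid back into a GenomeTrack.

    Bins not covered by any record are restored as missing (NaN).  Record
    starts must fall on the bin grid; ends may be partial (clipped last bin).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    records: dict[str, list[tuple[int, int, float]]] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"bedGraph needs 4 columns, got {len(f)}", lineno)
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if start % bin_size != 0:
                raise FormatError(f"record start {start} not on {bin_size} bp grid", lineno)
            records.setdefault(chrom, []).append((start, end, value))
            maxend[chrom] = max(maxend.get(chrom, 0), end)
    if chrom_lengths is None:
        chrom_lengths = maxend
    track = GenomeTrack.empty(chrom_lengths, bin_size, label=label)
    for chrom, recs in records.items():
        vals = track.values[chrom]
        for start, end, value in recs:
            vals[start // bin_size : n_bins(end, bin_size)] = value
    return track


# ---------------------------------------------------------------------------
# XMAP
# ---------------------------------------------------------------------------

def write_xmap(alignments, reference: MotifSiteTrack, path) -> None:
    """Write alignments as Bionano XMAP v0.2 (1-based coordinates)."""
    names = list(reference.sites)
    rid = {name: i + 1 for i, name in enumerate(names)}
    with open(path, "w") as fh:
        fh.write("# XMAP File Version:\t0.2\n")
        fh.write("# Contig Names:\t" + ";".join(f"{rid[n]}={n}" for n in names) + "\n")
        fh.write(
            "#h XmapEntryID\tQryContigID\tRefContigID\tQryStartPos\tQryEndPos"
            "\tRefStartPos\tRefEndPos\tOrientation\tConfidence\tHitEnum"
            "\tQryLen\tRefLen\tLabelChannel\tAlignment\n"
        )
        for i, aln in enumerate(alignments, start=1):
            pairs = "".join(f"({r + 1},{q + 1})" for q, r in aln.pairs)
            qry_start = aln.molecule_start
            qry_end = aln.molecule_end
            fh.write(
                f"{i}\t{aln.molecule_id}\t{rid[aln.chromosome]}"
                f"\t{qry_start + 1.0:.1f}\t{qry_end + 1.0:.1f}"
                f"\t{aln.ref_start + 1.0:.1f}\t{aln.ref_end + 1.0:.1f}"
                f"\t{aln.orientation}\t{aln.confidence:.2f}\t{len(aln.pairs)}M"
                f"\t{aln.molecule_length:.1f}"
                f"\t{float(reference.genome_lengths[aln.chromosome]):.1f}"
                f"\t1\t{pairs}\n"
            )


def read_xmap(path):
    """Read an XMAP written by :func:`write_xmap` back into Alignment records."""
    from .align import Alignment

    name_map: dict[str, str] = {}
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# Contig Names:"):
                    for item in line.split(":", 1)[1].strip().split(";"):
                        cid, name = item.split("=", 1)
                        name_map[cid] = name
                continue
            f = line.split("\t")
            if len(f) < 14:
                raise FormatError(f"XMAP needs 14 columns, got {len(f)}", lineno)
            pairs = []
            for token in f[13].replace("(", " ").replace(")", " ").split():
                r, q = token.split(",")
                pairs.append((int(q) - 1, int(r) - 1))
            out.append(
                Alignment(
                    molecule_id=f[1],
                    chromosome=name_map.get(f[2], f[2]),
                    ref_start=float(f[5]) - 1.0,
                    ref_end=float(f[6]) - 1.0,
                    orientation=f[7],
                    pairs=pairs,
                    score=float("nan"),
                    confidence=float(f[8]),
                    molecule_length=float(f[10]),
                    molecule_start=float(f[3]) - 1.0,
                    molecule_end=float(f[4]) - 1.0,
                )
            )
    return out
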