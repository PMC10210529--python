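"""Format IO: motif scanning, CMAP/BNX/BED/bedGraph/XMAP round trips."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dafca import formats
from dafca.types import GenomeInterval, GenomeTrack, Molecule, MoleculeSet, MotifSiteTrack

from oracles import naive_motif_scan, naive_two_strand_sites

dna = st.text(alphabet="ACGT", min_size=0, max_size=2000)


class TestMotifScan:
    def test_direct_examples(self):
        t = formats.find_motif_sites({"chr1": "GATCGATC"}, "GATC")
        assert t.sites["chr1"].tolist() == [0, 4]
        t = formats.find_motif_sites({"chrX": "ACTTAAGT"}, "CTTAAG")
        assert t.sites["chrX"].tolist() == [1]

    def test_overlapping_occurrences_reported(self):
        t = formats.find_motif_sites({"c": "AAAA"}, "AA")
        assert t.sites["c"].tolist() == [0, 1, 2]

    def test_ambiguity_codes_never_match(self):
        t = formats.find_motif_sites({"c": "GANCGATC"}, "GATC")
        assert t.sites["c"].tolist() == [4]

    def test_lower_case_input_upper_cased(self):
        t = formats.find_motif_sites({"c": "gatc"}, "GATC")
        assert t.sites["c"].tolist() == [0]

    @pytest.mark.parametrize("motif", ["", "GAXC", "gatc"])
    def test_invalid_motif_rejected(self, motif):
        with pytest.raises(ValueError):
            formats.find_motif_sites({"c": "GATC"}, motif)

    def test_empty_sequence_set_rejected(self):
        with pytest.raises(ValueError):
            formats.find_motif_sites({}, "GATC")

    @given(seq=dna)
    def test_matches_naive_oracle(self, seq):
        got = formats.find_motif_sites({"c": seq + "GATC"}, "GATC").sites["c"].tolist()
        assert got == naive_motif_scan(seq + "GATC", "GATC")

    @given(seq=dna)
    @pytest.mark.parametrize("motif", ["GATC", "CTTAAG"])
    def test_palindrome_forward_strand_suffices(self, seq, motif):
        """Both labeling motifs are reverse-complement palindromes, so the
        forward-strand scan equals the two-strand deduplicated scan."""
        fwd = formats.find_motif_sites({"c": seq + motif}, motif).sites["c"]
        assert set(fwd.tolist()) == naive_two_strand_sites(seq + motif, motif)

    def test_reverse_complement_same_count(self):
        seq = "GATCGATC"
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        a = formats.find_motif_sites({"c": seq}, "GATC").sites["c"].size
        b = formats.find_motif_sites({"c": rc}, "GATC").sites["c"].size
        assert a == b == 2


class TestCmap:
    def roundtrip(self, track, tmp_path):
        path = tmp_path / "x.cmap"
        formats.write_cmap(track, path)
        return formats.read_cmap(path)

    def test_roundtrip_identity(self, tmp_path):
        t = MotifSiteTrack("GATC", {"chr1": [0, 4]}, {"chr1": 100})
        back = self.roundtrip(t, tmp_path)
        assert back.motif == "GATC"
        assert back.sites["chr1"].tolist() == [0, 4]
        assert back.genome_lengths["chr1"] == 100

    def test_one_based_conversion(self, tmp_path):
        path = tmp_path / "x.cmap"
        path.write_text(
            "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition"
            "\tStdDev\tCoverage\tOccurrence\n"
            "1\t100.0\t1\t1\t1\t5.0\t1.0\t1.0\t1.0\n"
        )
        assert formats.read_cmap(path).sites["1"].tolist() == [4]

    def test_empty_contig_retained(self, tmp_path):
        t = MotifSiteTrack("GATC", {"chr1": [3], "chr2": []}, {"chr1": 50, "chr2": 80})
        back = self.roundtrip(t, tmp_path)
        assert back.sites["chr2"].size == 0
        assert back.genome_lengths["chr2"] == 80

    def test_fuzzed_roundtrip(self, tmp_path, rng):
        sites = {
            f"c{i}": np.unique(rng.integers(0, 99_996, size=rng.integers(0, 60)))
            for i in range(4)
        }
        t = MotifSiteTrack("CTTAAG", sites, {c: 100_000 for c in sites})
        back = self.roundtrip(t, tmp_path)
        for c in sites:
            assert back.sites[c].tolist() == t.sites[c].tolist()

    def test_non_monotone_positions_error_names_line(self, tmp_path):
        path = tmp_path / "bad.cmap"
        path.write_text(
            "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition"
            "\tStdDev\tCoverage\tOccurrence\n"
            "1\t100.0\t2\t1\t1\t50.0\t1\t1\t1\n"
            "1\t100.0\t2\t2\t1\t20.0\t1\t1\t1\n"
        )
        with pytest.raises(formats.FormatError, match="line 3"):
            formats.read_cmap(path)


def _mol(mid="7", length=200_000.0, labels=(10_000.0, 50_000.0), pixel=500.0, rng=None):
    n = int(np.ceil(length / pixel))
    profile = rng.random(n) if rng is not None else np.linspace(0, 1, n)
    return Molecule(id=mid, length=length, genetic_labels=np.array(labels),
                    profile=profile, pixel_size=pixel)


class TestBnxSidecar:
    def test_roundtrip_bit_exact(self, tmp_path, rng):
        mols = MoleculeSet([_mol(rng=rng), _mol("8", 151_111.25, (1.5, 99_999.875), rng=rng)],
                           sample_type="naked")
        formats.write_bnx_with_profiles(mols, tmp_path / "m.bnx", tmp_path / "m.tsv")
        back = formats.read_bnx_with_profiles(tmp_path / "m.bnx", tmp_path / "m.tsv")
        assert back.sample_type == "naked"
        for a, b in zip(mols, back):
            assert a.id == b.id and a.length == b.length
            assert a.genetic_labels.tolist() == b.genetic_labels.tolist()
            assert a.profile.tolist() == b.profile.tolist()

    def test_zero_label_molecule_retained(self, tmp_path):
        mols = MoleculeSet([_mol(labels=())])
        formats.write_bnx_with_profiles(mols, tmp_path / "m.bnx", tmp_path / "m.tsv")
        back = formats.read_bnx_with_profiles(tmp_path / "m.bnx", tmp_path / "m.tsv")
        assert len(back) == 1 and back.molecules[0].n_labels == 0

    def test_label_beyond_length_rejected(self, tmp_path):
        formats.write_bnx_with_profiles(MoleculeSet([_mol()]), tmp_path / "m.bnx",
                                        tmp_path / "m.tsv")
        text = (tmp_path / "m.bnx").read_text().replace("10000", "900000")
        (tmp_path / "m.bnx").write_text(text)
        with pytest.raises(formats.FormatError):
            formats.read_bnx_with_profiles(tmp_path / "m.bnx", tmp_path / "m.tsv")

    def test_missing_sidecar_entry(self, tmp_path):
        mols = MoleculeSet([_mol("1"), _mol("2")])
        formats.write_bnx_with_profiles(mols, tmp_path / "m.bnx", tmp_path / "m.tsv")
        kept = [ln for ln in (tmp_path / "m.tsv").read_text().splitlines()
                if not ln.startswith("2\t")]
        (tmp_path / "m.tsv").write_text("\n".join(kept) + "\n")
        with pytest.raises(formats.FormatError, match="missing from sidecar"):
            formats.read_bnx_with_profiles(tmp_path / "m.bnx", tmp_path / "m.tsv")
        back = formats.read_bnx_with_profiles(tmp_path / "m.bnx", tmp_path / "m.tsv",
                                              on_missing_profile="skip")
        assert [m.id for m in back] == ["1"]


class TestBed:
    def test_roundtrip(self, tmp_path):
        ivs = [GenomeInterval("chr1", 0, 100, "+", "a", 3.5),
               GenomeInterval("chr2", 50, 60, "-", None, None)]
        formats.write_bed(ivs, tmp_path / "x.bed")
        back = formats.read_bed(tmp_path / "x.bed")
        assert back == ivs

    def test_start_after_end_rejected(self, tmp_path):
        (tmp_path / "bad.bed").write_text("chr1\t100\t50\n")
        with pytest.raises(formats.FormatError):
            formats.read_bed(tmp_path / "bad.bed")

    def test_interval_beyond_chromosome_rejected(self, tmp_path):
        (tmp_path / "bad.bed").write_text("chr1\t10\t2000\n")
        with pytest.raises(formats.FormatError, match="beyond"):
            formats.read_bed(tmp_path / "bad.bed", chrom_lengths={"chr1": 1000})


class TestBedgraph:
    def test_adjacent_equal_bins_merged(self, tmp_path):
        t = GenomeTrack(500, {"chr1": [1.0, 1.0, 2.0]}, chrom_lengths={"chr1": 1500})
        formats.write_bedgraph(t, tmp_path / "x.bg")
        lines = (tmp_path / "x.bg").read_text().splitlines()
        assert lines == ["chr1\t0\t1000\t1", "chr1\t1000\t1500\t2"]

    def test_missing_bins_omitted_and_restored(self, tmp_path):
        vals = np.array([1.0, np.nan, 3.0])
        t = GenomeTrack(500, {"chr1": vals}, chrom_lengths={"chr1": 1500})
        formats.write_bedgraph(t, tmp_path / "x.bg")
        assert len((tmp_path / "x.bg").read_text().splitlines()) == 2
        back = formats.read_bedgraph(tmp_path / "x.bg", 500, {"chr1": 1500})
        assert np.isnan(back.values["chr1"][1])
        assert back.values["chr1"][[0, 2]].tolist() == [1.0, 3.0]

    def test_write_read_write_idempotent(self, tmp_path, rng):
        vals = rng.random(40)
        vals[rng.random(40) < 0.3] = np.nan
        t = GenomeTrack(500, {"chr1": vals}, chrom_lengths={"chr1": 19_800})
        formats.write_bedgraph(t, tmp_path / "a.bg")
        back = formats.read_bedgraph(tmp_path / "a.bg", 500, {"chr1": 19_800})
        formats.write_bedgraph(back, tmp_path / "b.bg")
        assert (tmp_path / "a.bg").read_text() == (tmp_path / "b.bg").read_text()
        np.testing.assert_array_equal(back.values["chr1"], vals)


class TestXmap:
    def test_roundtrip_via_aligner(self, tmp_path, rng):
        from dafca.align import LabelAligner

        ref_sites = np.sort(rng.choice(200_000, size=50, replace=False)).astype(float)
        ref = MotifSiteTrack("CTTAAG", {"chr1": ref_sites.astype(int)}, {"chr1": 200_000})
        labels = ref_sites[10:30] - ref_sites[10] + 100.0
        mol = Molecule("m1", 160_000.0, labels, np.zeros(320), 500.0)
        aligner = LabelAligner(ref, calibrate=False)
        aln = aligner.align(mol)
        aln.confidence = 33.0
        formats.write_xmap([aln], ref, tmp_path / "x.xmap")
        back = formats.read_xmap(tmp_path / "x.xmap")[0]
        assert back.molecule_id == "m1"
        assert back.chromosome == "chr1"
        assert back.orientation == aln.orientation
        assert back.pairs == aln.pairs
        assert back.confidence == pytest.approx(33.0, abs=0.01)
        assert back.ref_start == pytest.approx(aln.ref_start)
        assert back.molecule_length == pytest.approx(aln.molecule_length, abs=0.1)
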