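import numpy as np
import pytest

from reefadmix.alignment import Alignment, DuplicateTaxonError, read_alignment, write_alignment
from reefadmix.snp_io import (
    FilterSpec,
    SampleNotFoundError,
    SiteRecord,
    SnpMatrix,
    filter_sites,
    read_vcf,
    to_alignment,
    write_vcf,
)

from conftest import TOY_VCF_STATES


class TestReadVcf:
    def test_toy_fixture_matches_hand_decoded_table(self, toy_vcf):
        m = read_vcf(toy_vcf)
        assert m.sample_ids == ["s1", "s2", "s3"]
        assert m.n_sites == 5
        np.testing.assert_array_equal(m.genotypes, TOY_VCF_STATES)
        assert m.sites[0] == SiteRecord("chr1", 100, "A", ("G",), 50.0)
        assert m.sites[3].alt_alleles == ("A", "C")

    def test_half_call_maps_to_missing(self, toy_vcf):
        m = read_vcf(toy_vcf)
        assert m.genotypes[2, 4] == -1  # s3 "./0" on chr2:100

    def test_empty_vcf_gives_zero_sites(self, empty_vcf):
        m = read_vcf(empty_vcf)
        assert m.n_sites == 0
        assert m.genotypes.shape == (3, 0)

    def test_sample_subset_order_and_missing_sample_error(self, toy_vcf):
        m = read_vcf(toy_vcf, sample_subset=["s3", "s1"])
        assert m.sample_ids == ["s3", "s1"]
        np.testing.assert_array_equal(m.genotypes, TOY_VCF_STATES[[2, 0]])
        with pytest.raises(SampleNotFoundError, match="sX"):
            read_vcf(toy_vcf, sample_subset=["s1", "sX"])

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "absent.vcf")


def _matrix(sites, geno, ids=None):
    geno = np.asarray(geno, dtype=np.int8)
    ids = ids or [f"s{i}" for i in range(geno.shape[0])]
    return SnpMatrix(ids, sites, geno)


class TestFilterSites:
    def test_indel_removed(self):
        sites = [
            SiteRecord("c", 1, "A", ("AT",), 99.0),
            SiteRecord("c", 500, "A", ("G",), 99.0),
        ]
        m = _matrix(sites, [[0, 2], [2, 0], [1, 1], [0, 2]])
        out, report = filter_sites(m, FilterSpec(mac_min=0, thin_bp=0))
        assert [s.pos for s in out.sites] == [500]
        assert report.removed["indel"] == 1

    def test_call_rate_boundary_at_half(self):
        # 10 samples, 4 missing -> rate 0.6 kept; 6 missing -> rate 0.4 removed
        sites = [SiteRecord("c", 1, "A", ("G",), 99.0), SiteRecord("c", 500, "A", ("G",), 99.0)]
        col_keep = [-1] * 4 + [0, 2, 0, 2, 0, 2]
        col_drop = [-1] * 6 + [0, 2, 0, 2]
        geno = np.array([col_keep, col_drop]).T
        m = _matrix(sites, geno)
        out, report = filter_sites(
            m, FilterSpec(max_missing=0.5, mac_min=0, thin_bp=0, qual_min=0)
        )
        assert [s.pos for s in out.sites] == [1]
        assert report.removed["missing"] == 1

    def test_thin_is_greedy_left_to_right(self):
        sites = [SiteRecord("c", p, "A", ("G",), 99.0) for p in (100, 250, 500)]
        m = _matrix(sites, np.tile([0, 2, 0, 2], (3, 1)).T.reshape(4, 3))
        out, _ = filter_sites(m, FilterSpec(thin_bp=300, mac_min=0, qual_min=0))
        assert [s.pos for s in out.sites] == [100, 500]

    def test_report_counts_sum_to_removed_total(self, toy_vcf):
        m = read_vcf(toy_vcf)
        out, report = filter_sites(m, FilterSpec())
        assert report.n_in - report.n_out == sum(report.removed.values())
        # toy fixture: indel chr1:500, multiallelic chr1:600, low qual chr1:150,
        # mac-1 chr2:100 -> only chr1:100 survives
        assert [s.pos for s in out.sites] == [100]

    def test_idempotence(self, toy_vcf):
        m = read_vcf(toy_vcf)
        spec = FilterSpec()
        once, _ = filter_sites(m, spec)
        twice, report = filter_sites(once, spec)
        assert twice.n_sites == once.n_sites
        np.testing.assert_array_equal(twice.genotypes, once.genotypes)
        assert sum(report.removed.values()) == 0

    @pytest.mark.parametrize("qual_pair", [(0.0, 40.0), (10.0, 60.0)])
    def test_monotone_in_qual_threshold(self, toy_vcf, qual_pair):
        m = read_vcf(toy_vcf)
        lo, hi = qual_pair
        n_lo = filter_sites(m, FilterSpec(qual_min=lo, mac_min=0, thin_bp=0))[0].n_sites
        n_hi = filter_sites(m, FilterSpec(qual_min=hi, mac_min=0, thin_bp=0))[0].n_sites
        assert n_hi <= n_lo

    def test_monotone_in_missingness_allowance(self, toy_vcf):
        m = read_vcf(toy_vcf)
        strict = filter_sites(m, FilterSpec(max_missing=1.0, mac_min=0, thin_bp=0, qual_min=0))[0]
        loose = filter_sites(m, FilterSpec(max_missing=0.0, mac_min=0, thin_bp=0, qual_min=0))[0]
        assert strict.n_sites <= loose.n_sites


class TestToAlignment:
    def test_het_encodes_iupac_and_missing_n(self):
        sites = [SiteRecord("c", 1, "A", ("G",), 99.0)]
        m = _matrix(sites, [[0], [1], [2], [-1]])
        a = to_alignment(m, min_samples_locus=3)
        assert [s for s in a.seqs] == ["A", "R", "G", "N"]

    def test_major_allele_mode_resolves_het(self):
        sites = [SiteRecord("c", 1, "A", ("G",), 99.0)]
        m = _matrix(sites, [[2], [1], [2], [2]])
        a = to_alignment(m, min_samples_locus=3, het="major")
        assert a.seqs[1] == "G"  # alt is the majority allele

    def test_low_coverage_column_dropped_at_threshold_10(self):
        sites = [SiteRecord("c", 1, "A", ("G",), 99.0), SiteRecord("c", 500, "A", ("G",), 99.0)]
        # 16 samples; site 1 has 7 present (dropped), site 2 fully called
        col1 = [0, 2, 0, 2, 0, 2, 0] + [-1] * 9
        col2 = [0, 2] * 8
        m = _matrix(sites, np.array([col1, col2]).T)
        a = to_alignment(m, min_samples_locus=10)
        assert a.n_sites == 1

    def test_all_surviving_keeps_column_count(self, toy_vcf):
        m = read_vcf(toy_vcf)
        m, _ = filter_sites(m, FilterSpec())
        a = to_alignment(m, min_samples_locus=0)
        assert a.n_sites == m.n_sites

    def test_threshold_above_sample_count_errors(self, toy_vcf):
        m = read_vcf(toy_vcf)
        with pytest.raises(ValueError, match="min_samples_locus"):
            to_alignment(m, min_samples_locus=10)

    def test_binary_encoding_codes(self):
        sites = [SiteRecord("c", 1, "A", ("G",), 99.0)]
        m = _matrix(sites, [[0], [1], [2], [-1]])
        a = to_alignment(m, min_samples_locus=0, encoding="binary")
        assert a.seqs == ["0", "1", "2", "?"]


class TestAlignmentIO:
    @pytest.mark.parametrize("fmt", ["fasta", "phylip-relaxed"])
    def test_round_trip_nucleotide(self, tmp_path, toy_alignment, fmt):
        path = tmp_path / "a.aln"
        write_alignment(toy_alignment, path, fmt)
        back = read_alignment(path, fmt)
        assert back.ids == toy_alignment.ids
        assert back.seqs == toy_alignment.seqs

    def test_round_trip_binary_nexus(self, tmp_path):
        a = Alignment(["t1", "t2"], ["012?", "2100"])
        path = tmp_path / "a.nex"
        write_alignment(a, path, "binary-nexus")
        back = read_alignment(path, "binary-nexus")
        assert (back.ids, back.seqs) == (a.ids, a.seqs)
        text = path.read_text()
        assert "NTAX=2" in text and "NCHAR=4" in text
        assert 'SYMBOLS="012"' in text

    def test_phylip_header_dimensions(self, tmp_path):
        a = Alignment(["t1", "t2"], ["ACG", "ACT"])
        path = tmp_path / "a.phy"
        write_alignment(a, path, "phylip-relaxed")
        header = path.read_text().splitlines()[0].split()
        assert header == ["2", "3"]

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(DuplicateTaxonError):
            Alignment(["t1", "t1"], ["AC", "AG"])

    def test_vcf_round_trip(self, tmp_path, toy_vcf):
        m = read_vcf(toy_vcf)
        out = tmp_path / "rt.vcf"
        write_vcf(m, out)
        back = read_vcf(out)
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.genotypes, m.genotypes)
        assert [(s.chrom, s.pos, s.ref_allele, s.alt_alleles) for s in back.sites] == [
            (s.chrom, s.pos, s.ref_allele, s.alt_alleles) for s in m.sites
        ]
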