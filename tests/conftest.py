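import numpy as np
import pytest

from reefadmix.alignment import Alignment
from reefadmix.snp_io import SiteRecord, SnpMatrix

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t150\t.\tC\tT\t10\tPASS\t.\tGT\t0/0\t./.\t0/1
chr1\t500\t.\tG\tGA\t99\tPASS\t.\tGT\t0/0\t0/0\t1/1
chr1\t600\t.\tT\tA,C\t60\tPASS\t.\tGT\t0/0\t1/2\t2/2
chr2\t100\t.\tA\tC\t45\tPASS\t.\tGT\t1/1\t0/1\t./0
"""

#: Hand-decoded genotype states of TOY_VCF (samples x sites); -1 = missing.
TOY_VCF_STATES = np.array(
    [
        [0, 0, 0, 0, 2],
        [1, -1, 0, 1, 1],
        [2, 1, 2, 2, -1],
    ],
    dtype=np.int8,
)


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def empty_vcf(tmp_path):
    header = "\n".join(TOY_VCF.splitlines()[:5]) + "\n"
    path = tmp_path / "empty.vcf"
    path.write_text(header)
    return path


@pytest.fixture
def toy_alignment():
    return Alignment(
        ["t1", "t2", "t3", "t4"],
        ["AAAACCGG", "AAATCCGG", "AATTCAGG", "ACTTNAGT"],
    )


def random_matrix(rng, n_samples=6, n_sites=40):
    """Random SnpMatrix with indels, multiallelics, missing data and hets."""
    sites = []
    pos = 0
    for _ in range(n_sites):
        pos += int(rng.integers(1, 600))
        kind = rng.random()
        if kind < 0.15:  # indel
            ref, alts = "A", ("AT",)
        elif kind < 0.3:  # multiallelic SNP
            ref, alts = "A", ("C", "G")
        else:
            ref, alts = "A", ("G",)
        qual = float(rng.uniform(0, 80))
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        sites.append(SiteRecord(chrom, pos, ref, alts, qual))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    geno = rng.choice(
        np.array([-1, 0, 1, 2], dtype=np.int8),
        size=(n_samples, n_sites),
        p=[0.15, 0.4, 0.15, 0.3],
    )
    ids = [f"s{i}" for i in range(n_samples)]
    return SnpMatrix(ids, sites, geno)
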