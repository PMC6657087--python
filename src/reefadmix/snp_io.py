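"""VCF input, deterministic site filtering, and alignment export.

Genotypes are stored as a compact ``(n_samples, n_sites)`` int8 array:

* ``0`` homozygous reference, ``1`` heterozygous, ``2`` homozygous alternate,
  ``-1`` missing.  Half-calls (``./0``) are normalised to missing and phasing
  separators are ignored before mapping.

The site filters mirror the vcftools options a RADseq practitioner would run
(``--remove-indels --max-missing --thin --mac --minQ``), applied in a fixed,
documented order so the per-rule removal counts are reproducible:
indels -> multiallelic -> minimum quality -> minor-allele count ->
missingness -> thinning.  Multiallelic SNP records are removed because the
downstream four-taxon pattern counting and the 0/1/2 genotype coding both
require biallelic sites.  ``--thin`` keeps a greedy left-to-right set per
chromosome with successive retained positions at least ``thin_bp`` apart.
``max_missing`` follows the vcftools convention: the value is the minimum
fraction of called genotypes (1.0 allows no missing data).  Sites with a
missing QUAL field are removed by the quality rule whenever ``qual_min > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .alignment import Alignment, write_alignment  # re-exported  # noqa: F401

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: IUPAC codes for unordered nucleotide pairs (heterozygote encoding).
IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

FILTER_RULES = ("indel", "multiallelic", "qual", "mac", "missing", "thin")


class VcfParseError(ValueError):
    """The input is not readable as VCF v4.x."""


class SampleNotFoundError(KeyError):
    """A requested sample id is absent from the VCF header."""


@dataclass(frozen=True)
class SiteRecord:
    """One variant record: location, alleles and site quality."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) < 1:
            raise ValueError("ref_allele must be non-empty")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def is_indel(self) -> bool:
        if len(self.ref_allele) != 1:
            return True
        return any(len(a) != 1 or a in "*<" or a.startswith("<") for a in self.alt_alleles)

    @property
    def is_biallelic_snp(self) -> bool:
        return not self.is_indel and len(self.alt_alleles) == 1


@dataclass
class SnpMatrix:
    """Samples x biallelic sites genotype matrix with per-site metadata."""

    sample_ids: list[str]
    sites: list[SiteRecord]
    genotypes: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.sites)} sites)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise SampleNotFoundError(f"sample {sample_id!r} not in matrix") from None

    def take_sites(self, index: np.ndarray) -> "SnpMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpMatrix(
            list(self.sample_ids),
            [self.sites[i] for i in idx],
            self.genotypes[:, idx],
        )


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for the vcftools-style site filters."""

    remove_indels: bool = True
    max_missing: float = 0.5  # minimum call rate, vcftools convention
    thin_bp: int = 300
    mac_min: int = 3
    qual_min: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if self.thin_bp < 0 or self.mac_min < 0 or self.qual_min < 0:
            raise ValueError("thin_bp, mac_min and qual_min must be non-negative")


@dataclass
class FilterReport:
    """Per-rule removal counts; counts sum to n_in - n_out."""

    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in FILTER_RULES]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def _genotype_state(alleles: list[int]) -> int:
    if any(a < 0 for a in alleles):
        return MISSING
    if all(a == 0 for a in alleles):
        return HOM_REF
    if len(set(alleles)) == 1:
        return HOM_ALT
    return HET


def read_vcf(path: str | Path, sample_subset: list[str] | None = None) -> SnpMatrix:
    """Read a VCF v4.x file into a :class:`SnpMatrix`, preserving record order.

    Diploid calls map to the four genotype states; half-calls become missing.
    With ``sample_subset`` only those columns are kept (in the requested
    order); a requested id absent from the header raises
    :class:`SampleNotFoundError` naming the id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
        header_samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfParseError(f"{path}: not readable as VCF ({exc})") from exc

    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise SampleNotFoundError(
                f"sample(s) {missing} not present in VCF header of {path}"
            )
        keep = sample_subset
    else:
        keep = header_samples
    col_of = {s: i for i, s in enumerate(header_samples)}
    take = [col_of[s] for s in keep]

    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    try:
        for rec in vcf:
            alts = tuple(rec.ALT) if rec.ALT else ()
            if not alts:
                continue  # invariant reference block, not a variant record
            qual = None if rec.QUAL is None else float(rec.QUAL)
            sites.append(SiteRecord(rec.CHROM, rec.POS, rec.REF, alts, qual))
            states = np.array(
                [_genotype_state(list(g[:-1])) for g in rec.genotypes], dtype=np.int8
            )
            columns.append(states[take])
    except Exception as exc:
        if isinstance(exc, (ValueError, OSError)):
            raise VcfParseError(f"{path}: malformed record ({exc})") from exc
        raise

    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(keep), 0), dtype=np.int8)
    )
    return SnpMatrix(list(keep), sites, geno)


def _mac(column: np.ndarray) -> int:
    """Minor-allele count over called genotypes only."""
    called = column[column >= 0]
    if called.size == 0:
        return 0
    alt = int(called.sum())  # genotype code == alt-allele dosage
    total = 2 * called.size
    return min(alt, total - alt)


def filter_sites(m: SnpMatrix, spec: FilterSpec) -> tuple[SnpMatrix, FilterReport]:
    """Apply the site filters in the fixed documented order.

    Returns the filtered matrix and a :class:`FilterReport` whose per-rule
    removal counts sum to ``n_in - n_out``.  Empty output is legal.
    """
    n_in = m.n_sites
    alive = np.ones(n_in, dtype=bool)
    removed: dict[str, int] = {}

    def apply(rule: str, fail: np.ndarray) -> None:
        kill = alive & fail
        removed[rule] = int(kill.sum())
        alive[kill] = False

    if spec.remove_indels:
        apply("indel", np.array([s.is_indel for s in m.sites], dtype=bool))
    else:
        removed["indel"] = 0
    apply(
        "multiallelic",
        np.array([len(s.alt_alleles) > 1 for s in m.sites], dtype=bool),
    )
    qual_fail = np.array(
        [
            (s.qual is None and spec.qual_min > 0)
            or (s.qual is not None and s.qual < spec.qual_min)
            for s in m.sites
        ],
        dtype=bool,
    )
    apply("qual", qual_fail)
    macs = np.array([_mac(m.genotypes[:, j]) for j in range(n_in)])
    apply("mac", macs < spec.mac_min)
    call_rate = (m.genotypes >= 0).mean(axis=0) if m.n_samples else np.zeros(n_in)
    apply("missing", call_rate < spec.max_missing)

    # Greedy per-chromosome thinning over the surviving, position-ordered sites.
    thin_fail = np.zeros(n_in, dtype=bool)
    if spec.thin_bp > 0:
        last_kept: dict[str, int] = {}
        for j in np.flatnonzero(alive):
            s = m.sites[j]
            prev = last_kept.get(s.chrom)
            if prev is not None and s.pos - prev < spec.thin_bp:
                thin_fail[j] = True
            else:
                last_kept[s.chrom] = s.pos
    apply("thin", thin_fail)

    out = m.take_sites(alive)
    return out, FilterReport(n_in=n_in, n_out=out.n_sites, removed=removed)


def to_alignment(
    m: SnpMatrix,
    min_samples_locus: int = 10,
    het: str = "iupac",
    encoding: str = "nucleotide",
) -> Alignment:
    """Convert a biallelic SnpMatrix to an alignment.

    Sites with fewer than ``min_samples_locus`` called genotypes are dropped.
    ``encoding='nucleotide'`` writes REF/ALT bases with heterozygotes as IUPAC
    ambiguity codes (``het='iupac'``) or as the site's majority allele
    (``het='major'``, ties resolved to REF); missing is ``N``.
    ``encoding='binary'`` writes the 0/1/2 genotype codes with ``?`` missing.
    """
    if min_samples_locus > m.n_samples:
        raise ValueError(
            f"min_samples_locus={min_samples_locus} exceeds sample count {m.n_samples}"
        )
    if het not in ("iupac", "major"):
        raise ValueError("het must be 'iupac' or 'major'")
    if encoding not in ("nucleotide", "binary"):
        raise ValueError("encoding must be 'nucleotide' or 'binary'")
    non_biallelic = [s for s in m.sites if not s.is_biallelic_snp]
    if encoding == "nucleotide" and non_biallelic:
        raise ValueError(
            f"{len(non_biallelic)} sites are not biallelic SNPs; filter first"
        )

    called = (m.genotypes >= 0).sum(axis=0)
    keep = np.flatnonzero(called >= min_samples_locus)
    cols: list[list[str]] = []
    for j in keep:
        g = m.genotypes[:, j]
        if encoding == "binary":
            cols.append(["?" if x < 0 else str(int(x)) for x in g])
            continue
        ref = m.sites[j].ref_allele.upper()
        alt = m.sites[j].alt_alleles[0].upper()
        if het == "iupac":
            het_char = IUPAC.get(frozenset((ref, alt)), "N")
        else:
            alt_copies = int(g[g >= 0].sum())
            het_char = alt if alt_copies > 2 * (g >= 0).sum() - alt_copies else ref
        lut = {MISSING: "N", HOM_REF: ref, HET: het_char, HOM_ALT: alt}
        cols.append([lut[int(x)] for x in g])

    seqs = ["".join(col[i] for col in cols) for i in range(m.n_samples)]
    return Alignment(list(m.sample_ids), seqs)


def write_vcf(m: SnpMatrix, path: str | Path) -> Path:
    """Serialise a SnpMatrix as an uncompressed VCF v4.2 text file."""
    path = Path(path)
    gt = {MISSING: "./.", HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}
    contigs = sorted({s.chrom for s in m.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=reefadmix\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        for j, s in enumerate(m.sites):
            qual = "." if s.qual is None else f"{s.qual:g}"
            calls = "\t".join(gt[int(x)] for x in m.genotypes[:, j])
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{','.join(s.alt_alleles)}\t"
                f"{qual}\tPASS\t.\tGT\t{calls}\n"
            )
    return path
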