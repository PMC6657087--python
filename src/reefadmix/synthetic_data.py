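"""Seeded generator of four-taxon biallelic SNP data with ILS and admixture.

The generator emulates the signal the ABBA/BABA test is built to detect.
Each site is drawn independently from a finite outcome space:

1. *Admixture pulse.*  With probability ``gamma`` the recipient lineage is
   re-parented into the donor's population, so the effective quartet tree for
   that site has the donor and recipient as sisters; otherwise the species
   tree (((P1,P2),P3),O) applies.
2. *Incomplete lineage sorting.*  The sister pair coalesces inside the
   internal branch of length ``internal_branch_T`` (coalescent units) with
   probability 1 - exp(-T).  Otherwise the coalescence is deep and the three
   possible ingroup pairings are equiprobable.
3. *Mutation.*  A single mutation (infinite sites) is placed on one of the
   six branches of the realised rooted genealogy — four external, the branch
   above the first ingroup coalescence, and the branch above the second —
   uniformly per branch count by default, or proportionally to schematic
   expected branch lengths with ``mutation_weighting='length'``.  Every
   placement yields a polymorphic site.

Because the outcome space is finite, :func:`pattern_probabilities` gives the
exact site-pattern distribution of this scheme in closed form, so every
stochastic property of the generator can be checked against an enumeration
oracle rather than another simulator.

Each lineage carries ``samples_per_lineage`` diploid samples (one by
default, matching single-sample lineages); genotypes are homozygous for the
lineage allele, then perturbed to heterozygous with ``het_rate`` (to
exercise strict-mode exclusions) and masked with ``missing_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .snp_io import SiteRecord, SnpMatrix, write_vcf

LINEAGES = ("P1", "P2", "P3", "O")
#: Unordered ingroup pairings, indexed by the order used throughout.
PAIRS = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))
_BASES = "ACGT"

ABBA = (0, 1, 1, 0)
BABA = (1, 0, 1, 0)


@dataclass(frozen=True)
class SimulationConfig:
    n_sites: int = 10_000
    internal_branch_T: float = 1.0
    gamma: float = 0.0
    admix_pair: tuple[str, str] = ("P1", "P3")  # (donor, recipient)
    missing_rate: float = 0.05
    het_rate: float = 0.05
    qual_range: tuple[float, float] = (30.0, 90.0)
    seed: int = 0
    samples_per_lineage: int = 1
    pos_spacing: int = 500
    mutation_weighting: str = "count"  # or "length"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.internal_branch_T < 0:
            raise ValueError("internal_branch_T must be non-negative")
        for name in ("gamma", "missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        d, r = self.admix_pair
        if d == r or d not in LINEAGES[:3] or r not in LINEAGES[:3]:
            raise ValueError("admix_pair must be two distinct ingroup lineages")
        lo, hi = self.qual_range
        if not (0 < lo <= hi):
            raise ValueError("qual_range must be a positive interval")
        if self.samples_per_lineage < 1:
            raise ValueError("samples_per_lineage must be >= 1")
        if self.mutation_weighting not in ("count", "length"):
            raise ValueError("mutation_weighting must be 'count' or 'length'")


def _pair_index(a: str, b: str) -> int:
    key = frozenset((a, b))
    for i, p in enumerate(PAIRS):
        if frozenset(p) == key:
            return i
    raise ValueError(f"not an ingroup pair: {(a, b)}")


def _pattern_table() -> np.ndarray:
    """(pair_idx, branch) -> derived-state pattern over (P1, P2, P3, O).

    Branches of the realised genealogy (((a,b),c),O): 0..3 external in the
    order a, b, c, O; 4 the branch above the (a,b) coalescence; 5 the branch
    above the (a,b,c) coalescence.
    """
    table = np.zeros((3, 6, 4), dtype=np.int8)
    for k, (a, b) in enumerate(PAIRS):
        (c,) = [x for x in LINEAGES[:3] if x not in (a, b)]
        derived_sets = [{a}, {b}, {c}, {"O"}, {a, b}, {a, b, c}]
        for br, ds in enumerate(derived_sets):
            for j, lin in enumerate(LINEAGES):
                table[k, br, j] = int(lin in ds)
    return table


_PATTERNS = _pattern_table()


def _branch_weights(shallow: bool, T: float, weighting: str) -> np.ndarray:
    """Mutation placement weights over the six branches of one genealogy."""
    if weighting == "count" or (shallow and T <= 0):
        return np.full(6, 1 / 6)
    t_ab, t_abc, t_root = 1.0, 1.0 + T, 2.0 + T
    if shallow:
        e = math.exp(-T)
        tau1 = t_ab + (1.0 - (T + 1.0) * e) / (1.0 - e)  # E[Exp(1) | < T]
        tau2 = t_abc + 1.0
    else:
        tau1 = t_abc + 1.0 / 3.0
        tau2 = tau1 + 1.0
    tau3 = max(tau2, t_root) + 1.0
    lengths = np.array([tau1, tau1, tau2, tau3, tau2 - tau1, tau3 - tau2])
    return lengths / lengths.sum()


def pattern_probabilities(cfg: SimulationConfig) -> dict[tuple[int, ...], float]:
    """Exact site-pattern distribution of the generative scheme.

    Enumerates admixture state x coalescence category x mutation branch and
    returns probabilities keyed by the (P1, P2, P3, O) derived-state tuple.
    """
    T = cfg.internal_branch_T
    p_shallow = 1.0 - math.exp(-T)
    sis_admix = _pair_index(*cfg.admix_pair)
    probs: dict[tuple[int, ...], float] = {}
    for admixed, p_adm in ((False, 1.0 - cfg.gamma), (True, cfg.gamma)):
        if p_adm == 0.0:
            continue
        sisters = sis_admix if admixed else 0
        categories = [(sisters, p_shallow, True)]
        categories += [(k, (1.0 - p_shallow) / 3.0, False) for k in range(3)]
        for pair_idx, p_cat, shallow in categories:
            if p_cat == 0.0:
                continue
            weights = _branch_weights(shallow, T, cfg.mutation_weighting)
            for br in range(6):
                pat = tuple(int(x) for x in _PATTERNS[pair_idx, br])
                probs[pat] = probs.get(pat, 0.0) + p_adm * p_cat * weights[br]
    return probs


def expected_d(cfg: SimulationConfig) -> float:
    """Expected D over the ABBA/BABA subspace of the exact distribution."""
    probs = pattern_probabilities(cfg)
    pa, pb = probs.get(ABBA, 0.0), probs.get(BABA, 0.0)
    if pa + pb == 0:
        return 0.0
    return (pa - pb) / (pa + pb)


def sample_ids(cfg: SimulationConfig) -> list[str]:
    if cfg.samples_per_lineage == 1:
        return list(LINEAGES)
    return [
        f"{lin}_{i + 1}" for lin in LINEAGES for i in range(cfg.samples_per_lineage)
    ]


def popmap(cfg: SimulationConfig) -> dict[str, str]:
    """Sample -> lineage assignment for the generated matrix."""
    if cfg.samples_per_lineage == 1:
        return {lin: lin for lin in LINEAGES}
    return {
        f"{lin}_{i + 1}": lin
        for lin in LINEAGES
        for i in range(cfg.samples_per_lineage)
    }


def simulate_site_patterns(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, SnpMatrix]:
    """Draw per-site patterns and assemble the corresponding SnpMatrix.

    Returns ``(patterns, matrix)`` where ``patterns`` is the noise-free
    (n_sites, 4) derived-state array over (P1, P2, P3, O) and ``matrix``
    carries the diploid genotypes after heterozygote injection and masking,
    plus per-site REF/ALT alleles, positions and quality values.  Identical
    seed and config give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    T = cfg.internal_branch_T
    p_shallow = 1.0 - math.exp(-T)
    sis_admix = _pair_index(*cfg.admix_pair)

    admixed = rng.random(n) < cfg.gamma
    shallow = rng.random(n) < p_shallow
    deep_pick = rng.integers(0, 3, size=n)
    sisters = np.where(admixed, sis_admix, 0)
    pair_idx = np.where(shallow, sisters, deep_pick)

    if cfg.mutation_weighting == "count":
        branch = rng.integers(0, 6, size=n)
    else:
        w_sh = _branch_weights(True, T, "length")
        w_dp = _branch_weights(False, T, "length")
        branch = np.where(
            shallow,
            rng.choice(6, size=n, p=w_sh),
            rng.choice(6, size=n, p=w_dp),
        )

    patterns = _PATTERNS[pair_idx, branch]  # (n, 4)

    spl = cfg.samples_per_lineage
    geno = np.repeat(2 * patterns.T.astype(np.int8), spl, axis=0)  # samples x sites
    het_mask = rng.random(geno.shape) < cfg.het_rate
    miss_mask = rng.random(geno.shape) < cfg.missing_rate
    geno = geno.copy()
    geno[het_mask] = 1
    geno[miss_mask] = -1

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    quals = rng.uniform(cfg.qual_range[0], cfg.qual_range[1], size=n)
    sites = [
        SiteRecord(
            "sim1",
            1 + i * cfg.pos_spacing,
            _BASES[ref_idx[i]],
            (_BASES[alt_idx[i]],),
            float(quals[i]),
        )
        for i in range(n)
    ]
    matrix = SnpMatrix(sample_ids(cfg), sites, geno)
    return patterns, matrix


def emit_vcf(m: SnpMatrix, path) -> None:
    """Write the simulated matrix as uncompressed VCF v4.2."""
    write_vcf(m, path)


def emit_popmap(assignment: dict[str, str], path) -> None:
    """Write a sample -> taxon map as two-column TSV."""
    with open(path, "w") as fh:
        for sample, taxon in assignment.items():
            fh.write(f"{sample}\t{taxon}\n")
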