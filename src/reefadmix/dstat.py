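"""Patterson's D (ABBA/BABA) introgression tests on four-taxon hypotheses.

For a quartet with gene-tree shape (((P1, P2), P3), O) and the outgroup
defining the ancestral allele "A", two site patterns are phylogenetically
incongruent: ABBA (P2 and P3 share the derived allele "B") and BABA (P1 and
P3 share it).  Under incomplete lineage sorting alone both patterns are
equally probable, so

    D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA)

is centred on zero; a significant imbalance indicates gene flow involving P3
(with P1 when BABA is in excess, with P2 when ABBA is).  Significance is a
Pearson chi-square goodness-of-fit test of the 50:50 split, df = 1, no
continuity correction; note the identity chi2 = D^2 * (n_ABBA + n_BABA).
A block-jackknife alternative for linked sites is available via
``d_statistic_jackknife``.

Two counting modes are provided. ``strict`` uses only sites where all four
samples are called and homozygous (the outgroup call polarises the site) and
increments integer counts.  ``frequency`` accumulates fractional weights
(1-f1)*f2*f3*(1-f4) and f1*(1-f2)*f3*(1-f4), with f_i the per-sample
derived-allele dosage / 2, which keeps heterozygous information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .snp_io import SnpMatrix

DIRECTION_NONE = "none"


class UndefinedDError(ValueError):
    """n_ABBA + n_BABA = 0: D is undefined."""


@dataclass(frozen=True)
class QuartetHypothesis:
    """One (((P1,P2),P3),O) donor/recipient configuration."""

    id: str
    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        ids = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(ids)) != 4:
            raise ValueError(f"hypothesis {self.id}: the four sample ids must differ")


@dataclass
class SitePatternCounts:
    n_abba: float
    n_baba: float
    n_sites_used: int
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_abba < 0 or self.n_baba < 0:
            raise ValueError("pattern counts must be non-negative")
        if self.n_abba + self.n_baba > self.n_sites_used + 1e-9:
            raise ValueError("n_abba + n_baba cannot exceed n_sites_used")


@dataclass
class DstatResult:
    hypothesis: QuartetHypothesis
    counts: SitePatternCounts
    d: float
    chi2: float
    p_value: float
    alpha: float
    direction: str  # none | "13" | "23"


def enumerate_hypotheses(
    ingroup: list[str], outgroup: str, focal_p3: str | None = None
) -> list[QuartetHypothesis]:
    """All (((P1,P2),P3),O) hypotheses over an ingroup and fixed outgroup.

    Every ingroup member (or only ``focal_p3``) serves as the putative
    recipient/donor P3; each unordered pair from the remainder forms {P1,P2}.
    For k ingroup taxa this yields k * C(k-1, 2) hypotheses (30 for k = 5).
    Ordering is deterministic: P3 in ingroup-list order, pairs lexicographic.
    """
    if len(ingroup) < 3:
        raise ValueError("need at least 3 ingroup samples")
    if len(set(ingroup)) != len(ingroup):
        raise ValueError("ingroup ids must be unique")
    if outgroup in ingroup:
        raise ValueError(f"outgroup {outgroup!r} must not be in the ingroup")
    if focal_p3 is not None and focal_p3 not in ingroup:
        raise ValueError(f"focal_p3 {focal_p3!r} not in ingroup")
    p3_choices = [focal_p3] if focal_p3 is not None else list(ingroup)
    out: list[QuartetHypothesis] = []
    n = 0
    for p3 in p3_choices:
        rest = sorted(x for x in ingroup if x != p3)
        for p1, p2 in itertools.combinations(rest, 2):
            n += 1
            out.append(QuartetHypothesis(f"H{n}", p1, p2, p3, outgroup))
    return out


def count_patterns(
    m: SnpMatrix, h: QuartetHypothesis, mode: str = "strict"
) -> SitePatternCounts:
    """Count ABBA/BABA site patterns for one hypothesis.

    The ancestral state at each site is the outgroup allele.  Exclusion
    reasons (missing genotype; heterozygous call in strict mode) are tallied.
    """
    if mode not in ("strict", "frequency"):
        raise ValueError("mode must be 'strict' or 'frequency'")
    idx = [m.sample_index(s) for s in (h.p1, h.p2, h.p3, h.outgroup)]
    g = m.genotypes[idx, :].astype(np.int16)  # 4 x n_sites
    missing = (g < 0).any(axis=0)
    excluded = {"missing": int(missing.sum())}

    if mode == "strict":
        het = (~missing) & (g == 1).any(axis=0)
        excluded["heterozygous"] = int(het.sum())
        used = ~missing & ~het
        derived = g[:, used] != g[3, used]  # polarised against the outgroup
        b1, b2, b3 = derived[0], derived[1], derived[2]
        n_abba = int((~b1 & b2 & b3).sum())
        n_baba = int((b1 & ~b2 & b3).sum())
        return SitePatternCounts(n_abba, n_baba, int(used.sum()), excluded)

    used = ~missing
    f = g[:, used] / 2.0  # alternate-allele dosage frequencies
    f1, f2, f3, f4 = f
    n_abba = float(((1 - f1) * f2 * f3 * (1 - f4)).sum())
    n_baba = float((f1 * (1 - f2) * f3 * (1 - f4)).sum())
    return SitePatternCounts(n_abba, n_baba, int(used.sum()), excluded)


def d_statistic(c: SitePatternCounts) -> tuple[float, float, float]:
    """Patterson's D with Pearson chi-square significance (df=1).

    Returns ``(d, chi2, p_value)`` at full precision; use :func:`format_d`
    and :func:`format_p` for the reporting convention (3 decimals; p below
    1e-3 in 2-significant-digit scientific notation).
    """
    total = c.n_abba + c.n_baba
    if total == 0:
        raise UndefinedDError("n_abba + n_baba = 0: D undefined")
    d = (c.n_abba - c.n_baba) / total
    chi2 = (c.n_abba - c.n_baba) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    return float(d), float(chi2), p


def d_statistic_jackknife(
    c_blocks: list[SitePatternCounts],
) -> tuple[float, float, float]:
    """Block-jackknife D significance for linked sites (secondary option).

    Takes per-block pattern counts, computes the overall D, a delete-one
    jackknife standard error, and a two-sided normal-approximation p-value.
    """
    if len(c_blocks) < 2:
        raise ValueError("need at least 2 blocks")
    tot_a = sum(b.n_abba for b in c_blocks)
    tot_b = sum(b.n_baba for b in c_blocks)
    if tot_a + tot_b == 0:
        raise UndefinedDError("no ABBA/BABA sites in any block")
    d_all = (tot_a - tot_b) / (tot_a + tot_b)
    n = len(c_blocks)
    d_del = np.empty(n)
    for i, blk in enumerate(c_blocks):
        a = tot_a - blk.n_abba
        b = tot_b - blk.n_baba
        d_del[i] = (a - b) / (a + b) if a + b > 0 else d_all
    se = float(np.sqrt((n - 1) / n * ((d_del - d_del.mean()) ** 2).sum()))
    if se == 0:
        return float(d_all), float("inf") if d_all else 0.0, float(d_all == 0)
    z = d_all / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(d_all), float(z), p


def call_direction(d: float, p_value: float, alpha: float = 0.01) -> str:
    """Direction of gene flow at significance level alpha.

    BABA excess (d < 0) implicates P1 and P3 ("13"); ABBA excess (d > 0)
    implicates P2 and P3 ("23").  A tie (d = 0) never yields a call.
    """
    if not np.isfinite(p_value):
        raise ValueError("p_value must be finite")
    if p_value < alpha and d < 0:
        return "13"
    if p_value < alpha and d > 0:
        return "23"
    return DIRECTION_NONE


def format_d(d: float) -> str:
    return f"{d:.3f}"


def format_p(p: float) -> str:
    """3 decimals, switching to 2-significant-digit scientific below 1e-3."""
    if p < 1e-3:
        return f"{p:.1E}"
    return f"{p:.3f}"


def run_all(
    source: SnpMatrix | pd.DataFrame,
    hypotheses: list[QuartetHypothesis] | None = None,
    alpha: float = 0.01,
    mode: str = "strict",
) -> pd.DataFrame:
    """One DstatResult row per hypothesis, in enumeration order.

    ``source`` is either a :class:`SnpMatrix` (patterns are counted for each
    hypothesis) or a DataFrame with columns ``id, p1, p2, p3, outgroup,
    n_abba, n_baba`` (e.g. the packaged published-count fixture), in which
    case D, chi2, p and direction are regenerated from the counts.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    if isinstance(source, pd.DataFrame):
        for _, r in source.iterrows():
            c = SitePatternCounts(
                float(r["n_abba"]),
                float(r["n_baba"]),
                int(r["n_abba"] + r["n_baba"]),
            )
            d, chi2, p = d_statistic(c)
            rows.append(
                {
                    "id": r["id"],
                    "p1": r["p1"],
                    "p2": r["p2"],
                    "p3": r["p3"],
                    "outgroup": r["outgroup"],
                    "n_abba": r["n_abba"],
                    "n_baba": r["n_baba"],
                    "d": d,
                    "chi2": chi2,
                    "p_value": p,
                    "direction": call_direction(d, p, alpha),
                }
            )
    else:
        if hypotheses is None:
            raise ValueError("hypotheses are required with a SnpMatrix source")
        for h in hypotheses:
            c = count_patterns(source, h, mode=mode)
            d, chi2, p = d_statistic(c)
            rows.append(
                {
                    "id": h.id,
                    "p1": h.p1,
                    "p2": h.p2,
                    "p3": h.p3,
                    "outgroup": h.outgroup,
                    "n_abba": c.n_abba,
                    "n_baba": c.n_baba,
                    "d": d,
                    "chi2": chi2,
                    "p_value": p,
                    "direction": call_direction(d, p, alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "p1",
            "p2",
            "p3",
            "outgroup",
            "n_abba",
            "n_baba",
            "d",
            "chi2",
            "p_value",
            "direction",
        ],
    )
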