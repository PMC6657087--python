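"""Per-taxon base composition and an among-lineage homogeneity test.

Nonstationary base composition across lineages can mislead phylogenetic
inference and divergence dating.  This module provides the classical
screening diagnostic: a taxa x {A,C,G,T} contingency table of unambiguous
site counts and a Pearson chi-square test of the hypothesis that every
lineage shares the pooled base frequencies, optionally backed by a
parametric (multinomial) simulation null.  It is a tree-free analogue of the
tree-aware posterior-predictive homogeneity tests used by Bayesian
nonstationary-model software; those require a full MCMC engine and are out
of scope here.

Degrees of freedom are kept at the full 4-state dimension,
df = (n_taxa - 1) * 3.  A base absent from every taxon gives zero-expected
cells; with pooled expectations such a column is identically zero, so it is
dropped from the chi-square sum (contributing 0) and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment

BASES = ("A", "C", "G", "T")


@dataclass
class HomogeneityResult:
    chi2: float
    df: int
    p_analytic: float
    p_simulated: float | None
    n_sims: int
    dropped_bases: list[str] = field(default_factory=list)
    zero_total_taxa: list[str] = field(default_factory=list)


def base_composition(a: Alignment) -> pd.DataFrame:
    """Counts of A, C, G, T per taxon over unambiguous sites.

    Gaps, Ns and IUPAC ambiguity codes are excluded.  Taxa with zero
    unambiguous sites keep an all-zero row (flagged downstream).
    """
    if a.n_taxa == 0 or a.n_sites == 0:
        raise ValueError("alignment must be non-empty")
    rows = []
    for seq in a.seqs:
        s = seq.upper()
        rows.append([s.count(b) for b in BASES])
    return pd.DataFrame(rows, index=list(a.ids), columns=list(BASES))


def _chi2_pooled(counts: np.ndarray) -> float:
    """Pearson chi-square of rows against pooled column frequencies."""
    row_tot = counts.sum(axis=1, keepdims=True)
    col_freq = counts.sum(axis=0) / counts.sum()
    expected = row_tot * col_freq
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def homogeneity_test(
    table: pd.DataFrame, n_sims: int = 0, seed: int | None = None
) -> HomogeneityResult:
    """Chi-square test of among-taxon composition homogeneity.

    With ``n_sims > 0`` a simulated p-value is added: each taxon's counts are
    redrawn from a multinomial with the pooled base frequencies and the same
    row total, and ``p_simulated`` is the fraction of resamples whose
    chi-square (recomputed the same way) reaches the observed one.
    """
    counts = table[list(BASES)].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero_taxa = [str(t) for t, n in zip(table.index, totals) if n == 0]
    keep = totals > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 taxa with positive totals")
    counts = counts[keep]
    n_taxa = counts.shape[0]

    pooled = counts.sum(axis=0)
    dropped = [b for b, c in zip(BASES, pooled) if c == 0]
    chi2 = _chi2_pooled(counts)
    df = (n_taxa - 1) * (len(BASES) - 1)
    p_analytic = float(stats.chi2.sf(chi2, df=df))

    p_sim = None
    if n_sims > 0:
        rng = np.random.default_rng(seed)
        freq = pooled / pooled.sum()
        hits = 0
        for _ in range(n_sims):
            sim = np.stack(
                [rng.multinomial(int(t), freq) for t in counts.sum(axis=1)]
            ).astype(float)
            if _chi2_pooled(sim) >= chi2:
                hits += 1
        p_sim = hits / n_sims
    return HomogeneityResult(
        chi2=chi2,
        df=df,
        p_analytic=p_analytic,
        p_simulated=p_sim,
        n_sims=n_sims,
        dropped_bases=dropped,
        zero_total_taxa=zero_taxa,
    )
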