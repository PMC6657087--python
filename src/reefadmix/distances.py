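"""Uncorrected p-distances, group summaries and site-bootstrap errors.

The p-distance between two sequences is the proportion of differing sites
among sites where both taxa carry an unambiguous base (pairwise deletion;
IUPAC ambiguity codes, ``N`` and gaps are treated as missing).  Group
summaries follow the conventions of classical distance software: the within-
group distance is the mean over unordered intra-group pairs, the between-
group distance the mean over inter-group pairs, and the net between-group
distance

    d_net(A, B) = d_between(A, B) - (d_within(A) + d_within(B)) / 2

removes the within-group polymorphism component.  Standard errors come from
resampling alignment columns with replacement (the usual site bootstrap);
the bootstrap standard deviation uses the population (n) denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .alignment import Alignment

_UNAMBIGUOUS = frozenset("ACGT")


class NoComparableSitesError(ValueError):
    """All sites are missing/ambiguous in at least one of the two taxa."""


@dataclass
class DistanceResult:
    estimate: float
    se: float | None
    n_reps: int
    kind: str  # pairwise | within | between | net

    def __post_init__(self) -> None:
        if self.se is not None and self.n_reps < 2:
            raise ValueError("se requires n_reps >= 2")


@dataclass
class GroupDistances:
    """Within-, between- and net distances; undefined entries are None."""

    within: dict[str, float | None]
    between: dict[tuple[str, str], float]
    net: dict[tuple[str, str], float | None]


def p_distance(a: Alignment, t1: str, t2: str) -> float:
    """Proportion of differing sites between two taxa under pairwise deletion."""
    s1 = a.sequence(t1).upper()
    s2 = a.sequence(t2).upper()
    comparable = diffs = 0
    for c1, c2 in zip(s1, s2):
        if c1 in _UNAMBIGUOUS and c2 in _UNAMBIGUOUS:
            comparable += 1
            if c1 != c2:
                diffs += 1
    if comparable == 0:
        raise NoComparableSitesError(
            f"no comparable sites between {t1!r} and {t2!r}"
        )
    return diffs / comparable


def _check_groups(a: Alignment, groups: Mapping[str, str]) -> dict[str, list[str]]:
    missing = sorted(set(a.ids) - set(groups))
    extra = sorted(set(groups) - set(a.ids))
    if missing:
        raise ValueError(f"taxa without group assignment: {missing}")
    if extra:
        raise ValueError(f"assigned taxa absent from alignment: {extra}")
    members: dict[str, list[str]] = {}
    for tid in a.ids:  # alignment order keeps output deterministic
        members.setdefault(groups[tid], []).append(tid)
    return members


def group_distances(a: Alignment, groups: Mapping[str, str]) -> GroupDistances:
    """Mean within-, between- and net distances for a taxon->group mapping.

    A singleton group has no intra-group pair, so its within distance (and any
    net distance involving it) is reported as None.
    """
    members = _check_groups(a, groups)
    within: dict[str, float | None] = {}
    for g, taxa in members.items():
        pairs = list(itertools.combinations(taxa, 2))
        within[g] = (
            float(np.mean([p_distance(a, x, y) for x, y in pairs])) if pairs else None
        )
    between: dict[tuple[str, str], float] = {}
    net: dict[tuple[str, str], float | None] = {}
    for g1, g2 in itertools.combinations(members, 2):
        d_b = float(
            np.mean(
                [p_distance(a, x, y) for x in members[g1] for y in members[g2]]
            )
        )
        between[(g1, g2)] = d_b
        if within[g1] is None or within[g2] is None:
            net[(g1, g2)] = None
        else:
            net[(g1, g2)] = d_b - (within[g1] + within[g2]) / 2.0
    return GroupDistances(within=within, between=between, net=net)


def bootstrap_se(
    a: Alignment,
    statistic: Callable[[Alignment], float],
    n_reps: int = 500,
    seed: int | None = None,
    kind: str = "pairwise",
) -> DistanceResult:
    """Site-bootstrap standard error of any alignment statistic.

    Columns are resampled with replacement ``n_reps`` times; the reported
    ``se`` is the standard deviation of the replicate statistics (population
    denominator).  Identical seed and input give identical output.
    """
    if a.n_sites < 1:
        raise ValueError("alignment must have at least one column")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(a))
    reps = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, a.n_sites, size=a.n_sites)
        reps[r] = statistic(a.take_columns(idx))
    return DistanceResult(
        estimate=estimate, se=float(reps.std(ddof=0)), n_reps=n_reps, kind=kind
    )
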