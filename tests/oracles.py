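"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives its result with plain Python loops and its own
reading of the rule definitions, deliberately sharing no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math


def oracle_filter(matrix, spec):
    """Site-by-site re-application of each filter rule; returns kept indices."""
    kept = list(range(len(matrix.sites)))

    def is_indel(s):
        return len(s.ref_allele) != 1 or any(len(a) != 1 for a in s.alt_alleles)

    if spec.remove_indels:
        kept = [j for j in kept if not is_indel(matrix.sites[j])]
    kept = [j for j in kept if len(matrix.sites[j].alt_alleles) == 1]
    kept = [
        j
        for j in kept
        if matrix.sites[j].qual is not None and matrix.sites[j].qual >= spec.qual_min
        or (matrix.sites[j].qual is None and spec.qual_min == 0)
    ]

    def mac(j):
        calls = [int(g) for g in matrix.genotypes[:, j] if g >= 0]
        if not calls:
            return 0
        alt = sum(calls)
        return min(alt, 2 * len(calls) - alt)

    kept = [j for j in kept if mac(j) >= spec.mac_min]

    def call_rate(j):
        col = matrix.genotypes[:, j]
        return sum(1 for g in col if g >= 0) / len(col)

    kept = [j for j in kept if call_rate(j) >= spec.max_missing]

    if spec.thin_bp > 0:
        thinned = []
        last = {}
        for j in kept:
            s = matrix.sites[j]
            if s.chrom not in last or s.pos - last[s.chrom] >= spec.thin_bp:
                thinned.append(j)
                last[s.chrom] = s.pos
        kept = thinned
    return kept


def oracle_count_patterns(matrix, p1, p2, p3, outgroup):
    """Strict-mode ABBA/BABA counting with an explicit per-site loop."""
    rows = [matrix.sample_ids.index(s) for s in (p1, p2, p3, outgroup)]
    n_abba = n_baba = n_used = 0
    for j in range(len(matrix.sites)):
        g = [int(matrix.genotypes[r, j]) for r in rows]
        if any(x < 0 for x in g) or any(x == 1 for x in g):
            continue
        n_used += 1
        anc = g[3]
        states = ["A" if x == anc else "B" for x in g[:3]]
        if states == ["A", "B", "B"]:
            n_abba += 1
        elif states == ["B", "A", "B"]:
            n_baba += 1
    return n_abba, n_baba, n_used


def oracle_group_distances(alignment, groups):
    """Pair-by-pair p-distance means with explicit loops."""

    def pdist(t1, t2):
        s1 = alignment.sequence(t1).upper()
        s2 = alignment.sequence(t2).upper()
        comp = diff = 0
        for a, b in zip(s1, s2):
            if a in "ACGT" and b in "ACGT":
                comp += 1
                diff += a != b
        return diff / comp

    members = {}
    for t in alignment.ids:
        members.setdefault(groups[t], []).append(t)
    within = {}
    for g, taxa in members.items():
        pairs = list(itertools.combinations(taxa, 2))
        within[g] = sum(pdist(a, b) for a, b in pairs) / len(pairs) if pairs else None
    between, net = {}, {}
    for g1, g2 in itertools.combinations(members, 2):
        vals = [pdist(a, b) for a in members[g1] for b in members[g2]]
        between[(g1, g2)] = sum(vals) / len(vals)
        if within[g1] is None or within[g2] is None:
            net[(g1, g2)] = None
        else:
            net[(g1, g2)] = between[(g1, g2)] - (within[g1] + within[g2]) / 2
    return within, between, net


def oracle_pattern_probabilities(T, gamma, donor, recipient):
    """Exact site-pattern distribution of the generative scheme, re-derived.

    Enumerates the same outcome space as the generator but is written
    independently: admixture state, shallow/deep coalescence, realised pair,
    and uniform mutation placement over the six genealogy branches.
    """
    lineages = ["P1", "P2", "P3", "O"]
    all_pairs = [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]
    p_shallow = 1.0 - math.exp(-T)
    probs = {}
    for admixed, p_adm in ((False, 1 - gamma), (True, gamma)):
        if p_adm == 0:
            continue
        if admixed:
            sisters = tuple(sorted((donor, recipient)))
        else:
            sisters = ("P1", "P2")
        scenarios = [(sisters, p_shallow)]
        for pair in all_pairs:
            scenarios.append((pair, (1 - p_shallow) / 3))
        for (a, b), p_cat in scenarios:
            if p_cat == 0:
                continue
            (c,) = [x for x in ("P1", "P2", "P3") if x not in (a, b)]
            clades = [{a}, {b}, {c}, {"O"}, {a, b}, {a, b, c}]
            for clade in clades:
                pat = tuple(int(x in clade) for x in lineages)
                probs[pat] = probs.get(pat, 0.0) + p_adm * p_cat / 6
    return probs
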