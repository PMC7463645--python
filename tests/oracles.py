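"""Independent brute-force oracles for the population-genetic estimators.

Everything here is written as a literal, loop-by-loop transcription of the
textbook formulas (or outright enumeration), deliberately sharing no code
with :mod:`histstr.popgen`, so agreement between the two routes is evidence
for both.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

Genotype = Tuple[int, int]


def tally_freqs(genotypes: Sequence[Genotype]) -> Dict[int, Fraction]:
    counts: Dict[int, int] = {}
    for a, b in genotypes:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(genotypes)
    return {allele: Fraction(n, total) for allele, n in counts.items()}


def unbiased_he(genotypes: Sequence[Genotype]) -> float:
    """Nei's unbiased expected heterozygosity, exact-fraction arithmetic."""
    n = len(genotypes)
    freqs = tally_freqs(genotypes)
    plain = 1 - sum(p * p for p in freqs.values())
    return float(Fraction(2 * n, 2 * n - 1) * plain)


def rarefied_richness_enumeration(counts: Sequence[int], g: int) -> float:
    """Expected allele count in g gene copies, by full subset enumeration.

    Builds the explicit multiset of gene copies and averages the number of
    distinct alleles over every possible g-subset.
    """
    copies: List[int] = []
    for allele_idx, n in enumerate(counts):
        copies.extend([allele_idx] * n)
    total = Fraction(0)
    n_subsets = 0
    for subset in combinations(range(len(copies)), g):
        total += len({copies[i] for i in subset})
        n_subsets += 1
    return float(total / n_subsets)


def wc_theta(pop_genotypes: Sequence[Sequence[Sequence[Genotype]]]) -> float:
    """Weir & Cockerham's theta, transcribed component by component.

    ``pop_genotypes[locus][pop]`` is the list of genotypes of one population
    at one locus.  Combination over alleles and loci is by ratio of summed
    variance components.
    """
    num = 0.0
    den = 0.0
    for locus_data in pop_genotypes:
        r = len(locus_data)
        n = [len(p) for p in locus_data]
        if min(n) < 1:
            continue
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        alleles = sorted({a for pop in locus_data for g in pop for a in g})
        if len(alleles) < 2:
            continue
        for allele in alleles:
            p = []
            h = []
            for pop in locus_data:
                copies = sum((g[0] == allele) + (g[1] == allele) for g in pop)
                hets = sum(
                    1 for g in pop if g[0] != g[1] and allele in (g[0], g[1])
                )
                p.append(copies / (2 * len(pop)))
                h.append(hets / len(pop))
            pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    if den == 0:
        raise ZeroDivisionError("theta undefined on this fixture")
    return num / den


def jost_d_two_pops(
    per_locus: Sequence[Tuple[Sequence[Genotype], Sequence[Genotype]]]
) -> float:
    """Jost's D for two populations from Nei-Chesser unbiased Hs/Ht.

    ``per_locus`` is a list of (genotypes in pop 1, genotypes in pop 2);
    loci with fewer than two individuals in either population are skipped.
    Multilocus combination averages Hs and Ht across loci.
    """
    hs_list: List[float] = []
    ht_list: List[float] = []
    for geno_a, geno_b in per_locus:
        n1, n2 = len(geno_a), len(geno_b)
        if min(n1, n2) < 2:
            continue
        ntilde = 2.0 / (1.0 / n1 + 1.0 / n2)
        fa = tally_freqs(geno_a)
        fb = tally_freqs(geno_b)
        ho = 0.5 * (
            sum(1 for g in geno_a if g[0] != g[1]) / n1
            + sum(1 for g in geno_b if g[0] != g[1]) / n2
        )
        hs_plug = 1.0 - 0.5 * (
            sum(float(p) ** 2 for p in fa.values())
            + sum(float(p) ** 2 for p in fb.values())
        )
        alleles = set(fa) | set(fb)
        ht_plug = 1.0 - sum(
            (0.5 * (float(fa.get(x, 0)) + float(fb.get(x, 0)))) ** 2 for x in alleles
        )
        hs = (ntilde / (ntilde - 1.0)) * (hs_plug - ho / (2.0 * ntilde))
        ht = ht_plug + hs / (2.0 * ntilde) - ho / (4.0 * ntilde)
        hs_list.append(hs)
        ht_list.append(ht)
    hs = sum(hs_list) / len(hs_list)
    ht = sum(ht_list) / len(ht_list)
    return 2.0 * (ht - hs) / (1.0 - hs)


def allele_sets(matrix_entries, populations, group) -> Dict[str, set]:
    """Observed alleles per locus over a population group, by direct scan."""
    out: Dict[str, set] = {}
    for (sample, locus), pair in matrix_entries.items():
        if pair is None or populations[sample] not in group:
            continue
        out.setdefault(locus, set()).update(pair.alleles)
    return out
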