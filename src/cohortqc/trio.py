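"""Trio-based quality metrics.

Mendelian error rate (MER), de novo and inheritance rates, parental
transmission rate, and singleton stratification by relatedness.  Mendelian
compatibility uses explicit allele-multiset logic so haploid genotypes
(male non-PAR X, chrY) are handled correctly: a male child's single X
allele must be drawable from the mother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Genotype, Pedigree, SmallVariantSite, SVRecord


def mendelian_consistent(child: Genotype, father: Genotype,
                         mother: Genotype) -> bool | None:
    """True if the child genotype can be formed by one allele from each
    parent (or, for a haploid child, one allele from one parent per the
    ploidy of the parents).  Returns None when any member is missing
    (incomplete trio: not evaluable)."""
    if child is None or father is None or mother is None:
        return None
    if len(child) == 2:
        if len(father) >= 1 and len(mother) >= 1:
            for pa, ma in product(father, mother):
                if sorted((pa, ma)) == sorted(child):
                    return True
            return False
        return None
    if len(child) == 1:
        # haploid child (male X non-PAR / Y): X allele comes from the mother
        return child[0] in mother
    return None


@dataclass
class TrioGenotype:
    site_id: str
    child: Genotype
    father: Genotype
    mother: Genotype

    @property
    def complete(self) -> bool:
        return (self.child is not None and self.father is not None
                and self.mother is not None)


def mendelian_error_rate(genotypes: Sequence[Genotype],
                         sample_index: Mapping[str, int],
                         trios: Iterable[tuple[str, str, str]]) -> float | None:
    """MER at one biallelic site: errors / complete trios.

    Trios with any missing member are excluded from the denominator.
    Returns None (undefined, pass-through in filters) when no trio is
    complete.
    """
    errors = complete = 0
    for child, father, mother in trios:
        verdict = mendelian_consistent(
            genotypes[sample_index[child]], genotypes[sample_index[father]],
            genotypes[sample_index[mother]])
        if verdict is None:
            continue
        complete += 1
        if not verdict:
            errors += 1
    if complete == 0:
        return None
    return errors / complete


def site_mer(site: SmallVariantSite, ped: Pedigree,
             sample_order: Sequence[str]) -> float | None:
    idx = {s: i for i, s in enumerate(sample_order)}
    return mendelian_error_rate(site.genotypes, idx, ped.trios)


def _non_ref(gt: Genotype) -> bool:
    return gt is not None and any(a == 1 for a in gt)


@dataclass
class InheritanceReport:
    n_child_variants: int
    n_inherited: int

    @property
    def inheritance_rate(self) -> float:
        return self.n_inherited / self.n_child_variants

    @property
    def de_novo_rate(self) -> float:
        return 1.0 - self.inheritance_rate


def trio_inheritance(child_genotypes: Sequence[Genotype],
                     father_genotypes: Sequence[Genotype],
                     mother_genotypes: Sequence[Genotype]) -> InheritanceReport:
    """Child inheritance rate = fraction of the child's non-reference
    variants carried (non-reference) by at least one parent; de novo rate
    is its complement."""
    if len(child_genotypes) != len(father_genotypes) or \
            len(child_genotypes) != len(mother_genotypes):
        raise ValueError("genotype vectors must be parallel over sites")
    n_child = n_inherited = 0
    for c, f, m in zip(child_genotypes, father_genotypes, mother_genotypes):
        if not _non_ref(c):
            continue
        n_child += 1
        if _non_ref(f) or _non_ref(m):
            n_inherited += 1
    if n_child == 0:
        return InheritanceReport(0, 0)
    return InheritanceReport(n_child, n_inherited)


def cohort_inheritance(sites: Sequence[SmallVariantSite] | Sequence[SVRecord],
                       ped: Pedigree, sample_order: Sequence[str]
                       ) -> dict[str, InheritanceReport]:
    """Per-child inheritance/de novo report over a cohort of records."""
    idx = {s: i for i, s in enumerate(sample_order)}
    out: dict[str, InheritanceReport] = {}
    for child, father, mother in ped.trios:
        c = [s.genotypes[idx[child]] for s in sites]
        f = [s.genotypes[idx[father]] for s in sites]
        m = [s.genotypes[idx[mother]] for s in sites]
        out[child] = trio_inheritance(c, f, m)
    return out


def _het(gt: Genotype) -> bool:
    return gt is not None and len(gt) == 2 and sorted(gt) == [0, 1]


def _hom_ref(gt: Genotype) -> bool:
    return gt is not None and all(a == 0 for a in gt)


def parental_transmission(sites: Sequence[SmallVariantSite] | Sequence[SVRecord],
                          ped: Pedigree, sample_order: Sequence[str]
                          ) -> tuple[float | None, int, int]:
    """Transmission rate over informative sites.

    An informative site for a trio is heterozygous in exactly one parent
    and absent (hom-ref) in the other; the variant is transmitted if the
    child carries it.  Expected rate under Mendelian segregation: 0.5.
    Returns (rate or None, transmitted, informative).
    """
    idx = {s: i for i, s in enumerate(sample_order)}
    informative = transmitted = 0
    for child, father, mother in ped.trios:
        for s in sites:
            f, m, c = (s.genotypes[idx[father]], s.genotypes[idx[mother]],
                       s.genotypes[idx[child]])
            if c is None:
                continue
            if (_het(f) and _hom_ref(m)) or (_het(m) and _hom_ref(f)):
                informative += 1
                if _non_ref(c):
                    transmitted += 1
    if informative == 0:
        return None, 0, 0
    return transmitted / informative, transmitted, informative


@dataclass
class SingletonProfile:
    """Per-sample singleton counts plus within-family private-variant
    breakdown at cohort AC 2-4."""

    singletons: dict[str, int]
    family_private: dict[str, dict[int, int]] = field(default_factory=dict)

    def role_means(self, ped: Pedigree) -> dict[str, float]:
        sums: dict[str, list[int]] = {"child": [], "parent": [], "unrelated": [],
                                      "duo_child": []}
        for sid, count in self.singletons.items():
            s = ped.samples[sid]
            if s.is_duo_child:
                sums["duo_child"].append(count)
            else:
                sums[s.role].append(count)
        return {role: float(np.mean(vals)) if vals else float("nan")
                for role, vals in sums.items()}


def singleton_profile(sites: Sequence[SmallVariantSite] | Sequence[SVRecord],
                      ped: Pedigree, sample_order: Sequence[str]
                      ) -> SingletonProfile:
    """Count per-sample singletons (cohort AC = 1) and family-private
    variants at within-family AC 2-4.

    Cohort AC is computed over ALL samples including relatives.  Duo
    children are reported separately from trio children in role means.
    """
    singles = {sid: 0 for sid in sample_order}
    fam_of: dict[str, str] = {}
    for child, father, mother in ped.trios:
        fam_of[child] = fam_of[father] = fam_of[mother] = child
    private: dict[str, dict[int, int]] = {}
    for s in sites:
        carriers = [i for i, gt in enumerate(s.genotypes) if _non_ref(gt)]
        ac = sum(sum(1 for a in s.genotypes[i] if a == 1) for i in carriers)
        if ac == 1:
            singles[sample_order[carriers[0]]] += 1
        elif 2 <= ac <= 4:
            fams = {fam_of.get(sample_order[i]) for i in carriers}
            if len(fams) == 1 and None not in fams:
                fam = fams.pop()
                private.setdefault(fam, {2: 0, 3: 0, 4: 0})[ac] += 1
    return SingletonProfile(singletons=singles, family_private=private)
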