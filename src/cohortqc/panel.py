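"""Haplotype-panel site filtering.

The filter cascade retains biallelic sites that are FILTER=PASS, have
genotype missingness < 5%, pass the Hardy-Weinberg exact test (p > 1e-10)
in at least one super-population, have Mendelian error rate <= 5%, and
carry a minor allele count >= 2 (singletons are uninformative for
phasing).  Also provides the male-X ploidy fix applied after phasing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io import (CohortQCError, GenomicInterval, Genotype, Pedigree,
                 SmallVariantSite, SUPER_POPULATIONS)
from .trio import site_mer

# GRCh38 chrX pseudoautosomal regions (0-based half-open); overridable.
DEFAULT_PAR_INTERVALS = (
    GenomicInterval("chrX", 10_000, 2_781_479),
    GenomicInterval("chrX", 155_701_382, 156_030_895),
)


def hwe_exact_p(hom_ref: int, het: int, hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed minor-allele count and sums the
    probabilities of all heterozygote counts whose conditional probability
    is <= that of the observed configuration (the standard exact-test
    convention, no mid-p).  Monomorphic sites return 1 by convention.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise CohortQCError("negative genotype count")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise CohortQCError("HWE test needs at least one individual")
    rare = 2 * min(hom_ref, hom_alt) + het  # minor-allele copies
    if rare == 0:
        return 1.0

    # P(n_het | n, rare) via the symmetric recurrence; normalize at the end.
    probs = [0.0] * (rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # going down: het -> het - 2
    curr = mid
    while curr > 1:
        n_hom_rare = (rare - curr) // 2
        n_hom_common = n - curr - n_hom_rare
        probs[curr - 2] = probs[curr] * curr * (curr - 1) / (
            4.0 * (n_hom_rare + 1) * (n_hom_common + 1))
        curr -= 2
    curr = mid
    while curr <= rare - 2:
        n_hom_rare = (rare - curr) // 2
        n_hom_common = n - curr - n_hom_rare
        probs[curr + 2] = probs[curr] * 4.0 * n_hom_rare * n_hom_common / (
            (curr + 2.0) * (curr + 1.0))
        curr += 2
    total = sum(probs)
    obs = probs[het] / total
    p = sum(pr for pr in probs if pr / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_chisq_p(hom_ref: int, het: int, hom_alt: int) -> float:
    """1-df chi-square HWE test against expectations from the sample AF.

    Any zero expected cell (monomorphic site) yields p = 1 by convention.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise CohortQCError("negative genotype count")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise CohortQCError("HWE test needs at least one individual")
    p_alt = (het + 2 * hom_alt) / (2 * n)
    expected = (n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt),
                n * p_alt ** 2)
    if any(e == 0 for e in expected):
        warnings.warn("monomorphic site: chi-square HWE p set to 1")
        return 1.0
    chi2 = sum((o - e) ** 2 / e
               for o, e in zip((hom_ref, het, hom_alt), expected))
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class FilterThresholds:
    """Strict inequalities exactly as applied: missingness < max_missingness,
    HWE p > hwe_min_p in >=1 super-population, MER <= max_mer, MAC >= min_mac."""

    require_pass: bool = True
    max_missingness: float = 0.05
    hwe_min_p: float = 1e-10
    max_mer: float = 0.05
    min_mac: int = 2
    hwe_test: str = "exact"  # or "chisq" (used inside the Absinthe-style SV path)

    @classmethod
    def vacuous(cls) -> "FilterThresholds":
        return cls(require_pass=False, max_missingness=1.01, hwe_min_p=0.0,
                   max_mer=1.0, min_mac=0)


CRITERIA_ORDER = ("filter_pass", "missingness", "hwe", "mer", "mac")


@dataclass
class FilterDecision:
    site_id: str
    verdicts: dict[str, bool]
    retained: bool
    first_failing: str | None

    def __post_init__(self) -> None:
        assert self.retained == all(self.verdicts.values())


def _hwe_verdict(site: SmallVariantSite, pop_samples: Mapping[str, Sequence[int]],
                 thresholds: FilterThresholds) -> bool:
    test = hwe_exact_p if thresholds.hwe_test == "exact" else hwe_chisq_p
    for pop, idx in pop_samples.items():
        hr, het, ha = site.genotype_counts(idx)
        if hr + het + ha == 0:
            continue
        p = test(hr, het, ha)
        site.hwe_p[pop] = p
        if p > thresholds.hwe_min_p:
            return True
    return False


def apply_panel_filters(sites: Sequence[SmallVariantSite], ped: Pedigree,
                        sample_order: Sequence[str],
                        thresholds: FilterThresholds | None = None,
                        ) -> tuple[list[SmallVariantSite], list[FilterDecision]]:
    """Run the filter cascade; returns retained sites plus a per-site ledger.

    Each criterion is evaluated independently and the verdicts conjoined,
    so the retained set is order-independent; the named first-failing
    criterion follows the cascade order (FILTER, missingness, HWE, MER,
    MAC).  Sites with no complete trio have undefined MER and pass that
    criterion with a warning.
    """
    thresholds = thresholds or FilterThresholds()
    pops: dict[str, list[int]] = {}
    for i, sid in enumerate(sample_order):
        sp = ped.samples[sid].super_population if sid in ped.samples else ""
        if sp and sp not in SUPER_POPULATIONS:
            raise CohortQCError(f"unknown super-population label {sp!r}")
        pops.setdefault(sp or "ALL", []).append(i)

    retained: list[SmallVariantSite] = []
    ledger: list[FilterDecision] = []
    for site in sites:
        mer = site.mer if site.mer is not None else site_mer(site, ped, sample_order)
        site.mer = mer
        if mer is None:
            warnings.warn(f"site {site.site_id}: no complete trio; "
                          "MER undefined, criterion passed through")
        verdicts = {
            "filter_pass": (site.filter == "PASS") or not thresholds.require_pass,
            "missingness": site.missingness < thresholds.max_missingness,
            "hwe": _hwe_verdict(site, pops, thresholds),
            "mer": mer is None or mer <= thresholds.max_mer,
            "mac": site.mac >= thresholds.min_mac,
        }
        keep = all(verdicts.values())
        first = next((c for c in CRITERIA_ORDER if not verdicts[c]), None)
        ledger.append(FilterDecision(site.site_id, verdicts, keep, first))
        if keep:
            retained.append(site)
    return retained, ledger


def refilter_mac(sites: Sequence[SmallVariantSite], min_mac: int = 2
                 ) -> list[SmallVariantSite]:
    """Post-phasing re-check: drop sites that fell below MAC >= min_mac
    (phasing tools can set rare genotypes to reference)."""
    return [s for s in sites if s.mac >= min_mac]


def _in_par(pos: int, chrom: str, par: Iterable[GenomicInterval]) -> bool:
    return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in par)


def fix_male_x_ploidy(sites: Sequence[SmallVariantSite], ped: Pedigree,
                      sample_order: Sequence[str],
                      par_intervals: Iterable[GenomicInterval] = DEFAULT_PAR_INTERVALS,
                      x_chrom: str = "chrX") -> None:
    """Convert male diploid genotypes to haploid on non-PAR chrX, in place.

    "0|1", "1|0" and "1|1" become "1"; "0|0" becomes "0".  PAR regions and
    females are untouched; already-haploid genotypes are a no-op.
    """
    males = [i for i, sid in enumerate(sample_order)
             if sid in ped.samples and ped.samples[sid].sex == "male"]
    for site in sites:
        if site.chrom != x_chrom or _in_par(site.pos, site.chrom, par_intervals):
            continue
        for i in males:
            gt = site.genotypes[i]
            if gt is None or len(gt) == 1:
                continue
            site.genotypes[i] = (1,) if any(a == 1 for a in gt) else (0,)
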