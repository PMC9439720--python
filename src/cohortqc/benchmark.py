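"""Benchmarking against truth sets and headline summary statistics.

Precision, recall, and FDR (= 1 - precision) of a call set against a
truth set, restricted to high-confidence regions and stratified by
easy/difficult region class and optional subsets (e.g. singletons).
Small variants match on (chrom, pos, ref, alt) after normalization and,
in genotype-aware mode, on the unordered genotype as well; SV
benchmarking delegates to the truth-set matching rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .io import (CohortQCError, GenomicInterval, RegionStratification,
                 SmallVariantSite)
from .truthset import MatchCriteria, match_sv_sites


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    stratum: str = "all"

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        if self.tp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fn)

    @property
    def fdr(self) -> float | None:
        p = self.precision
        return None if p is None else 1.0 - p


def _site_key(site: SmallVariantSite, genotype_aware: bool,
              sample: int | None) -> tuple:
    key = (site.chrom, site.pos, site.ref, site.alt)
    if genotype_aware and sample is not None:
        gt = site.genotypes[sample] if sample < len(site.genotypes) else None
        key += (tuple(sorted(gt)) if gt is not None else None,)
    return key


def benchmark_calls(test: Sequence[SmallVariantSite],
                    truth: Sequence[SmallVariantSite],
                    confidence_regions: RegionStratification | None = None,
                    stratification: RegionStratification | None = None,
                    subset: Callable[[SmallVariantSite], bool] | None = None,
                    genotype_aware: bool = False,
                    sample: int | None = None) -> dict[str, BenchmarkResult]:
    """TP/FP/FN, precision, recall and FDR of test vs truth calls.

    All counts are restricted to the high-confidence regions when given;
    ``stratification`` adds easy/difficult strata and ``subset`` (e.g.
    singletons, AC = 1) restricts the truth/test universe.
    """

    def in_scope(site: SmallVariantSite) -> bool:
        if subset is not None and not subset(site):
            return False
        if confidence_regions is not None and \
                not confidence_regions.in_high_confidence(site.interval):
            return False
        return True

    test_in = [s for s in test if in_scope(s)]
    truth_in = [s for s in truth if in_scope(s)]
    truth_keys = {_site_key(s, genotype_aware, sample): s for s in truth_in}
    test_keys = {_site_key(s, genotype_aware, sample): s for s in test_in}

    def stratum_of(site: SmallVariantSite) -> str:
        if stratification is None:
            return "all"
        return stratification.classify(site.interval)

    strata = {"all"} if stratification is None else {"easy", "difficult"}
    results = {name: BenchmarkResult(0, 0, 0, name) for name in strata}
    for key, site in test_keys.items():
        r = results[stratum_of(site)]
        if key in truth_keys:
            r.tp += 1
        else:
            r.fp += 1
    for key, site in truth_keys.items():
        if key not in test_keys:
            results[stratum_of(site)].fn += 1
    if stratification is not None:
        results["all"] = BenchmarkResult(
            sum(r.tp for r in results.values()),
            sum(r.fp for r in results.values()),
            sum(r.fn for r in results.values()), "all")
    return results


def benchmark_sv_calls(test, truth, criteria: MatchCriteria = MatchCriteria()
                       ) -> BenchmarkResult:
    """SV precision/recall via one-to-one site matching (window + length
    ratio), mirroring the truth-set construction rules."""
    pairs = match_sv_sites(test, truth, criteria)
    tp = len(pairs)
    return BenchmarkResult(tp, len(test) - tp, len(truth) - tp)


# ---------------------------------------------------------------------------
# Summary statistics backing headline comparisons
# ---------------------------------------------------------------------------

def fold_change(a: float, b: float) -> float:
    """a/b rounded to 2 decimals (printed-precision convention)."""
    if b == 0:
        raise CohortQCError("zero denominator")
    return round(a / b, 2)


def fraction_percent(a: float, b: float) -> float:
    """100*a/b rounded to 1 decimal."""
    if b == 0:
        raise CohortQCError("zero denominator")
    return round(100.0 * a / b, 1)


def category_sum(*counts: int) -> int:
    """Exact integer sum across categories."""
    return int(sum(counts))
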