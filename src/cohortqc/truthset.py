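"""Dual-genotyper SV truth-set construction.

Integrates genotypes from two independent SV genotypers (a
graph/k-mer-based caller reporting genotype quality, and a
graph-realignment caller reporting a FILTER status) into high-confidence
genotypes: a site-sample genotype is kept only when the GQ-filtered
(>= 200) call and the PASS call agree; disagreement or a failed filter
yields missing.  Sites missing across all samples are dropped, matched
to a panel's SV sites by a +/-50 bp start window and an 80% length
ratio, and sites that are monomorphic or out of HWE (exact p < 1e-10)
are excluded from the final truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CohortQCError, Genotype, SVRecord
from .panel import hwe_exact_p

DEFAULT_GQ_MIN = 200
DEFAULT_START_WINDOW = 50   # +/- bp around each start => |delta| <= 100
DEFAULT_MIN_LENGTH_RATIO = 0.80
DEFAULT_HWE_MIN_P = 1e-10


@dataclass
class DualGenotypeRecord:
    site_id: str
    gt_a: Genotype
    gq_a: float | None
    gt_b: Genotype
    filter_b: str
    integrated: Genotype = None

    def integrate(self, gq_min: float = DEFAULT_GQ_MIN) -> Genotype:
        a_ok = self.gt_a is not None and self.gq_a is not None and \
            self.gq_a >= gq_min
        b_ok = self.gt_b is not None and self.filter_b == "PASS"
        if a_ok and b_ok and sorted(self.gt_a) == sorted(self.gt_b):
            self.integrated = self.gt_a
        else:
            self.integrated = None
        return self.integrated


def integrate_dual_genotypes(
        gts_a: Mapping[str, Sequence[Genotype]],
        gqs_a: Mapping[str, Sequence[float | None]],
        gts_b: Mapping[str, Sequence[Genotype]],
        filters_b: Mapping[str, str],
        gq_min: float = DEFAULT_GQ_MIN,
) -> dict[str, list[Genotype]]:
    """Integrate per-site genotype vectors from two genotypers.

    ``gts_a``/``gts_b`` map site id -> genotype per sample; ``gqs_a``
    carries genotyper A's per-sample GQ and ``filters_b`` genotyper B's
    per-site FILTER.  Only sites with a non-missing integrated genotype
    in at least one sample survive.  A site absent from either genotyper
    is missing everywhere (intersection semantics).
    """
    out: dict[str, list[Genotype]] = {}
    for site_id in set(gts_a) | set(gts_b):
        a = gts_a.get(site_id)
        b = gts_b.get(site_id)
        if a is None or b is None:
            continue
        if len(a) != len(b):
            raise CohortQCError(f"sample count mismatch at {site_id}")
        gq = gqs_a.get(site_id, [None] * len(a))
        filt = filters_b.get(site_id, ".")
        integrated: list[Genotype] = []
        for s in range(len(a)):
            rec = DualGenotypeRecord(site_id, a[s],
                                     gq[s] if s < len(gq) else None,
                                     b[s], filt)
            integrated.append(rec.integrate(gq_min))
        if any(g is not None for g in integrated):
            out[site_id] = integrated
    return out


# ---------------------------------------------------------------------------
# Site matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchCriteria:
    start_window: int = DEFAULT_START_WINDOW
    min_length_ratio: float = DEFAULT_MIN_LENGTH_RATIO

    def __post_init__(self) -> None:
        if self.start_window < 0:
            raise CohortQCError("start window must be >= 0")
        if not 0.0 < self.min_length_ratio <= 1.0:
            raise CohortQCError("length ratio must lie in (0, 1]")


def _pair_matches(a: SVRecord, b: SVRecord, crit: MatchCriteria) -> bool:
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    # closed +/-window intervals around each start intersect iff
    # |delta start| <= 2 * window
    if abs(a.start - b.start) > 2 * crit.start_window:
        return False
    ratio = min(a.length, b.length) / max(a.length, b.length)
    return ratio >= crit.min_length_ratio


def match_sv_sites(set1: Sequence[SVRecord], set2: Sequence[SVRecord],
                   criteria: MatchCriteria = MatchCriteria(),
                   ) -> list[tuple[SVRecord, SVRecord]]:
    """One-to-one greedy matching of two SV site sets.

    Candidate pairs satisfy the start-window and length-ratio criteria
    within the same SV type; pairs are taken greedily by smallest
    |delta start|, ties broken by larger length ratio (then record ids
    for determinism), and no record is matched twice.
    """
    candidates = []
    for a in set1:
        for b in set2:
            if _pair_matches(a, b, criteria):
                ratio = min(a.length, b.length) / max(a.length, b.length)
                candidates.append((abs(a.start - b.start), -ratio,
                                   a.record_id, b.record_id, a, b))
    candidates.sort(key=lambda c: c[:4])
    used1: set[str] = set()
    used2: set[str] = set()
    pairs = []
    for _, _, ida, idb, a, b in candidates:
        if ida in used1 or idb in used2:
            continue
        used1.add(ida)
        used2.add(idb)
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Metrics and finalization
# ---------------------------------------------------------------------------

def _is_nonref(gt: Genotype) -> bool:
    return gt is not None and any(a == 1 for a in gt)


def truth_metrics(test: Sequence[Genotype], validation: Sequence[Genotype]
                  ) -> dict[str, float | None]:
    """Genotype concordance and non-reference precision.

    Concordance = correct genotypes / validation-set site count; NRP =
    (correct HET + correct hom-alt) / non-reference genotypes called in
    the test set.
    """
    if len(test) != len(validation):
        raise CohortQCError("test/validation genotype vectors must align")
    n_val = len(validation)
    if n_val == 0:
        return {"concordance": None, "non_reference_precision": None}
    correct = sum(1 for t, v in zip(test, validation)
                  if t is not None and v is not None and
                  sorted(t) == sorted(v))
    nonref_calls = [(t, v) for t, v in zip(test, validation) if _is_nonref(t)]
    correct_nonref = sum(1 for t, v in nonref_calls
                         if v is not None and sorted(t) == sorted(v))
    nrp = correct_nonref / len(nonref_calls) if nonref_calls else None
    return {"concordance": correct / n_val, "non_reference_precision": nrp}


def finalize_truth_set(integrated: Mapping[str, Sequence[Genotype]],
                       hwe_min_p: float = DEFAULT_HWE_MIN_P,
                       svtypes: Mapping[str, str] | None = None,
                       ) -> tuple[dict[str, list[Genotype]], dict[str, int]]:
    """Drop monomorphic and HWE-violating sites; report per-type counts.

    A site is monomorphic when no non-missing genotype carries the alt
    allele (or all carry only alt); HWE uses the exact test on diploid
    genotype counts with exclusion at p < hwe_min_p (strict).
    """
    kept: dict[str, list[Genotype]] = {}
    counts: dict[str, int] = {}
    for site_id, gts in integrated.items():
        present = [g for g in gts if g is not None]
        if not present:
            continue
        acs = [sum(1 for a in g if a == 1) for g in present]
        ans = [len(g) for g in present]
        if sum(acs) == 0 or sum(acs) == sum(ans):
            continue  # monomorphic
        hr = sum(1 for g in present if len(g) == 2 and sum(g) == 0)
        het = sum(1 for g in present if len(g) == 2 and sum(g) == 1)
        ha = sum(1 for g in present if len(g) == 2 and sum(g) == 2)
        if hr + het + ha > 0 and hwe_exact_p(hr, het, ha) < hwe_min_p:
            continue
        kept[site_id] = list(gts)
        if svtypes:
            t = svtypes.get(site_id, "NA")
            counts[t] = counts.get(t, 0) + 1
    counts["total"] = len(kept)
    return kept, counts
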