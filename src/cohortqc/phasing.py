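"""Phasing-accuracy statistics.

Switch error rate (SER) against a truth panel, SV flip rate against
SV-flanking-SNV truth pairs, and trio-based parental flip rate.  SER
follows the plain junction-count definition: switches / assessed
heterozygous pairs, so an isolated single-site flip contributes two
switches; dedicated flip-rate metrics handle SV flips instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CohortQCError, Genotype, Pedigree

#: MAF bin edges: (0, 0.1%], (0.1%, 1%], (1%, 10%], (10%, 50%]
DEFAULT_MAF_BINS = (0.001, 0.01, 0.1, 0.5)


@dataclass
class SERReport:
    n_switches: int
    n_pairs: int
    strata: dict[str, "SERReport"] = field(default_factory=dict)

    @property
    def ser(self) -> float | None:
        """switches / assessed HET pairs; None (n/a, never 0) when no
        pair was assessable."""
        if self.n_pairs == 0:
            return None
        return self.n_switches / self.n_pairs


def _orientations(test: np.ndarray, truth: np.ndarray,
                  assessed: np.ndarray) -> np.ndarray:
    """Relative phase orientation (0/1) at each assessed het site."""
    return (test[assessed, 0] != truth[assessed, 0]).astype(int)


def assessable_het_sites(test: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Sites heterozygous (and hence phase-bearing) in both panels."""
    het_test = test[:, 0] != test[:, 1]
    het_truth = truth[:, 0] != truth[:, 1]
    return np.flatnonzero(het_test & het_truth)


def switch_error_rate(test: np.ndarray, truth: np.ndarray,
                      mafs: Sequence[float] | None = None,
                      maf_bins: Sequence[float] = DEFAULT_MAF_BINS,
                      ) -> SERReport:
    """SER for one sample's haplotypes (arrays of shape (sites, 2)).

    Assessed sites are heterozygous in both panels; a switch is counted at
    every junction between consecutive assessed sites where the relative
    phase orientation changes.  With MAFs supplied, per-MAF-bin strata are
    reported (a junction falls in the bin of its right-hand site).
    SER is orientation-free: globally swapping hap1/hap2 of either panel
    leaves it unchanged.
    """
    test = np.asarray(test)
    truth = np.asarray(truth)
    if test.shape != truth.shape:
        raise CohortQCError("test/truth panels must cover the same sites")
    assessed = assessable_het_sites(test, truth)
    if len(assessed) < 2:
        return SERReport(0, 0)
    orient = _orientations(test, truth, assessed)
    switches = np.flatnonzero(np.diff(orient) != 0)
    report = SERReport(int(len(switches)), int(len(assessed) - 1))
    if mafs is not None:
        mafs = np.asarray(mafs)
        edges = [0.0, *maf_bins]
        for lo, hi in zip(edges[:-1], edges[1:]):
            label = f"({lo:g},{hi:g}]"
            right = assessed[1:]
            in_bin = (mafs[right] > lo) & (mafs[right] <= hi)
            n_pairs = int(in_bin.sum())
            n_sw = int(sum(1 for j in switches if in_bin[j]))
            report.strata[label] = SERReport(n_sw, n_pairs)
    return report


# ---------------------------------------------------------------------------
# SV flip rate against flanking SNVs
# ---------------------------------------------------------------------------

@dataclass
class FlipReport:
    n_assessed: int
    n_flipped: int
    n_total_het: int = 0
    by_type: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def flip_rate(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return self.n_flipped / self.n_assessed

    @property
    def assessed_fraction(self) -> float | None:
        if self.n_total_het == 0:
            return None
        return self.n_assessed / self.n_total_het


def _phase_rel(sv_pair: np.ndarray, snv_pair: np.ndarray) -> int:
    """cis (0) if the alt alleles share a haplotype, trans (1) otherwise."""
    sv_hap = int(np.argmax(sv_pair))   # which haplotype carries the SV alt
    snv_hap = int(np.argmax(snv_pair))
    return int(sv_hap != snv_hap)


def sv_flip_rate(sv_test: np.ndarray, sv_truth: np.ndarray,
                 sv_positions: Sequence[int], sv_types: Sequence[str],
                 snv_test: np.ndarray, snv_truth: np.ndarray,
                 snv_positions: Sequence[int],
                 window: int = 50_000) -> FlipReport:
    """Flip rate of phased het SVs relative to SV-flanking-SNV pairs.

    For each SV heterozygous and phased in both panels, the nearest
    flanking SNV on each side (within ``window`` bp) that is heterozygous
    in both panels anchors a cis/trans comparison; the SV is flipped iff
    its phase relative to the flank(s) is inverted in the test panel
    (majority over the two sides when both are available).  SVs with no
    usable flank are unassessed but count toward the assessed-fraction
    denominator.
    """
    snv_positions = np.asarray(snv_positions)
    snv_ok = np.flatnonzero((snv_test[:, 0] != snv_test[:, 1]) &
                            (snv_truth[:, 0] != snv_truth[:, 1]))
    assessed = flipped = 0
    total_het = 0
    by_type: dict[str, list[int]] = {}
    for i, pos in enumerate(sv_positions):
        het_both = (sv_test[i, 0] != sv_test[i, 1]) and \
                   (sv_truth[i, 0] != sv_truth[i, 1])
        if not het_both:
            continue
        total_het += 1
        left = snv_ok[(snv_positions[snv_ok] < pos) &
                      (snv_positions[snv_ok] >= pos - window)]
        right = snv_ok[(snv_positions[snv_ok] > pos) &
                       (snv_positions[snv_ok] <= pos + window)]
        flanks = []
        if len(left):
            flanks.append(int(left[-1]))
        if len(right):
            flanks.append(int(right[0]))
        if not flanks:
            continue
        votes = []
        for j in flanks:
            rel_test = _phase_rel(sv_test[i], snv_test[j])
            rel_truth = _phase_rel(sv_truth[i], snv_truth[j])
            votes.append(int(rel_test != rel_truth))
        assessed += 1
        is_flipped = int(sum(votes) * 2 > len(votes))
        flipped += is_flipped
        t = by_type.setdefault(sv_types[i], [0, 0])
        t[0] += 1
        t[1] += is_flipped
    return FlipReport(assessed, flipped, total_het,
                      {k: (v[0], v[1]) for k, v in by_type.items()})


# ---------------------------------------------------------------------------
# Parental flip rate
# ---------------------------------------------------------------------------

def _unambiguous_origin(child: Genotype, father: Genotype,
                        mother: Genotype) -> str | None:
    """Which parent contributed the child's single alt allele.

    Only trio-unambiguous sites qualify: child HET, not a de novo, and
    not all three members HET.  Returns "father"/"mother" or None when
    ambiguous/unassessable.
    """
    if child is None or father is None or mother is None:
        return None
    if len(child) != 2 or sorted(child) != [0, 1]:
        return None
    f_alt = any(a == 1 for a in father)
    m_alt = any(a == 1 for a in mother)
    if not f_alt and not m_alt:
        return None  # de novo: excluded
    f_het = len(father) == 2 and sorted(father) == [0, 1]
    m_het = len(mother) == 2 and sorted(mother) == [0, 1]
    if f_het and m_het:
        return None  # all-HET trio: ambiguous
    # child carries exactly one alt and one ref allele; each must be
    # drawable from a distinct parent
    f_ref = any(a == 0 for a in father)
    m_ref = any(a == 0 for a in mother)
    can_f = f_alt and m_ref   # alt from father, ref from mother
    can_m = m_alt and f_ref
    if can_f and not can_m:
        return "father"
    if can_m and not can_f:
        return "mother"
    if can_f and can_m:
        return None  # both parents could have contributed the alt
    return None  # Mendelian-inconsistent: not assessable


def parental_flip_rate(child_haps: np.ndarray,
                       father_gts: Sequence[Genotype],
                       mother_gts: Sequence[Genotype]) -> FlipReport:
    """Fraction of a child's phased HET genotypes inconsistent with trio
    inheritance, under the per-chromosome orientation that minimizes
    inconsistencies (majority vote), so one orientation error cannot
    masquerade as many flips.

    ``child_haps`` is (sites, 2); sites where all three members are HET
    and de novo sites are excluded from assessment.
    """
    assignments = []  # 1 if hap1 carries the alt from father's side
    for i in range(child_haps.shape[0]):
        gt = (int(child_haps[i, 0]), int(child_haps[i, 1]))
        origin = _unambiguous_origin(gt, father_gts[i], mother_gts[i])
        if origin is None:
            continue
        alt_on_h1 = child_haps[i, 0] == 1
        # consistent with "hap1 == paternal" iff alt on hap1 came from father
        assignments.append(int(alt_on_h1 == (origin == "father")))
    n = len(assignments)
    if n == 0:
        return FlipReport(0, 0)
    agree = sum(assignments)
    flips = min(agree, n - agree)
    return FlipReport(n, flips)


def cohort_parental_flip(child_haps_by_sample: Mapping[str, np.ndarray],
                         genotypes: Mapping[str, Sequence[Genotype]],
                         ped: Pedigree) -> dict[str, FlipReport]:
    """Per-child parental flip rate over a cohort."""
    out = {}
    for child, father, mother in ped.trios:
        if child not in child_haps_by_sample:
            continue
        out[child] = parental_flip_rate(
            child_haps_by_sample[child], genotypes[father], genotypes[mother])
    return out
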