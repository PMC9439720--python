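"""Imputed-genotype evaluation.

Dosage r² per allele-frequency bin, IMPUTE-style info scores, hard-call
genotype discordance, and info/MAF-binned variant counting.  Dosage is
the expected alternate-allele count, e = p_het + 2*p_homalt in [0, 2];
the info score is the variance-ratio form
``1 - sum(f_i - e_i^2) / (2N theta (1 - theta))`` with
f_i = p_het + 4*p_homalt and theta the expected allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CohortQCError

DEFAULT_HARD_CALL_THRESHOLD = 0.90
DEFAULT_INFO_THRESHOLDS = (0.4, 0.8)
#: MAF bins: very rare (<0.5%), rare (0.5-5%), common (>=5%)
DEFAULT_MAF_BIN_EDGES = (0.005, 0.05)
MAF_BIN_LABELS = ("maf<0.5%", "0.5%<=maf<5%", "maf>=5%")


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != 3:
        raise CohortQCError("expected probability triples (p_homref, p_het, "
                            "p_homalt)")
    if np.any(probs < -1e-9) or \
            np.any(np.abs(probs.sum(axis=-1) - 1.0) > 1e-6):
        raise CohortQCError("probability triples must be >= 0 and sum to 1")
    return probs


def dosages(probs: np.ndarray) -> np.ndarray:
    """Expected alt-allele dosage per triple: p_het + 2*p_homalt."""
    probs = _check_probs(probs)
    return probs[..., 1] + 2.0 * probs[..., 2]


def info_score(site_probs: np.ndarray) -> float:
    """IMPUTE-style info score for one site's probability triples.

    info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta)) with theta the
    expected AF; monomorphic sites (theta in {0, 1}) return 1 by
    convention, as do fully certain genotype sets.
    """
    probs = _check_probs(site_probs)
    e = probs[:, 1] + 2.0 * probs[:, 2]
    f = probs[:, 1] + 4.0 * probs[:, 2]
    n = len(e)
    if n < 1:
        raise CohortQCError("info score needs at least one sample")
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    info = 1.0 - (f - e ** 2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(min(1.0, max(0.0, info)))


def expected_af(site_probs: np.ndarray) -> float:
    probs = _check_probs(site_probs)
    e = probs[:, 1] + 2.0 * probs[:, 2]
    return float(e.sum() / (2.0 * len(e)))


def hard_call(probs: np.ndarray,
              threshold: float = DEFAULT_HARD_CALL_THRESHOLD) -> np.ndarray:
    """Best-guess genotypes (0/1/2), -1 (missing) below the threshold.

    The genotype is the argmax triple entry when its probability is at
    least the threshold (0.90 exactly is not below 0.90); ties at the max
    are defensive-missing (cannot occur above 0.5).
    """
    probs = _check_probs(probs)
    best = probs.argmax(axis=-1)
    best_p = probs.max(axis=-1)
    calls = np.where(best_p >= threshold, best, -1)
    sorted_p = np.sort(probs, axis=-1)
    ties = (sorted_p[..., -1] - sorted_p[..., -2] < 1e-12) & (calls >= 0)
    if np.any(ties):
        warnings.warn("tied maximum genotype probabilities set to missing")
        calls = np.where(ties, -1, calls)
    return calls


@dataclass
class R2Report:
    """Mean r² per AF bin (per-sample r² across sites, averaged over the
    samples with assessable variance in the bin)."""

    mean_r2: dict[str, float]
    n_samples_used: dict[str, int]
    n_excluded: dict[str, int]


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None  # undefined, n/a — never 0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def dosage_r2(imputed: np.ndarray, truth: np.ndarray,
              panel_af: Sequence[float],
              bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
              bin_labels: Sequence[str] = MAF_BIN_LABELS,
              per_sample: bool = True) -> R2Report:
    """Squared Pearson correlation of imputed vs truth dosages per AF bin.

    ``imputed``/``truth`` are (sites, samples) dosage matrices; sites are
    binned by the reference panel's (unrelated-sample) AF.  Default
    aggregation computes per-sample r² within a bin and averages over
    samples; samples with no assessable variance in a bin are excluded
    from the mean and counted.  ``per_sample=False`` pools all
    site-sample pairs in a bin instead.
    """
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if imputed.shape != truth.shape:
        raise CohortQCError("imputed/truth dosage matrices must align")
    panel_af = np.asarray(panel_af, dtype=float)
    maf = np.minimum(panel_af, 1.0 - panel_af)
    edges = [-np.inf, *bin_edges, np.inf]
    means: dict[str, float] = {}
    used: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for label, lo, hi in zip(bin_labels, edges[:-1], edges[1:]):
        in_bin = np.flatnonzero((maf >= lo) & (maf < hi))
        if len(in_bin) == 0:
            continue
        if per_sample:
            r2s = []
            n_excl = 0
            for s in range(imputed.shape[1]):
                ok = ~(np.isnan(imputed[in_bin, s]) | np.isnan(truth[in_bin, s]))
                r2 = _pearson_r2(imputed[in_bin, s][ok], truth[in_bin, s][ok])
                if r2 is None:
                    n_excl += 1
                else:
                    r2s.append(r2)
            if r2s:
                means[label] = float(np.mean(r2s))
            used[label] = len(r2s)
            excluded[label] = n_excl
        else:
            x = imputed[in_bin].ravel()
            y = truth[in_bin].ravel()
            ok = ~(np.isnan(x) | np.isnan(y))
            r2 = _pearson_r2(x[ok], y[ok])
            if r2 is not None:
                means[label] = r2
            used[label] = 1 if r2 is not None else 0
            excluded[label] = 0 if r2 is not None else 1
    return R2Report(means, used, excluded)


def gt_discordance(hard_calls: np.ndarray, truth: np.ndarray,
                   shared_mask: np.ndarray | None = None
                   ) -> dict[int, float | None]:
    """Per-sample genotype discordance: 1 - (matching non-missing calls /
    non-missing calls), optionally restricted to shared sites."""
    hard_calls = np.asarray(hard_calls)
    truth = np.asarray(truth)
    if shared_mask is not None:
        hard_calls = hard_calls[shared_mask]
        truth = truth[shared_mask]
    out: dict[int, float | None] = {}
    for s in range(hard_calls.shape[1]):
        called = hard_calls[:, s] >= 0
        n = int(called.sum())
        if n == 0:
            out[s] = None
            continue
        match = int((hard_calls[called, s] == truth[called, s]).sum())
        out[s] = 1.0 - match / n
    return out


def count_by_info_and_maf(info: Sequence[float], maf: Sequence[float],
                          info_thresholds: Sequence[float] = DEFAULT_INFO_THRESHOLDS,
                          bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
                          bin_labels: Sequence[str] = MAF_BIN_LABELS,
                          ) -> dict[tuple[float, str], int]:
    """Variant counts per (info threshold, MAF bin); strict > at the
    thresholds, so counts at info>0.8 nest within counts at info>0.4."""
    info = np.asarray(info, dtype=float)
    maf = np.asarray(maf, dtype=float)
    edges = [-np.inf, *bin_edges, np.inf]
    out: dict[tuple[float, str], int] = {}
    for t in info_thresholds:
        above = info > t
        for label, lo, hi in zip(bin_labels, edges[:-1], edges[1:]):
            out[(t, label)] = int((above & (maf >= lo) & (maf < hi)).sum())
    return out
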