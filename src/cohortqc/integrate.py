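"""Ensemble SV call-set integration with a learned boost-score filter.

Pairs of same-class SVs are concordant under reciprocal-overlap rules
(50% for pairs larger than 5 kb, 10% below; insertions by breakpoint
distance <= 100 bp).  Records are clustered across call sets by
single-linkage, a per-SV-class gradient-boosted model ("boost" model)
scores each call per genome from its read evidence, a score threshold is
chosen to keep the estimated FDR below 5% (default 0.448, strict >), and
call-set-specific loci failing the model in >= 48% of carrier samples are
dropped.  One canonical record per locus is selected by split-read
support, then boost score, then sample support.

Reciprocal overlap is min(overlap/len_A, overlap/len_B): both fractions
must meet the cutoff (bedtools -r semantics).  mCNV/CPX/CTX records pass
through unscored and are flagged for manual review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io import CohortQCError, GENOMIC_CONTEXTS, SVRecord

DEFAULT_BOOST_THRESHOLD = 0.448
SIZE_CLASS_BOUNDARY = 5_000
RO_CUTOFF_LARGE = 0.50
RO_CUTOFF_SMALL = 0.10
INS_WINDOW = 100
RETENTION_FAIL_FRACTION = 0.48
UNSCORED_TYPES = ("mCNV", "CPX", "CTX")


@dataclass(frozen=True)
class ConcordancePair:
    record_a: str
    record_b: str
    svtype: str
    reciprocal_overlap: float | None  # None for INS
    breakpoint_distance: int
    concordant: bool


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """min(overlap/len_A, overlap/len_B); undefined (error) for INS."""
    if a.svtype == "INS" or b.svtype == "INS":
        raise CohortQCError("reciprocal overlap is undefined for insertions")
    ov = a.interval.overlap_length(b.interval)
    return min(ov / a.interval.length, ov / b.interval.length)


def sv_concordant(a: SVRecord, b: SVRecord) -> ConcordancePair:
    """Concordance under the size-dependent reciprocal-overlap rules.

    INS pairs are concordant iff insertion points are within 100 bp.
    Other pairs use reciprocal overlap >= 50% when the larger member
    exceeds 5 kb, >= 10% otherwise.  Cross-type comparison is an error.
    """
    if a.svtype != b.svtype:
        raise CohortQCError(
            f"cross-type concordance ({a.svtype} vs {b.svtype})")
    dist = abs(a.start - b.start)
    if a.svtype == "INS":
        return ConcordancePair(a.record_id, b.record_id, a.svtype, None,
                               dist, a.chrom == b.chrom and dist <= INS_WINDOW)
    if a.chrom != b.chrom:
        return ConcordancePair(a.record_id, b.record_id, a.svtype, 0.0, dist,
                               False)
    ro = reciprocal_overlap(a, b)
    cutoff = RO_CUTOFF_LARGE if max(a.length, b.length) > SIZE_CLASS_BOUNDARY \
        else RO_CUTOFF_SMALL
    return ConcordancePair(a.record_id, b.record_id, a.svtype, ro, dist,
                           ro >= cutoff)


@dataclass
class Locus:
    """A single-linkage cluster of concordant records across call sets."""

    members: list[SVRecord]
    sources: tuple[str, ...]

    @property
    def stratum(self) -> str:
        return "shared" if len(self.sources) > 1 else f"{self.sources[0]}-only"

    @property
    def svtype(self) -> str:
        return self.members[0].svtype


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_across_callsets(callsets: Mapping[str, Sequence[SVRecord]]
                            ) -> list[Locus]:
    """Single-linkage clustering of pooled records under sv_concordant.

    Records are canonically sorted (chrom, start, id) first, so the
    output is invariant to input file order.  Candidate pairs come from a
    positional sweep; two records never joined by a concordant pair stay
    in different loci.
    """
    if len(callsets) < 2:
        raise CohortQCError("need at least two call sets to integrate")
    pool: list[SVRecord] = []
    for caller, recs in sorted(callsets.items()):
        for r in recs:
            if not r.source:
                r.source = caller
            pool.append(r)
    pool.sort(key=lambda r: (r.chrom, r.start, r.record_id))
    uf = _UnionFind(len(pool))
    # max joinable distance: INS window or full span of the longer record
    for i, a in enumerate(pool):
        for j in range(i + 1, len(pool)):
            b = pool[j]
            if b.chrom != a.chrom:
                break
            reach = INS_WINDOW if a.svtype == "INS" else a.interval.length
            if b.start - a.start > max(reach, INS_WINDOW):
                break
            if a.svtype != b.svtype:
                continue
            if sv_concordant(a, b).concordant:
                uf.union(i, j)
    clusters: dict[int, list[SVRecord]] = {}
    for i, rec in enumerate(pool):
        clusters.setdefault(uf.find(i), []).append(rec)
    loci = [Locus(members=members,
                  sources=tuple(sorted({m.source for m in members})))
            for members in clusters.values()]
    loci.sort(key=lambda l: (l.members[0].chrom, l.members[0].start,
                             l.members[0].record_id))
    return loci


# ---------------------------------------------------------------------------
# Boost model
# ---------------------------------------------------------------------------

_CONTEXT_CODE = {c: i for i, c in enumerate(GENOMIC_CONTEXTS)}


def record_features(rec: SVRecord, sample: int) -> list[float]:
    """Per-genome feature vector: SV depth, 1-kb flank depth, PE count
    (<=150 bp), SR count (<=100 bp of breakpoints), size, allele fraction,
    genomic-context class, de novo fraction."""
    ev = rec.evidence[sample]
    return [ev.depth, ev.flank_depth, float(ev.pe_count), float(ev.sr_count),
            float(np.log10(rec.length)), rec.allele_fraction(),
            float(_CONTEXT_CODE[rec.genomic_context]),
            rec.de_novo_fraction]


@dataclass
class BoostModel:
    """Per-SV-class scorer mapping evidence features to [0, 1].

    The scorer is pluggable: gradient-boosted trees (LightGBM) by default,
    logistic regression as a dependency-light fallback.
    """

    scorers: dict[str, object]
    threshold: float = DEFAULT_BOOST_THRESHOLD
    backend: str = "lightgbm"

    def score(self, rec: SVRecord, sample: int) -> float:
        scorer = self.scorers.get(rec.svtype) or self.scorers.get("*")
        if scorer is None:
            raise CohortQCError(f"no scorer trained for {rec.svtype}")
        x = np.asarray([record_features(rec, sample)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return float(scorer.predict_proba(x)[0, 1])

    def score_record(self, rec: SVRecord) -> None:
        """Attach per-carrier boost scores to a record in place."""
        rec.boost_scores = [None] * len(rec.genotypes)
        for s in rec.carriers():
            rec.boost_scores[s] = self.score(rec, s)

    def passes(self, score: float) -> bool:
        return score > self.threshold  # strict: 0.448 exactly fails


def _make_scorer(backend: str, seed: int):
    if backend == "lightgbm":
        import lightgbm
        return lightgbm.LGBMClassifier(
            n_estimators=100, num_leaves=15, min_child_samples=5,
            random_state=seed, deterministic=True, force_row_wise=True,
            verbose=-1)
    if backend == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000, random_state=seed))
    raise CohortQCError(f"unknown boost backend {backend!r}")


def train_boost_model(training: Sequence[tuple[SVRecord, int, int]],
                      backend: str = "lightgbm", seed: int = 0,
                      threshold: float = DEFAULT_BOOST_THRESHOLD) -> BoostModel:
    """Fit per-SV-class scorers from (record, sample, label) examples.

    Labels are 1 (true SV) / 0 (false).  SV classes with fewer than 50
    labeled examples share a pooled fallback scorer; single-class training
    data is an error.
    """
    by_type: dict[str, list[tuple[list[float], int]]] = {}
    all_rows: list[tuple[list[float], int]] = []
    for rec, sample, label in training:
        row = (record_features(rec, sample), int(label))
        by_type.setdefault(rec.svtype, []).append(row)
        all_rows.append(row)
    labels = {l for _, l in all_rows}
    if labels != {0, 1}:
        raise CohortQCError("training data must contain both classes")
    scorers: dict[str, object] = {}

    def fit(rows):
        x = np.asarray([r for r, _ in rows])
        y = np.asarray([l for _, l in rows])
        scorer = _make_scorer(backend, seed)
        scorer.fit(x, y)
        return scorer

    scorers["*"] = fit(all_rows)
    for svtype, rows in by_type.items():
        if len(rows) >= 50 and {l for _, l in rows} == {0, 1}:
            scorers[svtype] = fit(rows)
    return BoostModel(scorers=scorers, threshold=threshold, backend=backend)


def label_training_truth(loci: Sequence[Locus],
                         uniparental: Callable[[SVRecord, int], bool],
                         de_novo: Callable[[SVRecord, int], bool],
                         support_a: Callable[[SVRecord], bool],
                         support_b: Callable[[SVRecord], bool],
                         ) -> list[tuple[SVRecord, int, int | None]]:
    """Label (record, carrier) pairs as true / false / unlabeled (None).

    True: uni-parentally inherited AND shared across call sets AND both
    external support flags.  False: de novo AND call-set-specific AND
    neither flag.  Everything else is unlabeled.  In synthetic mode the
    support flags come from the generator's injection log, standing in
    for long-read (VaPoR) and assembly (PacBio) support.
    """
    out: list[tuple[SVRecord, int, int | None]] = []
    for locus in loci:
        shared = locus.stratum == "shared"
        for rec in locus.members:
            sa, sb = support_a(rec), support_b(rec)
            for s in rec.carriers():
                if shared and uniparental(rec, s) and sa and sb:
                    out.append((rec, s, 1))
                elif (not shared) and de_novo(rec, s) and not sa and not sb:
                    out.append((rec, s, 0))
                else:
                    out.append((rec, s, None))
    return out


def select_threshold(scores: Sequence[float], labels: Sequence[int] | None,
                     target_fdr: float = 0.05) -> float:
    """Smallest threshold t with estimated FDR among score > t below target.

    With no labeled validation data, falls back to the default 0.448.
    """
    if labels is None:
        return DEFAULT_BOOST_THRESHOLD
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    candidates = np.concatenate([[0.0], np.unique(scores)])
    for t in candidates:
        mask = scores > t
        if not mask.any():
            continue
        fdr = 1.0 - labels[mask].mean()
        if fdr < target_fdr:
            return float(t)
    raise CohortQCError("no threshold achieves the target FDR with "
                        "positive-scoring records remaining")


def retention_rule(rec: SVRecord, model: BoostModel) -> bool:
    """Keep a call-set-specific record iff the fraction of examined
    (carrier) samples failing the boost model is < 48% (strict).

    Zero examined samples excludes the record with a warning.
    """
    carriers = rec.carriers()
    if not carriers:
        warnings.warn(f"{rec.record_id}: no carrier samples; excluded")
        return False
    if not rec.boost_scores or all(b is None for b in rec.boost_scores):
        model.score_record(rec)
    failing = sum(1 for s in carriers
                  if not model.passes(rec.boost_scores[s] or 0.0))
    return failing / len(carriers) < RETENTION_FAIL_FRACTION


def select_final_record(locus: Locus,
                        preferred_ins_source: str | None = None) -> SVRecord:
    """Pick the canonical record for a locus.

    Per sample the winner has the greatest split-read count, ties broken
    by higher boost score; the locus winner is the record winning for the
    most samples (i.e. greatest sample support), ties broken by higher
    sample support then lexicographic record id.  For shared INS loci the
    designated higher-precision caller's record is kept.
    """
    if locus.svtype == "INS" and preferred_ins_source and \
            locus.stratum == "shared":
        preferred = [m for m in locus.members
                     if m.source == preferred_ins_source]
        if preferred:
            return max(preferred, key=lambda r: (len(r.carriers()),
                                                 r.record_id))
    wins: dict[str, int] = {m.record_id: 0 for m in locus.members}
    by_id = {m.record_id: m for m in locus.members}
    samples = range(len(locus.members[0].genotypes))
    for s in samples:
        best = None
        best_key = None
        for m in locus.members:
            if s not in set(m.carriers()):
                continue
            boost = (m.boost_scores[s] if m.boost_scores and
                     m.boost_scores[s] is not None else 0.0)
            key = (m.evidence[s].sr_count if m.evidence else 0, boost,
                   m.record_id)
            if best_key is None or key > best_key:
                best, best_key = m, key
        if best is not None:
            wins[best.record_id] += 1
    return max(by_id.values(),
               key=lambda m: (len(m.carriers()), wins[m.record_id],
                              m.record_id))


# ---------------------------------------------------------------------------
# End-to-end integration
# ---------------------------------------------------------------------------

@dataclass
class IntegrationResult:
    final_records: list[SVRecord]
    loci: list[Locus]
    model: BoostModel | None
    threshold: float
    dropped_specific: list[str] = field(default_factory=list)
    manual_review: list[str] = field(default_factory=list)


def integrate_callsets(callsets: Mapping[str, Sequence[SVRecord]],
                       model: BoostModel | None = None,
                       training: Sequence[tuple[SVRecord, int, int]] | None = None,
                       validation: tuple[Sequence[float], Sequence[int]] | None = None,
                       target_fdr: float = 0.05,
                       preferred_ins_source: str | None = None,
                       backend: str = "lightgbm",
                       seed: int = 0) -> IntegrationResult:
    """Cluster, score, threshold, retain, and select final records.

    Shared loci are retained outright (low observed FDR); call-set-specific
    loci must pass the 48% boost-failure retention rule.  mCNV/CPX/CTX
    records pass through unscored, flagged for manual review.
    """
    loci = cluster_across_callsets(callsets)
    if model is None and training is not None:
        model = train_boost_model(training, backend=backend, seed=seed)
        if validation is not None:
            model.threshold = select_threshold(*validation, target_fdr=target_fdr)
    final: list[SVRecord] = []
    dropped: list[str] = []
    review: list[str] = []
    for locus in loci:
        if model is not None:
            for m in locus.members:
                if m.svtype not in UNSCORED_TYPES:
                    model.score_record(m)
        if locus.svtype in UNSCORED_TYPES:
            winner = select_final_record(locus, preferred_ins_source)
            winner.info["STRATUM"] = locus.stratum
            winner.info["SOURCES"] = list(locus.sources)
            winner.info["MANUAL_REVIEW"] = "Manual_LQ"
            review.append(winner.record_id)
            final.append(winner)
            continue
        if locus.stratum != "shared" and model is not None:
            keep = any(retention_rule(m, model) for m in locus.members)
            if not keep:
                dropped.extend(m.record_id for m in locus.members)
                continue
        winner = select_final_record(locus, preferred_ins_source)
        winner.info["STRATUM"] = locus.stratum
        winner.info["SOURCES"] = list(locus.sources)
        winner.info["WINNER"] = winner.record_id
        final.append(winner)
    return IntegrationResult(
        final_records=final, loci=loci, model=model,
        threshold=model.threshold if model else DEFAULT_BOOST_THRESHOLD,
        dropped_specific=dropped, manual_review=review)
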