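"""End-to-end orchestration on synthetic cohorts.

Wires the generator, the ensemble SV integration, and the evaluation
modules together: simulate a trio cohort, derive per-caller call sets,
label training data from the injection log (standing in for long-read
and assembly support), train and apply the boost filter, and score the
final integrated call set against the injection log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .integrate import (BoostModel, IntegrationResult, Locus,
                        cluster_across_callsets, integrate_callsets,
                        label_training_truth, train_boost_model)
from .io import Pedigree, SVRecord
from .simulate import (CallsetInjectionLog, SimulationConfig, SyntheticCohort,
                       corrupt_callsets, simulate_cohort)


def sv_de_novo_fraction(rec: SVRecord, ped: Pedigree,
                        sample_order: Sequence[str]) -> float:
    """Fraction of offspring harboring the SV de novo among trios in
    which the SV is observed."""
    idx = {sid: i for i, sid in enumerate(sample_order)}

    def carries(i: int) -> bool:
        gt = rec.genotypes[i]
        return gt is not None and any(a == 1 for a in gt)

    observed = de_novo = 0
    for child, father, mother in ped.trios:
        ci, fi, mi = idx[child], idx[father], idx[mother]
        if not (carries(ci) or carries(fi) or carries(mi)):
            continue
        observed += 1
        if carries(ci) and not carries(fi) and not carries(mi):
            de_novo += 1
    return de_novo / observed if observed else 0.0


def annotate_de_novo_fractions(callsets: Mapping[str, Sequence[SVRecord]],
                               ped: Pedigree,
                               sample_order: Sequence[str]) -> None:
    for recs in callsets.values():
        for rec in recs:
            rec.de_novo_fraction = sv_de_novo_fraction(rec, ped, sample_order)


def label_from_injection(loci: Sequence[Locus], cohort: SyntheticCohort,
                         log: CallsetInjectionLog
                         ) -> list[tuple[SVRecord, int, int | None]]:
    """Boost-model training labels from the generator's injection log.

    Uni-parental inheritance and de novo status come from the recorded
    genotypes; the two external support flags both derive from the
    injection log (a record is supported iff it is not an injected FP).
    """
    idx = {sid: i for i, sid in enumerate(cohort.sample_order)}
    child_parents = {idx[c]: (idx[f], idx[m])
                     for c, f, m in cohort.pedigree.trios}

    def carries(rec: SVRecord, i: int) -> bool:
        gt = rec.genotypes[i]
        return gt is not None and any(a == 1 for a in gt)

    def uniparental(rec: SVRecord, s: int) -> bool:
        if s not in child_parents:
            return False
        f, m = child_parents[s]
        return carries(rec, s) and (carries(rec, f) != carries(rec, m))

    def de_novo(rec: SVRecord, s: int) -> bool:
        if s not in child_parents:
            return False
        f, m = child_parents[s]
        return carries(rec, s) and not carries(rec, f) and not carries(rec, m)

    support = lambda rec: not log.is_fp(rec.record_id)
    return label_training_truth(loci, uniparental, de_novo, support, support)


@dataclass
class EnsembleEvaluation:
    result: IntegrationResult
    n_final: int
    n_false_loci: int
    fdr: float
    n_true_shared: int
    n_recovered_shared: int
    recall_shared: float


def evaluate_against_log(result: IntegrationResult,
                         callsets: Mapping[str, Sequence[SVRecord]],
                         log: CallsetInjectionLog) -> EnsembleEvaluation:
    """Score a final integrated call set against the injection log.

    A final locus is false iff every clustered member is an injected FP;
    recall is measured over truth SVs discovered by at least two callers
    (the shared stratum the integration is meant to preserve).
    """
    members_by_winner = {}
    for locus in result.loci:
        for m in locus.members:
            members_by_winner[m.record_id] = locus
    n_false = 0
    recovered: set[str] = set()
    for rec in result.final_records:
        locus = members_by_winner[rec.record_id]
        truths = {log.truth_of(m.record_id) for m in locus.members}
        truths.discard(None)
        if truths:
            recovered |= truths
        else:
            n_false += 1
    truth_seen: dict[str, int] = {}
    for caller, recs in callsets.items():
        for r in recs:
            t = log.truth_of(r.record_id)
            if t is not None:
                truth_seen[t] = truth_seen.get(t, 0) + 1
    shared_truth = {t for t, k in truth_seen.items() if k >= 2}
    n_final = len(result.final_records)
    return EnsembleEvaluation(
        result=result, n_final=n_final, n_false_loci=n_false,
        fdr=n_false / n_final if n_final else 0.0,
        n_true_shared=len(shared_truth),
        n_recovered_shared=len(recovered & shared_truth),
        recall_shared=(len(recovered & shared_truth) / len(shared_truth)
                       if shared_truth else 1.0))


def run_ensemble_integration(config: SimulationConfig | None = None,
                             seed: int = 0,
                             backend: str = "lightgbm",
                             ) -> tuple[EnsembleEvaluation, SyntheticCohort,
                                        CallsetInjectionLog]:
    """Simulate, corrupt, train, integrate, and evaluate in one call.

    The boost model is trained on injection-log labels; the decision
    threshold is the default PASS cutoff (strict > 0.448).
    """
    config = config or SimulationConfig(seed=seed)
    cohort = simulate_cohort(config)
    callsets, log = corrupt_callsets(cohort)
    annotate_de_novo_fractions(callsets, cohort.pedigree, cohort.sample_order)
    loci = cluster_across_callsets(callsets)
    labeled = label_from_injection(loci, cohort, log)
    training = [(r, s, l) for r, s, l in labeled if l is not None]
    model = train_boost_model(training, backend=backend, seed=seed)
    result = integrate_callsets(callsets, model=model)
    return evaluate_against_log(result, callsets, log), cohort, log
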