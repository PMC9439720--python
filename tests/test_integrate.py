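"""Concordance rules, clustering, boost model, thresholding, selection."""

import numpy as np
import pytest

from cohortqc import (CohortQCError, cluster_across_callsets,
                      reciprocal_overlap, retention_rule,
                      select_final_record, select_threshold, sv_concordant,
                      train_boost_model)
from cohortqc.integrate import (DEFAULT_BOOST_THRESHOLD, BoostModel, Locus,
                                record_features)
from cohortqc.pipeline import label_from_injection, run_ensemble_integration
from cohortqc.simulate import CallerProfile, corrupt_callsets
from conftest import make_sv


class TestConcordance:
    def test_small_deletions_at_half_overlap(self):
        a = make_sv(start=100, end=200, record_id="a")
        b = make_sv(start=150, end=250, record_id="b")
        pair = sv_concordant(a, b)
        assert pair.reciprocal_overlap == pytest.approx(0.5)
        assert pair.concordant  # small class needs only 10%

    def test_insertion_window_boundary(self):
        a = make_sv(svtype="INS", start=1000, record_id="a")
        assert sv_concordant(a, make_sv(svtype="INS", start=1099,
                                        record_id="b")).concordant
        assert not sv_concordant(a, make_sv(svtype="INS", start=1101,
                                            record_id="c")).concordant

    def test_large_deletions_need_half_overlap(self):
        a = make_sv(start=0, end=10_000, length=10_000, record_id="a")
        b = make_sv(start=6_000, end=16_000, length=10_000, record_id="b")
        pair = sv_concordant(a, b)  # RO = 0.4
        assert pair.reciprocal_overlap == pytest.approx(0.4)
        assert not pair.concordant

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            s1, s2 = rng.integers(0, 5000, 2)
            l1, l2 = rng.integers(50, 8000, 2)
            a = make_sv(start=int(s1), end=int(s1 + l1), length=int(l1),
                        record_id="a")
            b = make_sv(start=int(s2), end=int(s2 + l2), length=int(l2),
                        record_id="b")
            assert sv_concordant(a, b).concordant == \
                sv_concordant(b, a).concordant

    def test_cross_type_comparison_rejected(self):
        with pytest.raises(CohortQCError):
            sv_concordant(make_sv(svtype="DEL"), make_sv(svtype="DUP"))

    def test_reciprocal_overlap_undefined_for_ins(self):
        with pytest.raises(CohortQCError):
            reciprocal_overlap(make_sv(svtype="INS"), make_sv(svtype="INS"))


class TestClustering:
    def test_identical_callsets_all_shared(self):
        recs_a = [make_sv(start=s, record_id=f"a{i}", source="callerA")
                  for i, s in enumerate(range(1000, 50_000, 5000))]
        recs_b = [make_sv(start=s, record_id=f"b{i}", source="callerB")
                  for i, s in enumerate(range(1000, 50_000, 5000))]
        loci = cluster_across_callsets({"callerA": recs_a, "callerB": recs_b})
        assert all(l.stratum == "shared" for l in loci)
        assert len(loci) == len(recs_a)

    def test_unique_record_forms_specific_locus(self):
        a = [make_sv(start=1000, record_id="a0", source="callerA")]
        b = [make_sv(start=1000, record_id="b0", source="callerB"),
             make_sv(start=90_000, record_id="b1", source="callerB")]
        loci = cluster_across_callsets({"callerA": a, "callerB": b})
        strata = sorted(l.stratum for l in loci)
        assert strata == ["callerB-only", "shared"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        recs = {}
        for caller in ("callerA", "callerB"):
            rs = []
            for i in range(60):
                start = int(rng.integers(0, 200_000))
                length = int(rng.integers(50, 3000))
                rs.append(make_sv(start=start, end=start + length,
                                  length=length, record_id=f"{caller}.{i}",
                                  source=caller))
            recs[caller] = rs
        loci1 = cluster_across_callsets(recs)
        shuffled = {c: list(reversed(rs)) for c, rs in recs.items()}
        loci2 = cluster_across_callsets(shuffled)
        key = lambda loci: sorted(tuple(sorted(m.record_id for m in l.members))
                                  for l in loci)
        assert key(loci1) == key(loci2)

    def test_matches_brute_force_all_pairs_transitive_closure(self):
        """Sweep-based single linkage equals brute-force all-pairs
        clustering on random records."""
        rng = np.random.default_rng(5)
        recs = {"callerA": [], "callerB": []}
        rid = 0
        for caller in recs:
            for _ in range(120):
                svtype = str(rng.choice(["DEL", "DUP", "INS"]))
                start = int(rng.integers(0, 100_000))
                length = int(rng.integers(50, 9000))
                recs[caller].append(make_sv(
                    svtype=svtype, start=start,
                    end=start + (0 if svtype == "INS" else length),
                    length=length, record_id=f"r{rid}", source=caller))
                rid += 1
        pool = recs["callerA"] + recs["callerB"]
        # brute force: union-find over ALL concordant pairs
        parent = {r.record_id: r.record_id for r in pool}
        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                if a.svtype == b.svtype and sv_concordant(a, b).concordant:
                    parent[find(a.record_id)] = find(b.record_id)
        brute = {}
        for r in pool:
            brute.setdefault(find(r.record_id), set()).add(r.record_id)
        loci = cluster_across_callsets(recs)
        got = sorted((frozenset(m.record_id for m in l.members)
                      for l in loci), key=sorted)
        want = sorted(map(frozenset, brute.values()), key=sorted)
        assert got == want


class TestBoostModel:
    def _training(self, rng, n, sep=True, backend_labels=None):
        out = []
        for i in range(n):
            label = i % 2
            sr = int(rng.poisson(8 if label else 1)) if sep else \
                int(rng.poisson(3))
            rec = make_sv(start=1000 + 200 * i, record_id=f"r{i}",
                          genotypes=[(0, 1)], sr=[sr])
            rec.evidence[0].depth = rng.normal(0.55 if label else 1.0, 0.1)
            rec.evidence[0].pe_count = int(rng.poisson(8 if label else 1))
            out.append((rec, 0, label))
        return out

    @pytest.mark.parametrize("backend", ["lightgbm", "logistic"])
    def test_separable_feature_perfect_heldout_accuracy(self, backend):
        rng = np.random.default_rng(0)
        train = []
        for i in range(200):
            label = i % 2
            rec = make_sv(start=1000 + 200 * i, record_id=f"r{i}",
                          sr=[5 + int(rng.integers(0, 5)) if label
                              else int(rng.integers(0, 2))])
            train.append((rec, 0, label))
        model = train_boost_model(train[:150], backend=backend, seed=0)
        correct = sum((model.score(rec, s) > 0.5) == label
                      for rec, s, label in train[150:])
        assert correct == 50

    def test_heldout_auc_above_point_nine(self):
        rng = np.random.default_rng(1)
        data = self._training(rng, 5000)
        model = train_boost_model(data[:4000], seed=0)
        scores = np.array([model.score(r, s) for r, s, _ in data[4000:]])
        labels = np.array([l for _, _, l in data[4000:]])
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(labels, scores) > 0.9

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        data = self._training(rng, 3000)
        perm = rng.permutation([l for _, _, l in data])
        shuffled = [(r, s, int(p)) for (r, s, _), p in zip(data, perm)]
        model = train_boost_model(shuffled[:2400], seed=0)
        scores = np.array([model.score(r, s) for r, s, _ in shuffled[2400:]])
        labels = np.array([l for _, _, l in shuffled[2400:]])
        from sklearn.metrics import roc_auc_score
        assert abs(roc_auc_score(labels, scores) - 0.5) < 0.05

    def test_single_class_training_rejected(self):
        rec = make_sv()
        with pytest.raises(CohortQCError):
            train_boost_model([(rec, 0, 1), (rec, 0, 1)])

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        data = self._training(rng, 400)
        m1 = train_boost_model(data, seed=5)
        m2 = train_boost_model(data, seed=5)
        rec, s, _ = data[0]
        assert m1.score(rec, s) == m2.score(rec, s)


class TestThreshold:
    def test_default_pass_semantics_strict(self):
        model = BoostModel(scorers={}, threshold=DEFAULT_BOOST_THRESHOLD)
        assert model.passes(0.5)
        assert not model.passes(0.448)  # exactly the threshold fails

    def test_separable_scores_yield_zero_fdr(self):
        scores = [0.9, 0.8, 0.85, 0.2, 0.1, 0.15] * 20
        labels = [1, 1, 1, 0, 0, 0] * 20
        t = select_threshold(scores, labels, target_fdr=0.05)
        picked = [l for s, l in zip(scores, labels) if s > t]
        assert picked and 1.0 - np.mean(picked) == 0.0

    def test_no_labels_falls_back_to_default(self):
        assert select_threshold([0.5], None) == DEFAULT_BOOST_THRESHOLD

    def test_unreachable_target_raises(self):
        with pytest.raises(CohortQCError):
            select_threshold([0.5, 0.6], [0, 0], target_fdr=0.05)


class TestRetention:
    def _model(self):
        return BoostModel(scorers={}, threshold=DEFAULT_BOOST_THRESHOLD)

    def _record(self, frac_fail, n=50):
        n_fail = int(round(frac_fail * n))
        boosts = [0.2] * n_fail + [0.9] * (n - n_fail)
        return make_sv(genotypes=[(0, 1)] * n, sr=None, record_id="r",
                       boost=boosts)

    def test_forty_percent_failing_included(self):
        assert retention_rule(self._record(0.40), self._model())

    def test_sixty_percent_failing_excluded(self):
        assert not retention_rule(self._record(0.60), self._model())

    def test_exactly_48_percent_excluded(self):
        assert not retention_rule(self._record(0.48), self._model())

    def test_no_carriers_excluded_with_warning(self):
        rec = make_sv(genotypes=[(0, 0), None])
        with pytest.warns(UserWarning):
            assert not retention_rule(rec, self._model())


class TestFinalRecordSelection:
    def test_split_read_count_wins(self):
        a = make_sv(record_id="a", sr=[10], boost=[0.5])
        b = make_sv(record_id="b", sr=[7], boost=[0.9])
        locus = Locus(members=[a, b], sources=("callerA", "callerB"))
        assert select_final_record(locus).record_id == "a"

    def test_sr_tie_broken_by_boost(self):
        a = make_sv(record_id="a", sr=[7], boost=[0.9])
        b = make_sv(record_id="b", sr=[7], boost=[0.7])
        locus = Locus(members=[a, b], sources=("callerA", "callerB"))
        assert select_final_record(locus).record_id == "a"

    def test_sample_support_decides_locus(self):
        a = make_sv(record_id="a", genotypes=[(0, 1)] * 100 + [(0, 0)] * 20,
                    sr=[5] * 120)
        b = make_sv(record_id="b", genotypes=[(0, 1)] * 80 + [(0, 0)] * 40,
                    sr=[5] * 120)
        locus = Locus(members=[a, b], sources=("callerA", "callerB"))
        assert select_final_record(locus).record_id == "a"

    def test_shared_insertion_prefers_designated_caller(self):
        a = make_sv(svtype="INS", record_id="a", source="callerA", sr=[10])
        b = make_sv(svtype="INS", record_id="b", source="callerB", sr=[2])
        locus = Locus(members=[a, b], sources=("callerA", "callerB"))
        assert select_final_record(
            locus, preferred_ins_source="callerB").record_id == "b"


class TestEndToEnd:
    def test_fp_enrichment_in_caller_specific_strata(self, small_cohort):
        profiles = {"callerA": CallerProfile(0.02, 0.05, 5.0),
                    "callerB": CallerProfile(0.25, 0.05, 5.0)}
        callsets, log = corrupt_callsets(small_cohort, profiles)
        loci = cluster_across_callsets(callsets)
        def fp_frac(stratum):
            recs = [m for l in loci if l.stratum == stratum
                    for m in l.members]
            return np.mean([log.is_fp(r.record_id) for r in recs])
        assert fp_frac("callerB-only") > fp_frac("shared")

    def test_training_labels_follow_truth_definition(self, small_cohort):
        callsets, log = corrupt_callsets(small_cohort)
        loci = cluster_across_callsets(callsets)
        labeled = label_from_injection(loci, small_cohort, log)
        by_label = {1: [], 0: [], None: []}
        for r, s, l in labeled:
            by_label[l].append((r, s))
        # every positive example is from a shared, non-FP record
        locus_of = {m.record_id: l for l in loci for m in l.members}
        for r, _ in by_label[1]:
            assert not log.is_fp(r.record_id)
            assert locus_of[r.record_id].stratum == "shared"
        # every negative example is caller-specific and an injected FP
        for r, _ in by_label[0]:
            assert log.is_fp(r.record_id)
            assert locus_of[r.record_id].stratum != "shared"
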