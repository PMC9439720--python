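"""HWE tests, the panel filter cascade, and the male-X ploidy fix."""

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from scipy import stats

from cohortqc import (FilterThresholds, GenomicInterval, SmallVariantSite,
                      apply_panel_filters, fix_male_x_ploidy, hwe_chisq_p,
                      hwe_exact_p, refilter_mac)
from cohortqc.panel import CRITERIA_ORDER
from conftest import make_pedigree


def hwe_exact_oracle(hom_ref, het, hom_alt):
    """Brute-force conditional enumeration with exact probabilities."""
    n = hom_ref + het + hom_alt
    rare = 2 * min(hom_ref, hom_alt) + het
    if rare == 0:
        return 1.0
    def prob(n_het):
        n_hom_rare = (rare - n_het) // 2
        n_hom_common = n - n_het - n_hom_rare
        if n_hom_rare < 0 or n_hom_common < 0:
            return 0.0
        return math.exp(
            math.lgamma(n + 1) - math.lgamma(n_het + 1)
            - math.lgamma(n_hom_rare + 1) - math.lgamma(n_hom_common + 1)
            + n_het * math.log(2)
            + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1))
    hets = [h for h in range(rare % 2, rare + 1, 2)]
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    obs = probs[het] / total
    return min(1.0, sum(p for p in probs.values()
                        if p / total <= obs * (1 + 1e-9)) / total)


class TestHweExact:
    def test_two_hets_of_two(self):
        # enumeration over het in {0, 2}: P(2)=2/3, P(0)=1/3; both <= 2/3
        assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0)

    def test_two_homs_of_two(self):
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_convention(self):
        assert hwe_exact_p(7, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(Exception):
            hwe_exact_p(-1, 2, 0)

    def test_exhaustive_enumeration_up_to_n50(self):
        """Matches the brute-force conditional distribution for every
        genotype configuration with n <= 50 (exhaustive oracle check)."""
        checked = 0
        for n in range(1, 51):
            for hom_ref, het, hom_alt in (
                    (a, b, n - a - b) for a in range(n + 1)
                    for b in range(n + 1 - a)):
                got = hwe_exact_p(hom_ref, het, hom_alt)
                want = hwe_exact_oracle(hom_ref, het, hom_alt)
                assert got == pytest.approx(want, rel=1e-8), \
                    (hom_ref, het, hom_alt)
                checked += 1
        assert checked > 20_000


class TestHweChisq:
    def test_exact_hwe_proportions_give_p_one(self):
        assert hwe_chisq_p(25, 50, 25) == pytest.approx(1.0)

    def test_complete_het_deficit_closed_form(self):
        # (50, 0, 50): AF=0.5, chi2 = sum (o-e)^2/e = 25/25+50/50+25/25? No:
        # e = (25, 50, 25); chi2 = 25 + 50 + 25 = 100 = n
        n = 100
        expected = float(stats.chi2.sf(n, df=1))
        assert hwe_chisq_p(50, 0, 50) == pytest.approx(expected)

    def test_monomorphic_convention(self):
        with pytest.warns(UserWarning):
            assert hwe_chisq_p(30, 0, 0) == 1.0

    def test_converges_to_exact_at_large_balanced_n(self):
        for het_frac in (0.4, 0.5, 0.45):
            het = int(1000 * het_frac)
            hom = (1000 - het) // 2
            p_exact = hwe_exact_p(hom, het, 1000 - het - hom)
            p_chi = hwe_chisq_p(hom, het, 1000 - het - hom)
            assert abs(p_exact - p_chi) < 0.01


def _site(gts, **kw):
    defaults = dict(chrom="chr1", pos=100, ref="A", alt="T",
                    genotypes=gts, site_id="s1")
    defaults.update(kw)
    return SmallVariantSite(**defaults)


class TestFilterCascade:
    @pytest.fixture()
    def cohort(self):
        ped = make_pedigree(n_trios=2, n_unrelated=4)
        for i, s in enumerate(ped.samples.values()):
            s.super_population = ["AFR", "EUR", "EAS", "SAS", "AMR"][i % 5]
        order = list(ped.samples)
        return ped, order

    def test_passing_site_retained(self, cohort):
        ped, order = cohort
        gts = [(0, 1), (0, 0), (0, 1), (0, 1), (0, 0), (0, 1), (0, 0),
               (0, 1), (0, 0), (0, 0)]
        retained, ledger = apply_panel_filters([_site(gts)], ped, order)
        assert len(retained) == 1
        assert ledger[0].retained and ledger[0].first_failing is None

    def test_singleton_excluded_by_mac(self, cohort):
        ped, order = cohort
        gts = [(0, 0)] * 9 + [(0, 1)]
        retained, ledger = apply_panel_filters([_site(gts)], ped, order)
        assert not retained
        assert ledger[0].first_failing == "mac"

    def test_non_pass_filter_named_first(self, cohort):
        ped, order = cohort
        gts = [(0, 0)] * 9 + [(0, 1)]  # would also fail MAC
        _, ledger = apply_panel_filters([_site(gts, filter="LOWQ")], ped, order)
        assert ledger[0].first_failing == "filter_pass"
        assert not ledger[0].verdicts["mac"]

    def test_hwe_passes_if_any_superpop_passes(self, cohort):
        """The HWE criterion is an any-super-population rule; a site in
        catastrophic HWE violation in every super-population fails."""
        n_trios, n_unrel = 0, 300
        ped = make_pedigree(n_trios, n_unrel)
        for i, s in enumerate(ped.samples.values()):
            s.super_population = ["AFR", "EUR", "EAS", "SAS", "AMR"][i % 5]
        order = list(ped.samples)
        # het-free polymorphic: extreme HWE violation everywhere
        gts = [(0, 0) if i % 2 else (1, 1) for i in range(n_unrel)]
        _, ledger = apply_panel_filters([_site(gts)], ped, order)
        assert ledger[0].first_failing == "hwe"
        # heterozygote-balanced site passes in every super-population
        gts2 = [(0, 1) if i % 2 else ((0, 0) if i % 4 else (1, 1))
                for i in range(n_unrel)]
        _, ledger2 = apply_panel_filters([_site(gts2)], ped, order)
        assert ledger2[0].verdicts["hwe"]

    def test_high_missingness_excluded(self, cohort):
        ped, order = cohort
        gts = [None, (0, 1), (0, 1), (0, 0), (0, 1), (0, 0), (0, 1),
               (0, 0), (0, 1), (0, 0)]
        _, ledger = apply_panel_filters([_site(gts)], ped, order)
        assert ledger[0].first_failing == "missingness"  # 10% >= 5%

    def test_every_exclusion_names_exactly_one_first_criterion(self, cohort):
        ped, order = cohort
        rng = np.random.default_rng(3)
        sites = []
        for i in range(100):
            gts = [tuple(rng.integers(0, 2, 2)) if rng.random() > 0.1
                   else None for _ in order]
            sites.append(_site(gts, pos=100 + i, site_id=f"s{i}"))
        _, ledger = apply_panel_filters(sites, ped, order)
        for d in ledger:
            if d.retained:
                assert d.first_failing is None
            else:
                assert d.first_failing in CRITERIA_ORDER
                # first_failing really is the first failing in cascade order
                for c in CRITERIA_ORDER:
                    if c == d.first_failing:
                        assert not d.verdicts[c]
                        break
                    assert d.verdicts[c]

    def test_vacuous_thresholds_retain_everything(self, cohort):
        ped, order = cohort
        rng = np.random.default_rng(4)
        sites = []
        for i in range(80):
            gts = [tuple(rng.integers(0, 2, 2)) if rng.random() > 0.2
                   else None for _ in order]
            filt = "PASS" if rng.random() < 0.5 else "VQSR"
            sites.append(_site(gts, pos=i, site_id=f"s{i}", filter=filt))
        retained, _ = apply_panel_filters(sites, ped, order,
                                          FilterThresholds.vacuous())
        assert len(retained) == len(sites)

    def test_post_phasing_mac_recheck(self):
        keep = _site([(0, 1), (0, 1), (0, 0)])
        drop = _site([(0, 1), (0, 0), (0, 0)], site_id="s2")
        assert refilter_mac([keep, drop]) == [keep]


class TestMaleXPloidy:
    def _x_site(self, pos, gts):
        return SmallVariantSite(chrom="chrX", pos=pos, ref="A", alt="T",
                                genotypes=gts, phased=True)

    def test_male_nonpar_diploid_becomes_haploid(self):
        ped = make_pedigree(1)  # F0 male, M0 female, C0 female
        order = ["F0", "M0", "C0"]
        site = self._x_site(50_000_000, [(0, 1), (0, 1), (1, 1)])
        fix_male_x_ploidy([site], ped, order)
        assert site.genotypes == [(1,), (0, 1), (1, 1)]

    def test_male_homref_becomes_haploid_ref(self):
        ped = make_pedigree(1)
        site = self._x_site(50_000_000, [(0, 0), (0, 1), (0, 1)])
        fix_male_x_ploidy([site], ped, ["F0", "M0", "C0"])
        assert site.genotypes[0] == (0,)

    def test_par_region_untouched(self):
        ped = make_pedigree(1)
        site = self._x_site(1_000_000, [(0, 1), (0, 1), (0, 1)])  # PAR1
        fix_male_x_ploidy([site], ped, ["F0", "M0", "C0"])
        assert site.genotypes == [(0, 1), (0, 1), (0, 1)]

    def test_already_haploid_noop_and_autosome_untouched(self):
        ped = make_pedigree(1)
        x = self._x_site(50_000_000, [(1,), (0, 1), (0, 1)])
        fix_male_x_ploidy([x], ped, ["F0", "M0", "C0"])
        assert x.genotypes[0] == (1,)
        auto = SmallVariantSite(chrom="chr1", pos=5, ref="A", alt="T",
                                genotypes=[(0, 1)])
        fix_male_x_ploidy([auto], ped, ["F0"])
        assert auto.genotypes == [(0, 1)]
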