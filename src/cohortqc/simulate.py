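"""Synthetic trio-cohort generator.

Generates trio-structured cohorts with Mendelian inheritance and a
configurable de novo rate, multi-caller SV call sets with caller-specific
false positives and breakpoint jitter, phased truth haplotypes with
injected switch/flip errors, and imputation-style posterior genotype
probabilities with controlled noise.  Every corruption emits a
machine-readable injection log so the true FP/FN/switch labels can be
recovered without re-deriving them; all outputs are reproducible from
(seed, config) alone.

The allele-frequency spectrum is a singleton point mass plus a
Beta-distributed common component; evidence features for true vs false
SVs default to well-separated Poisson/normal distributions so the boost
model is learnable at small n (the separation is configurable to probe
threshold selection).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (EvidenceFeatures, GenomicInterval, Genotype, Pedigree,
                 PedigreeSample, SVRecord, SmallVariantSite,
                 SUPER_POPULATIONS, write_pedigree, write_small_variant_vcf,
                 write_sv_vcf)

_POPS_BY_SUPER = {"AFR": "YRI", "EUR": "CEU", "EAS": "CHB", "SAS": "PJL",
                  "AMR": "PEL"}


@dataclass
class CallerProfile:
    """Error model for one synthetic SV caller."""

    fp_rate: float = 0.05   # expected FPs as a fraction of the truth count
    fn_rate: float = 0.05   # per-truth-record drop probability
    jitter_sd: float = 10.0  # breakpoint jitter sd (bp)
    # per-sample genotype error rate: carrier status flipped, evidence
    # drawn from the false distribution for spurious carriers (real
    # callers mis-genotype individual genomes, which is what makes the
    # per-genome de novo fraction a noisy, not oracular, feature)
    genotype_error_rate: float = 0.01


@dataclass
class SimulationConfig:
    n_trios: int = 30
    n_unrelated: int = 40
    n_small_sites: int = 800
    n_sv_sites: int = 300
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    # allele-frequency spectrum: singleton point mass + Beta common component
    singleton_mass: float = 0.15
    af_beta_a: float = 0.5
    af_beta_b: float = 2.0
    # de novo rate per child: fraction of a child's non-reference variants
    # that are de novo (prior short-read WGS estimates put this at 0.2-0.5%)
    de_novo_rate: float = 0.003
    sv_de_novo_rate: float = 0.003
    # per-caller SV corruption
    callers: dict[str, CallerProfile] = field(default_factory=lambda: {
        "callerA": CallerProfile(), "callerB": CallerProfile()})
    # evidence-feature distributions for true vs false SVs
    true_sr_mean: float = 8.0
    false_sr_mean: float = 1.0
    true_pe_mean: float = 8.0
    false_pe_mean: float = 1.0
    depth_sd: float = 0.08
    # haplotype corruption
    switch_rate: float = 0.01      # per het-het junction
    flip_rate: float = 0.0         # isolated single-site flips
    # imputation-style posterior noise
    gp_noise: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        rates = [self.singleton_mass, self.de_novo_rate, self.sv_de_novo_rate,
                 self.switch_rate, self.flip_rate, self.gp_noise]
        rates += [c.fp_rate for c in self.callers.values()]
        rates += [c.fn_rate for c in self.callers.values()]
        rates += [c.genotype_error_rate for c in self.callers.values()]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if any(c.jitter_sd < 0 for c in self.callers.values()):
            raise ValueError("jitter sd must be >= 0")
        if self.n_trios + self.n_unrelated == 0:
            raise ValueError("cohort must contain at least one sample")


@dataclass
class SyntheticCohort:
    """Truth cohort: pedigree, phased small variants, SVs, and draw logs."""

    config: SimulationConfig
    pedigree: Pedigree
    sample_order: list[str]
    small_sites: list[SmallVariantSite]
    haplotypes: np.ndarray          # (n_small_sites, n_samples, 2)
    sv_records: list[SVRecord]
    sv_haplotypes: np.ndarray       # (n_sv, n_samples, 2)
    de_novo_log: dict[str, list[tuple[int, int]]]
    #: parental origin of child haplotype 1 is always the father by
    #: construction (hap 1 paternal, hap 2 maternal)

    @property
    def n_samples(self) -> int:
        return len(self.sample_order)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "small_vcf": outdir / "truth.small.vcf",
            "sv_vcf": outdir / "truth.sv.vcf",
            "ped": outdir / "cohort.ped",
            "de_novo_log": outdir / "de_novo_log.json",
        }
        write_small_variant_vcf(paths["small_vcf"], self.small_sites,
                                self.sample_order)
        write_sv_vcf(paths["sv_vcf"], self.sv_records, self.sample_order)
        write_pedigree(paths["ped"], self.pedigree)
        with open(paths["de_novo_log"], "w") as fh:
            json.dump({k: [list(t) for t in v]
                       for k, v in self.de_novo_log.items()}, fh, indent=1)
        return paths


def _make_pedigree(config: SimulationConfig) -> tuple[Pedigree, list[str]]:
    samples: dict[str, PedigreeSample] = {}
    order: list[str] = []
    supers = SUPER_POPULATIONS
    for t in range(config.n_trios):
        sp = supers[t % len(supers)]
        pop = _POPS_BY_SUPER[sp]
        fid, mid, cid = f"T{t:04d}_F", f"T{t:04d}_M", f"T{t:04d}_C"
        samples[fid] = PedigreeSample(fid, None, None, "male", pop, sp)
        samples[mid] = PedigreeSample(mid, None, None, "female", pop, sp)
        child_sex = "male" if t % 2 == 0 else "female"
        samples[cid] = PedigreeSample(cid, fid, mid, child_sex, pop, sp)
        order += [fid, mid, cid]
    for u in range(config.n_unrelated):
        sp = supers[u % len(supers)]
        sid = f"U{u:04d}"
        samples[sid] = PedigreeSample(sid, None, None,
                                      "male" if u % 2 else "female",
                                      _POPS_BY_SUPER[sp], sp)
        order.append(sid)
    return Pedigree(samples), order


def _draw_afs(rng: np.random.Generator, n: int, config: SimulationConfig,
              n_haplotypes: int) -> np.ndarray:
    afs = rng.beta(config.af_beta_a, config.af_beta_b, size=n)
    single = rng.random(n) < config.singleton_mass
    afs[single] = 1.0 / n_haplotypes
    return afs


def _founder_haplotypes(rng: np.random.Generator, afs: np.ndarray,
                        n_founders: int) -> np.ndarray:
    return (rng.random((len(afs), n_founders, 2)) < afs[:, None, None]
            ).astype(np.int8)


def _transmit(rng: np.random.Generator, parent_haps: np.ndarray) -> np.ndarray:
    """Per-site random transmitted allele (meiosis without linkage)."""
    n_sites = parent_haps.shape[0]
    pick = rng.integers(0, 2, size=n_sites)
    return parent_haps[np.arange(n_sites), pick]


def _inject_de_novo(rng: np.random.Generator, haps: np.ndarray,
                    child_idx: Sequence[tuple[int, int, int]],
                    rate: float) -> list[tuple[int, int]]:
    """Flip hom-ref child alleles to alt so that the expected fraction of
    the child's non-reference variants that are de novo equals ``rate``.

    The per-candidate injection probability is calibrated per child from
    its inherited non-ref count k: with c candidate sites, q = k*rate /
    ((1-rate)*c) gives E[#de novo] = k*rate/(1-rate), hence an expected de
    novo fraction of ``rate``.  Every injection is logged.
    """
    log: list[tuple[int, int]] = []
    if rate <= 0:
        return log
    for ci, fi, mi in child_idx:
        child = haps[:, ci, :]
        nonref = (child.sum(axis=1) > 0)
        parents_ref = (haps[:, fi, :].sum(axis=1) == 0) & \
                      (haps[:, mi, :].sum(axis=1) == 0)
        candidates = np.flatnonzero(~nonref & parents_ref)
        k = int(nonref.sum())
        if k == 0 or len(candidates) == 0:
            continue
        q = min(1.0, k * rate / ((1.0 - rate) * len(candidates)))
        hits = candidates[rng.random(len(candidates)) < q]
        for site in hits:
            haps[site, ci, rng.integers(0, 2)] = 1
            log.append((int(site), int(ci)))
    return log


def _haps_to_genotypes(haps: np.ndarray) -> list[list[Genotype]]:
    """Phased genotype tuples per site (list over sites of lists over samples)."""
    return [[(int(h[0]), int(h[1])) for h in site] for site in haps]


_SVTYPE_WEIGHTS = {"DEL": 0.45, "DUP": 0.15, "INS": 0.30, "INV": 0.10}


def _draw_sv_shape(rng: np.random.Generator) -> tuple[str, int]:
    svtype = rng.choice(list(_SVTYPE_WEIGHTS), p=list(_SVTYPE_WEIGHTS.values()))
    # ALU-to-LINE1-like size range; ~15% exceed the 5 kb size-class boundary
    length = int(np.clip(rng.lognormal(mean=6.6, sigma=1.2), 60, 200_000))
    return str(svtype), length


def _evidence(rng: np.random.Generator, config: SimulationConfig,
              svtype: str, is_true: bool, carrier: bool) -> EvidenceFeatures:
    sr_mean = config.true_sr_mean if is_true else config.false_sr_mean
    pe_mean = config.true_pe_mean if is_true else config.false_pe_mean
    if not carrier:
        sr_mean = pe_mean = 0.2
    depth = 1.0
    if carrier and is_true:
        depth = {"DEL": 0.55, "DUP": 1.45}.get(svtype, 1.0)
    return EvidenceFeatures(
        depth=float(max(0.0, rng.normal(depth, config.depth_sd))),
        flank_depth=float(max(0.0, rng.normal(1.0, config.depth_sd / 2))),
        pe_count=int(rng.poisson(pe_mean)),
        sr_count=int(rng.poisson(sr_mean)))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the truth cohort (small variants, SVs, phased haplotypes).

    Children's genotypes are Mendelian-consistent with their parents
    except at logged de novo sites; child haplotype 1 is paternal and
    haplotype 2 maternal by construction, so parental origin is recorded
    for every child allele.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ped, order = _make_pedigree(config)
    n = len(order)
    idx = {sid: i for i, sid in enumerate(order)}
    founders = [i for i, sid in enumerate(order)
                if ped.samples[sid].role != "child"]
    trio_idx = [(idx[c], idx[f], idx[m]) for c, f, m in ped.trios]

    def build(n_sites: int, positions: np.ndarray, de_novo_rate: float
              ) -> tuple[np.ndarray, list[tuple[int, int]]]:
        afs = _draw_afs(rng, n_sites, config, 2 * len(founders))
        haps = np.zeros((n_sites, n, 2), dtype=np.int8)
        fh = _founder_haplotypes(rng, afs, len(founders))
        for j, fi in enumerate(founders):
            haps[:, fi, :] = fh[:, j, :]
        for ci, fi, mi in trio_idx:
            haps[:, ci, 0] = _transmit(rng, haps[:, fi, :])  # paternal
            haps[:, ci, 1] = _transmit(rng, haps[:, mi, :])  # maternal
        log = _inject_de_novo(rng, haps, trio_idx, de_novo_rate)
        return haps, log

    # small variants (distinct positions, rejection-sampled)
    small_pos = np.unique(rng.integers(
        1_000_000, config.chrom_length,
        size=3 * config.n_small_sites + 100))
    while len(small_pos) < config.n_small_sites:
        small_pos = np.unique(np.concatenate([
            small_pos,
            rng.integers(1_000_000, config.chrom_length,
                         size=config.n_small_sites)]))
    small_pos = np.sort(rng.choice(small_pos, size=config.n_small_sites,
                                   replace=False))
    small_haps, small_dn = build(config.n_small_sites, small_pos,
                                 config.de_novo_rate)
    bases = np.array(list("ACGT"))
    small_sites = []
    gts = _haps_to_genotypes(small_haps)
    for i, pos in enumerate(small_pos):
        ref, alt = rng.choice(bases, size=2, replace=False)
        small_sites.append(SmallVariantSite(
            chrom=config.chrom, pos=int(pos), ref=str(ref), alt=str(alt),
            genotypes=list(gts[i]), phased=True, site_id=f"snv{i:06d}"))

    # SVs: spaced >= 20 kb apart so distinct truth loci never cluster
    gap = max(20_000, (config.chrom_length - 2_000_000) // max(config.n_sv_sites, 1))
    sv_start = 1_000_000 + rng.integers(0, gap // 2, size=config.n_sv_sites) \
        + np.arange(config.n_sv_sites) * gap
    sv_haps, sv_dn = build(config.n_sv_sites, sv_start, config.sv_de_novo_rate)
    sv_gts = _haps_to_genotypes(sv_haps)
    sv_records = []
    for i in range(config.n_sv_sites):
        svtype, length = _draw_sv_shape(rng)
        start = int(sv_start[i])
        end = start if svtype == "INS" else start + length
        rec = SVRecord(
            interval=GenomicInterval(config.chrom, start, end),
            svtype=svtype, length=length, source="truth",
            record_id=f"sv{i:05d}", genotypes=list(sv_gts[i]), phased=True,
            genomic_context=str(rng.choice(
                ["unique", "repeat-masked", "short-repeat",
                 "segmental-duplication"], p=[0.6, 0.2, 0.12, 0.08])))
        carriers = set(rec.carriers())
        rec.evidence = [_evidence(rng, config, svtype, True, s in carriers)
                        for s in range(n)]
        sv_records.append(rec)

    return SyntheticCohort(
        config=config, pedigree=ped, sample_order=order,
        small_sites=small_sites, haplotypes=small_haps,
        sv_records=sv_records, sv_haplotypes=sv_haps,
        de_novo_log={"small": small_dn, "sv": sv_dn})


# ---------------------------------------------------------------------------
# Call-set corruption
# ---------------------------------------------------------------------------

@dataclass
class CallsetInjectionLog:
    """Which emitted records are FPs, which truth records were dropped,
    and which per-sample genotypes were corrupted."""

    records: dict[str, dict[str, dict]]   # caller -> record_id -> {truth_id, is_fp}
    false_negatives: dict[str, list[str]]  # caller -> dropped truth ids
    genotype_errors: dict[str, list[list]] = field(default_factory=dict)
    # caller -> [[record_id, sample_index], ...]

    def is_fp(self, record_id: str) -> bool:
        caller = record_id.split(".", 1)[0]
        return bool(self.records[caller][record_id]["is_fp"])

    def truth_of(self, record_id: str) -> str | None:
        caller = record_id.split(".", 1)[0]
        return self.records[caller][record_id]["truth_id"]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"records": self.records,
                       "false_negatives": self.false_negatives,
                       "genotype_errors": self.genotype_errors}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CallsetInjectionLog":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["records"], d["false_negatives"],
                   d.get("genotype_errors", {}))


def corrupt_callsets(cohort: SyntheticCohort,
                     callers: dict[str, CallerProfile] | None = None,
                     ) -> tuple[dict[str, list[SVRecord]], CallsetInjectionLog]:
    """Derive per-caller SV call sets from the truth.

    Each caller's output is the truth minus false-negative draws, plus
    false positives with evidence from the false-SV distribution, with
    breakpoints jittered N(0, sd).  Record ids are ``caller.ruNNNN`` so
    the injection log can be keyed by caller.
    """
    config = cohort.config
    callers = callers or config.callers
    rng = np.random.default_rng(config.seed + 1)
    n = cohort.n_samples
    out: dict[str, list[SVRecord]] = {}
    log_records: dict[str, dict[str, dict]] = {}
    log_fn: dict[str, list[str]] = {}
    log_gterr: dict[str, list[list]] = {}
    for caller, prof in callers.items():
        recs: list[SVRecord] = []
        log_records[caller] = {}
        log_fn[caller] = []
        log_gterr[caller] = []
        lost_concordance = 0
        for truth in cohort.sv_records:
            if rng.random() < prof.fn_rate:
                log_fn[caller].append(truth.record_id)
                continue
            if truth.svtype == "INS":
                start = max(0, truth.start + int(round(rng.normal(0, prof.jitter_sd))))
                end = start
                length = max(1, truth.length + int(round(rng.normal(0, prof.jitter_sd))))
            else:
                start = max(0, truth.start + int(round(rng.normal(0, prof.jitter_sd))))
                end = truth.end + int(round(rng.normal(0, prof.jitter_sd)))
                if end <= start:
                    end = start + 1
                length = end - start
                ro = (min(end, truth.end) - max(start, truth.start)) / max(
                    length, truth.length)
                cutoff = 0.5 if max(length, truth.length) > 5000 else 0.1
                if ro < cutoff:
                    lost_concordance += 1
            rid = f"{caller}.{truth.record_id}"
            gts = list(truth.genotypes)
            spurious: set[int] = set()
            for s in range(n):
                if gts[s] is not None and \
                        rng.random() < prof.genotype_error_rate:
                    if any(a == 1 for a in gts[s]):
                        gts[s] = (0, 0)
                    else:
                        gts[s] = (0, 1)
                        spurious.add(s)
                    log_gterr[caller].append([rid, s])
            carriers = {s for s in range(n) if gts[s] is not None
                        and any(a == 1 for a in gts[s])}
            rec = SVRecord(
                interval=GenomicInterval(truth.chrom, start, end),
                svtype=truth.svtype, length=length, source=caller,
                record_id=rid, genotypes=gts,
                genomic_context=truth.genomic_context,
                evidence=[_evidence(rng, config, truth.svtype,
                                    s not in spurious, s in carriers)
                          for s in range(n)])
            recs.append(rec)
            log_records[caller][rid] = {"truth_id": truth.record_id,
                                        "is_fp": False}
        if cohort.sv_records and lost_concordance / len(cohort.sv_records) > 0.5:
            warnings.warn(f"{caller}: jitter sd {prof.jitter_sd} breaks "
                          "concordance for >50% of true pairs")
        n_fp = rng.poisson(prof.fp_rate * len(cohort.sv_records))
        for j in range(n_fp):
            svtype, length = _draw_sv_shape(rng)
            start = int(rng.integers(1_000_000, config.chrom_length))
            end = start if svtype == "INS" else start + length
            gts: list[Genotype] = [(0, 0)] * n
            # FPs are recurrent systematic artifacts: carrier sets follow
            # the same frequency spectrum as real variants rather than
            # appearing in isolated genomes
            af = float(_draw_afs(rng, 1, config, 2 * n)[0])
            k = max(1, int(rng.binomial(n, af)))
            carriers = set(rng.choice(n, size=min(k, n), replace=False))
            for s in carriers:
                gts[s] = (0, 1)
            rid = f"{caller}.fp{j:05d}"
            recs.append(SVRecord(
                interval=GenomicInterval(config.chrom, start, end),
                svtype=svtype, length=length, source=caller, record_id=rid,
                genotypes=gts,
                evidence=[_evidence(rng, config, svtype, False, s in carriers)
                          for s in range(n)]))
            log_records[caller][rid] = {"truth_id": None, "is_fp": True}
        out[caller] = sorted(recs, key=lambda r: (r.chrom, r.start, r.record_id))
    return out, CallsetInjectionLog(log_records, log_fn, log_gterr)


# ---------------------------------------------------------------------------
# Phasing corruption
# ---------------------------------------------------------------------------

@dataclass
class PhasingInjectionLog:
    """Injected switch junctions and isolated flips, per sample index."""

    switches: dict[int, list[int]]  # sample -> het-junction indices toggled
    flips: dict[int, list[int]]     # sample -> site indices flipped


def corrupt_phasing(haplotypes: np.ndarray, switch_rate: float,
                    flip_rate: float = 0.0, seed: int = 0,
                    ) -> tuple[np.ndarray, PhasingInjectionLog]:
    """Inject switch and flip errors into phased truth haplotypes.

    Switch errors are Markov orientation toggles at each junction between
    consecutive heterozygous sites (per sample); isolated single-site
    flips are injected independently on top.
    """
    if not (0.0 <= switch_rate <= 1.0 and 0.0 <= flip_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = haplotypes.copy()
    n_sites, n_samples, _ = haplotypes.shape
    log = PhasingInjectionLog({}, {})
    for s in range(n_samples):
        het = np.flatnonzero(haplotypes[:, s, 0] != haplotypes[:, s, 1])
        if len(het) == 0:
            continue
        orient = 0
        switched: list[int] = []
        for j in range(1, len(het)):
            if rng.random() < switch_rate:
                orient ^= 1
                switched.append(j - 1)
            if orient:
                out[het[j], s, :] = out[het[j], s, ::-1]
        flipped = [int(i) for i in het if rng.random() < flip_rate]
        for i in flipped:
            out[i, s, :] = out[i, s, ::-1]
        if switched:
            log.switches[s] = switched
        if flipped:
            log.flips[s] = flipped
    return out, log


# ---------------------------------------------------------------------------
# Dual-genotyper corruption
# ---------------------------------------------------------------------------

def corrupt_genotypers(truth_gts: dict[str, list[Genotype]],
                       error_rate: float, seed: int = 0,
                       gq_high: float = 250.0,
                       ) -> tuple[dict[str, list[Genotype]],
                                  dict[str, list[float]],
                                  dict[str, list[Genotype]],
                                  dict[str, str],
                                  dict[str, list[tuple[str, int]]]]:
    """Two independent genotypers as corrupted copies of the truth.

    Each genotyper replaces a diploid genotype with one of the two other
    genotypes (uniformly) with probability ``error_rate``, independently.
    Genotyper A reports GQ (high for all sites here), genotyper B a PASS
    filter; the error log records every corrupted (site, sample) pair per
    genotyper.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gts_a: dict[str, list[Genotype]] = {}
    gts_b: dict[str, list[Genotype]] = {}
    gqs_a: dict[str, list[float]] = {}
    filters_b: dict[str, str] = {}
    log: dict[str, list[tuple[str, int]]] = {"A": [], "B": []}
    alternatives = {0: [(0, 1), (1, 1)], 1: [(0, 0), (1, 1)],
                    2: [(0, 0), (0, 1)]}
    for site_id, gts in truth_gts.items():
        out_a, out_b, gq = [], [], []
        for s, gt in enumerate(gts):
            for caller, out in (("A", out_a), ("B", out_b)):
                if gt is not None and rng.random() < error_rate:
                    wrong = alternatives[sum(gt)][rng.integers(0, 2)]
                    out.append(wrong)
                    log[caller].append((site_id, s))
                else:
                    out.append(gt)
            gq.append(gq_high)
        gts_a[site_id] = out_a
        gts_b[site_id] = out_b
        gqs_a[site_id] = gq
        filters_b[site_id] = "PASS"
    return gts_a, gqs_a, gts_b, filters_b, log


# ---------------------------------------------------------------------------
# Imputation-style posteriors
# ---------------------------------------------------------------------------

def simulate_imputation_output(genotype_dosages: np.ndarray, noise: float,
                               seed: int = 0) -> np.ndarray:
    """Posterior genotype-probability triples for a truth dosage matrix.

    ``genotype_dosages`` holds 0/1/2 truth genotypes, shape (sites,
    samples); returns (sites, samples, 3) triples summing to 1,
    concentrated on the truth genotype.  The mass moved off the truth
    genotype is noise * U(0,1) per entry, split randomly between the two
    other genotypes; noise 0 yields degenerate (one-hot) triples.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sites, n_samples = genotype_dosages.shape
    probs = np.zeros((n_sites, n_samples, 3))
    g = genotype_dosages.astype(int)
    eps = noise * rng.random((n_sites, n_samples))
    split = rng.random((n_sites, n_samples))
    for k in range(3):
        probs[..., k] = np.where(g == k, 1.0 - eps, 0.0)
    others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    for k in range(3):
        a, b = others[k]
        mask = g == k
        probs[..., a] += np.where(mask, eps * split, 0.0)
        probs[..., b] += np.where(mask, eps * (1 - split), 0.0)
    return probs
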