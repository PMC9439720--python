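"""Domain types and readers/writers for VCF/BED/PED.

All internal coordinates are 0-based half-open; VCF positions (1-based)
are converted at the read/write boundary and BED is consumed natively.
Haploid genotypes are first-class (male non-PAR X, chrY) and missing is a
distinct state, never conflated with homozygous reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

SUPER_POPULATIONS = ("AFR", "EUR", "EAS", "SAS", "AMR")

#: genotype = tuple of allele indices, or None when missing.
#: Length 1 encodes haploid calls; ``phased`` is tracked per record.
Genotype = tuple[int, ...] | None

SV_TYPES = ("DEL", "DUP", "mCNV", "INS", "INV", "CPX", "CTX")


class CohortQCError(ValueError):
    """Raised for malformed inputs (duplicate samples, bad regions, ...)."""


# ---------------------------------------------------------------------------
# Intervals and region stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval; insertion points have ``end == start``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CohortQCError(
                f"interval end < start: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RegionStratification:
    """Easy/difficult (and optional high-confidence) genome stratification.

    ``easy`` and ``difficult`` must be disjoint and together cover the
    declared reference space, making :meth:`classify` total over it.
    """

    easy: dict[str, IntervalTree]
    difficult: dict[str, IntervalTree]
    high_confidence: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        easy: Iterable[GenomicInterval],
        difficult: Iterable[GenomicInterval],
        high_confidence: Iterable[GenomicInterval] = (),
    ) -> "RegionStratification":
        return cls(_build_trees(easy), _build_trees(difficult),
                   _build_trees(high_confidence))

    def classify(self, variant: GenomicInterval) -> str:
        """Classify a variant as ``"easy"`` or ``"difficult"``.

        SNVs (length-1 intervals) are classified by their single base; any
        length-bearing variant that touches at least one difficult base —
        which includes anything spanning an easy/difficult border — is
        difficult.
        """
        span = variant if variant.length > 0 else replace(
            variant, end=variant.start + 1)
        diff = self.difficult.get(span.chrom)
        easy = self.easy.get(span.chrom)
        if diff is None and easy is None:
            raise CohortQCError(
                f"chromosome {span.chrom!r} not in the declared stratification")
        if diff is not None and diff.overlap(span.start, span.end):
            return "difficult"
        if easy is not None and easy.overlap(span.start, span.end):
            # total classification: every base must be declared
            covered = sorted(iv for iv in easy.overlap(span.start, span.end))
            pos = span.start
            for iv in covered:
                if iv.begin > pos:
                    raise CohortQCError(
                        f"{span.chrom}:{pos} outside the declared reference space")
                pos = max(pos, iv.end)
            if pos < span.end:
                raise CohortQCError(
                    f"{span.chrom}:{pos} outside the declared reference space")
            return "easy"
        raise CohortQCError(
            f"{span.chrom}:{span.start} outside the declared reference space")

    def in_high_confidence(self, variant: GenomicInterval) -> bool:
        tree = self.high_confidence.get(variant.chrom)
        if tree is None:
            return False
        span_end = variant.end if variant.length > 0 else variant.start + 1
        return bool(tree.overlap(variant.start, span_end))


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if iv.length <= 0:
            raise CohortQCError(f"zero-length stratification interval: {iv}")
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 intervals (native 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSample:
    sample_id: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female"
    population: str = ""
    super_population: str = ""
    role: str = "unrelated"  # derived: child | parent | unrelated
    is_duo_child: bool = False


@dataclass
class Pedigree:
    """Cohort pedigree with derived child/parent/unrelated roles.

    A sample is a *child* iff both its parents are present in the cohort; a
    *parent* iff it is a listed parent of a present child and not itself a
    child; everything else is *unrelated*.  Children with exactly one parent
    present (duos) are classified unrelated for singleton accounting but
    carry ``is_duo_child``.
    """

    samples: dict[str, PedigreeSample]

    def __post_init__(self) -> None:
        self._derive_roles()

    def _derive_roles(self) -> None:
        present = self.samples
        children = set()
        for s in present.values():
            n_present = sum(p in present for p in (s.father, s.mother) if p)
            if s.father and s.mother and s.father in present and s.mother in present:
                children.add(s.sample_id)
            s.is_duo_child = (
                n_present == 1
                or (n_present == 0 and bool(s.father) != bool(s.mother)))
            if s.father == s.sample_id or s.mother == s.sample_id:
                raise CohortQCError(f"sample {s.sample_id} is its own parent")
        parents = set()
        for cid in children:
            parents.add(present[cid].father)
            parents.add(present[cid].mother)
        for s in present.values():
            if s.sample_id in children:
                s.role = "child"
            elif s.sample_id in parents:
                s.role = "parent"
            else:
                s.role = "unrelated"
        self._check_no_ancestor_cycle()

    def _check_no_ancestor_cycle(self) -> None:
        for sid in self.samples:
            seen = set()
            stack = [sid]
            while stack:
                cur = stack.pop()
                s = self.samples.get(cur)
                if s is None:
                    continue
                for p in (s.father, s.mother):
                    if p == sid:
                        raise CohortQCError(f"sample {sid} is its own ancestor")
                    if p and p not in seen:
                        seen.add(p)
                        stack.append(p)

    @property
    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) for every complete trio."""
        return [(s.sample_id, s.father, s.mother)
                for s in self.samples.values() if s.role == "child"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def role_of(self, sample_id: str) -> str:
        return self.samples[sample_id].role

    def sex_of(self, sample_id: str) -> str:
        return self.samples[sample_id].sex


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6+-column PED file (optionally with population columns).

    Columns: family, sample, father, mother, sex (1=male, 2=female),
    phenotype, then optionally population and super-population.
    Parent ids referenced but absent from the file are kept as external;
    the child is classified by the presence of BOTH parents in the cohort.
    """
    samples: dict[str, PedigreeSample] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise CohortQCError(f"PED row has <6 columns: {line!r}")
            _fam, sid, father, mother, sex, _pheno = fields[:6]
            if sid in samples:
                raise CohortQCError(f"duplicate sample id {sid!r} in PED")
            samples[sid] = PedigreeSample(
                sample_id=sid,
                father=None if father in ("0", ".", "") else father,
                mother=None if mother in ("0", ".", "") else mother,
                sex={"1": "male", "2": "female"}.get(sex, "female"),
                population=fields[6] if len(fields) > 6 else "",
                super_population=fields[7] if len(fields) > 7 else "",
            )
    return Pedigree(samples)


def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for s in ped.samples.values():
            sex = "1" if s.sex == "male" else "2"
            fh.write("\t".join([
                "FAM_" + s.sample_id, s.sample_id, s.father or "0",
                s.mother or "0", sex, "-9", s.population,
                s.super_population]) + "\n")


# ---------------------------------------------------------------------------
# Small variants
# ---------------------------------------------------------------------------

@dataclass
class SmallVariantSite:
    """One biallelic small-variant allele with per-sample genotypes.

    ``pos`` is 0-based internally (converted from the 1-based VCF POS at the
    boundary).  Genotypes may be diploid, haploid, or missing (None).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter: str = "PASS"
    genotypes: list[Genotype] = field(default_factory=list)
    phased: bool = False
    site_id: str = ""
    hwe_p: dict[str, float] = field(default_factory=dict)
    mer: float | None = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.ref))

    def allele_counts(self) -> tuple[int, int]:
        """(AC, AN) over all non-missing alleles."""
        ac = an = 0
        for gt in self.genotypes:
            if gt is None:
                continue
            an += len(gt)
            ac += sum(1 for a in gt if a == 1)
        return ac, an

    @property
    def ac(self) -> int:
        return self.allele_counts()[0]

    @property
    def an(self) -> int:
        return self.allele_counts()[1]

    @property
    def af(self) -> float:
        ac, an = self.allele_counts()
        return ac / an if an else float("nan")

    @property
    def mac(self) -> int:
        ac, an = self.allele_counts()
        return min(ac, an - ac)

    @property
    def missingness(self) -> float:
        n = len(self.genotypes)
        if n == 0:
            return 0.0
        return sum(1 for gt in self.genotypes if gt is None) / n

    def genotype_counts(self, sample_idx: Sequence[int] | None = None
                        ) -> tuple[int, int, int]:
        """(hom_ref, het, hom_alt) over diploid genotypes."""
        idx = range(len(self.genotypes)) if sample_idx is None else sample_idx
        hr = het = ha = 0
        for i in idx:
            gt = self.genotypes[i]
            if gt is None or len(gt) != 2:
                continue
            n_alt = sum(1 for a in gt if a == 1)
            if n_alt == 0:
                hr += 1
            elif n_alt == 1:
                het += 1
            else:
                ha += 1
        return hr, het, ha


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize by allele trimming: shared suffix, then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VcfRow:
    """A raw (possibly multiallelic) small-variant VCF row."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    filter: str = "PASS"
    genotypes: list[Genotype] = field(default_factory=list)
    phased: bool = False
    site_id: str = ""


def split_multiallelics(rows: Iterable[VcfRow]) -> list[SmallVariantSite]:
    """Split multiallelic rows into biallelic, left-normalized records.

    Genotypes are recoded against the retained alt: the target allele maps
    to 1 and every other allele (reference or other alt) to 0, preserving
    order and ploidy.  Symbolic alleles are rejected — they belong in the
    SV stream.
    """
    out: list[SmallVariantSite] = []
    for row in rows:
        for k, alt in enumerate(row.alts, start=1):
            if alt.startswith("<") or alt in ("*",):
                raise CohortQCError(
                    f"symbolic allele {alt!r} at {row.chrom}:{row.pos + 1}: "
                    "route symbolic/SV alleles through the SV stream")
            pos, ref, a = _trim_alleles(row.pos, row.ref, alt)
            gts: list[Genotype] = []
            for gt in row.genotypes:
                if gt is None:
                    gts.append(None)
                else:
                    gts.append(tuple(1 if al == k else 0 for al in gt))
            sid = row.site_id or f"{row.chrom}:{row.pos + 1}"
            out.append(SmallVariantSite(
                chrom=row.chrom, pos=pos, ref=ref, alt=a, filter=row.filter,
                genotypes=gts, phased=row.phased,
                site_id=f"{sid}:{k}" if len(row.alts) > 1 else sid))
    return out


class PositionDisambiguator:
    """Reversible keys for same-start split records.

    Phasing tools require distinct start positions; rather than mutating
    coordinates (which would corrupt overlap math), each record gets a
    unique integer sort key that can be mapped back to the original
    coordinate afterwards.
    """

    def __init__(self) -> None:
        self._forward: dict[str, tuple[str, int, int]] = {}

    def assign(self, sites: Sequence[SmallVariantSite]) -> dict[str, int]:
        """Assign per-record unique keys; same-start records get offsets
        increased by the minimum possible number of steps (0, 1, 2, ...)."""
        seen: dict[tuple[str, int], int] = {}
        keys: dict[str, int] = {}
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.site_id)):
            off = seen.get((s.chrom, s.pos), 0)
            seen[(s.chrom, s.pos)] = off + 1
            keys[s.site_id] = s.pos + off
            self._forward[s.site_id] = (s.chrom, s.pos, off)
        return keys

    def restore(self, site_id: str) -> tuple[str, int]:
        chrom, pos, _ = self._forward[site_id]
        return chrom, pos


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

@dataclass
class EvidenceFeatures:
    """Per-sample read evidence backing one SV call."""

    depth: float = 1.0        # normalized depth over the SV span
    flank_depth: float = 1.0  # normalized depth of the 1 kb flanks
    pe_count: int = 0         # aberrant pair-ends within 150 bp of the SV
    sr_count: int = 0         # split reads within 100 bp of each breakpoint


GENOMIC_CONTEXTS = ("short-repeat", "segmental-duplication", "repeat-masked",
                    "unique")


@dataclass
class SVRecord:
    """One SV allele with genotypes, evidence, and (after scoring) a boost
    score in [0, 1].  Insertions carry a point coordinate (end == start)
    plus a separate inserted-sequence length; reciprocal overlap is
    undefined for INS by construction."""

    interval: GenomicInterval
    svtype: str
    length: int
    source: str = ""
    record_id: str = ""
    genotypes: list[Genotype] = field(default_factory=list)
    phased: bool = False
    evidence: list[EvidenceFeatures] = field(default_factory=list)
    genomic_context: str = "unique"
    boost_scores: list[float | None] = field(default_factory=list)
    de_novo_fraction: float = 0.0
    info: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise CohortQCError(f"unknown SVTYPE {self.svtype!r}")
        if self.length <= 0:
            raise CohortQCError(f"SV length must be positive: {self.record_id}")
        if self.svtype in ("DEL", "DUP", "INV") and \
                self.length != self.interval.length:
            raise CohortQCError(
                f"{self.svtype} length must equal end-start: {self.record_id}")
        if self.svtype == "INS" and self.interval.length != 0:
            raise CohortQCError(
                f"INS must use a point coordinate: {self.record_id}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def carriers(self) -> list[int]:
        """Indices of samples with a non-reference, non-missing genotype."""
        return [i for i, gt in enumerate(self.genotypes)
                if gt is not None and any(a == 1 for a in gt)]

    def allele_fraction(self) -> float:
        ac = an = 0
        for gt in self.genotypes:
            if gt is None:
                continue
            an += len(gt)
            ac += sum(1 for a in gt if a == 1)
        return ac / an if an else 0.0


# ---------------------------------------------------------------------------
# VCF reading/writing (pysam at the boundary)
# ---------------------------------------------------------------------------

_SMALL_HEADER_LINES = [
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_SV_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    '##INFO=<ID=SOURCES,Number=.,Type=String,Description="Contributing call sets">',
    '##INFO=<ID=STRATUM,Number=1,Type=String,Description="Call-set membership stratum">',
    '##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Genomic context class">',
    '##INFO=<ID=DNFRAC,Number=1,Type=Float,Description="De novo fraction among observed trios">',
    '##INFO=<ID=WINNER,Number=1,Type=String,Description="Winning record id">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DPR,Number=1,Type=Float,Description="Normalized SV depth">',
    '##FORMAT=<ID=DPF,Number=1,Type=Float,Description="Normalized 1kb flank depth">',
    '##FORMAT=<ID=PE,Number=1,Type=Integer,Description="Pair-end count within 150bp">',
    '##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Split-read count within 100bp of breakpoints">',
    '##FORMAT=<ID=BS,Number=1,Type=Float,Description="Boost score">',
]


def _make_header(samples: Sequence[str], contigs: Sequence[str],
                 extra_lines: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in contigs:
        header.contigs.add(chrom, length=2_000_000_000)
    for line in extra_lines:
        header.add_line(line)
    for s in samples:
        header.add_sample(s)
    return header


def _format_gt(gt: Genotype, phased: bool) -> str:
    if gt is None:
        return "."
    sep = "|" if phased else "/"
    return sep.join(str(a) for a in gt)


def _parse_gt(value) -> tuple[Genotype, bool]:
    # pysam yields tuples of allele ints (None for missing)
    alleles = [a for a in value if a is not None] if value else []
    if not alleles and (not value or all(a is None for a in value)):
        return None, False
    return tuple(alleles), True


def write_small_variant_vcf(path: str | Path, sites: Sequence[SmallVariantSite],
                            samples: Sequence[str]) -> None:
    contigs = sorted({s.chrom for s in sites})
    header = _make_header(samples, contigs, _SMALL_HEADER_LINES)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.site_id)):
            rec = vf.new_record(contig=s.chrom, start=s.pos,
                                alleles=(s.ref, s.alt), id=s.site_id or None)
            rec.filter.add(s.filter)
            ac, an = s.allele_counts()
            rec.info["AC"] = (ac,)
            rec.info["AN"] = an
            if an:
                rec.info["AF"] = (ac / an,)
            for i, sid in enumerate(samples):
                gt = s.genotypes[i] if i < len(s.genotypes) else None
                rec.samples[sid]["GT"] = gt if gt is not None else (None,)
                rec.samples[sid].phased = s.phased and gt is not None
            vf.write(rec)


def read_small_variant_vcf(path: str | Path) -> tuple[list[SmallVariantSite], list[str]]:
    sites: list[SmallVariantSite] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise CohortQCError(
                    f"multiallelic row at {rec.chrom}:{rec.pos}; "
                    "run split_multiallelics first")
            gts: list[Genotype] = []
            phased = False
            for sid in samples:
                gt, _ = _parse_gt(rec.samples[sid].get("GT"))
                phased = phased or (gt is not None and rec.samples[sid].phased)
                gts.append(gt)
            sites.append(SmallVariantSite(
                chrom=rec.chrom, pos=rec.start, ref=rec.ref, alt=rec.alts[0],
                filter=list(rec.filter) [0] if list(rec.filter) else "PASS",
                genotypes=gts, phased=phased, site_id=rec.id or ""))
    return sites, samples


def write_sv_vcf(path: str | Path, records: Sequence[SVRecord],
                 samples: Sequence[str]) -> None:
    contigs = sorted({r.chrom for r in records})
    header = _make_header(samples, contigs, _SV_HEADER_LINES)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.record_id)):
            rec = vf.new_record(contig=r.chrom, start=r.start,
                                stop=max(r.end, r.start + 1),  # INS: POS only
                                alleles=("N", f"<{r.svtype}>"),
                                id=r.record_id or None)
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.length
            rec.info["CONTEXT"] = r.genomic_context
            rec.info["DNFRAC"] = r.de_novo_fraction
            if "SOURCES" in r.info:
                rec.info["SOURCES"] = tuple(r.info["SOURCES"])
            if "STRATUM" in r.info:
                rec.info["STRATUM"] = str(r.info["STRATUM"])
            if "WINNER" in r.info:
                rec.info["WINNER"] = str(r.info["WINNER"])
            for i, sid in enumerate(samples):
                gt = r.genotypes[i] if i < len(r.genotypes) else None
                rec.samples[sid]["GT"] = gt if gt is not None else (None,)
                rec.samples[sid].phased = r.phased and gt is not None
                if i < len(r.evidence):
                    ev = r.evidence[i]
                    rec.samples[sid]["DPR"] = float(ev.depth)
                    rec.samples[sid]["DPF"] = float(ev.flank_depth)
                    rec.samples[sid]["PE"] = int(ev.pe_count)
                    rec.samples[sid]["SR"] = int(ev.sr_count)
                if i < len(r.boost_scores) and r.boost_scores[i] is not None:
                    rec.samples[sid]["BS"] = float(r.boost_scores[i])
            vf.write(rec)


def read_sv_vcf(path: str | Path) -> tuple[list[SVRecord], list[str]]:
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = rec.info["SVTYPE"]
            length = int(rec.info["SVLEN"])
            start = rec.start
            # end derives from SVLEN (exact), not INFO/END
            end = start if svtype == "INS" else start + length
            gts: list[Genotype] = []
            evidence: list[EvidenceFeatures] = []
            boosts: list[float | None] = []
            phased = False
            for sid in samples:
                fmt = rec.samples[sid]
                gt, _ = _parse_gt(fmt.get("GT"))
                phased = phased or (gt is not None and fmt.phased)
                gts.append(gt)
                evidence.append(EvidenceFeatures(
                    depth=float(fmt.get("DPR", 1.0) or 1.0),
                    flank_depth=float(fmt.get("DPF", 1.0) or 1.0),
                    pe_count=int(fmt.get("PE", 0) or 0),
                    sr_count=int(fmt.get("SR", 0) or 0)))
                bs = fmt.get("BS")
                boosts.append(float(bs) if bs is not None else None)
            info: dict[str, object] = {}
            if "SOURCES" in rec.info:
                info["SOURCES"] = list(rec.info["SOURCES"])
            if "STRATUM" in rec.info:
                info["STRATUM"] = rec.info["STRATUM"]
            if "WINNER" in rec.info:
                info["WINNER"] = rec.info["WINNER"]
            records.append(SVRecord(
                interval=GenomicInterval(rec.chrom, start, end),
                svtype=svtype, length=length,
                source=rec.id.split(".")[0] if rec.id and "." in rec.id else "",
                record_id=rec.id or "", genotypes=gts, phased=phased,
                evidence=evidence, boost_scores=boosts,
                genomic_context=rec.info.get("CONTEXT", "unique"),
                de_novo_fraction=float(rec.info.get("DNFRAC", 0.0)),
                info=info))
    return records, samples
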