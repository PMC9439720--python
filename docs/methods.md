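# Methods

## Coordinate and genotype conventions

All internal coordinates are 0-based half-open; the VCF boundary
converts to/from 1-based positions and BED is consumed natively, so all
overlap arithmetic lives in a single convention.  Insertions carry a
point coordinate (`end == start`) plus a separate inserted-sequence
length; reciprocal overlap is undefined for insertions by construction
and their concordance is judged by breakpoint distance instead.
Genotypes are tuples of allele indices; haploid calls (male non-PAR X,
chrY) are first-class single-element tuples and missing (`None`) is a
distinct state, never conflated with homozygous reference.

Multiallelic rows are split into biallelic records with genotypes
recoded against the retained alternate allele (other alternates map to
the reference class) and left-normalized by allele trimming (shared
suffix, then shared prefix).  Phasing tools that require distinct start
positions are served by a *reversible key map* (`PositionDisambiguator`)
that assigns same-start records minimal integer offsets without
mutating coordinates; the original positions are recoverable exactly,
so downstream overlap math is never corrupted.  When SV records are
read back from VCF, the end coordinate is derived from SVLEN rather
than INFO/END (htslib's END round-trip for symbolic alleles is not
exact), which is lossless for the length-bearing types this package
emits.

## Ensemble SV integration

Pairs of same-class SVs are concordant under size-dependent reciprocal
overlap: RO = min(overlap/len_A, overlap/len_B) (both fractions must
meet the cutoff, the bedtools `-r` semantics), with cutoff 50% when the
longer member exceeds 5,000 bp and 10% otherwise.  The size rule as usually
stated leaves exactly 5 kb unassigned ("under 5 kb" vs "larger than
5 kb") and speaks per SV rather than per pair; this implementation classes a pair
by its longer member and assigns exactly 5 kb to the 10% class.
Insertions are concordant within 100 bp.

Clustering is single-linkage over concordant pairs, computed by a
positional sweep after canonical sorting, so the result is invariant to
input file order and provably equal to the all-pairs transitive closure
(tested against brute force).  Each locus is labelled by the call sets
that contributed (`shared` vs caller-specific strata).

The boost model is a per-SV-class scorer over eight per-genome
features: SV depth, 1-kb flank depth, pair-end count within 150 bp,
split-read count within 100 bp of each breakpoint, log10 size, allele
fraction, genomic-context class (short repeat / segmental duplication /
repeat-masked / unique), and the de novo fraction among observed
trios.  The default backend is LightGBM (100 trees, 15 leaves,
deterministic under a fixed seed); a scaler + logistic-regression
pipeline is available behind the same interface as a dependency-light
alternative.  Classes with fewer than 50 labelled examples share a
pooled scorer.  Training truth follows the ensemble-QC definitions: true
examples are uni-parentally inherited carriers of shared records with
both external support flags; false examples are de novo carriers of
caller-specific records with neither flag.  On synthetic data both
support flags derive from the generator's injection log, standing in
for long-read and assembly support.

Scores above the PASS threshold (strict `> 0.448`) pass;
`select_threshold` alternatively picks the smallest threshold whose
estimated validation FDR is below a 5% target.  The end-to-end pipeline
applies the default 0.448 cutoff: with well-separated synthetic
evidence the labelled validation set is dominated by true examples, so
the smallest-threshold rule can legitimately return a near-zero cutoff,
and the fixed reference operating point is the better-behaved default.
Caller-specific records are retained only when the fraction of
*examined* samples failing the model is below 48% (strict); "examined"
is interpreted as samples carrying a non-reference genotype, and that
interpretation is recorded in output metadata.  mCNV/CPX/CTX records
pass through unscored and are flagged `Manual_LQ` for review.

Final record selection: per sample, the member with the most split
reads wins (ties by higher boost score); per locus, the record carried
by the most samples wins (ties by per-sample wins, then record id).
For shared insertion loci a designated higher-precision caller's record
can be preferred.

## Trio metrics

Mendelian consistency uses explicit allele-multiset logic — a diploid
child genotype must be formable by one allele from each parent; a
haploid child X allele must be drawable from the mother — and equals
exhaustive enumeration over the 27 diploid genotype combinations.
Sites with a missing trio member are excluded from that trio's MER
denominator rather than counted as errors, and a site with no complete
trio has *undefined* MER (passed through filters with a warning, never
treated as 0).  The de novo rate is the complement of the child
inheritance rate (fraction of a child's non-reference variants carried
by at least one parent); the transmission rate is measured over
informative sites (heterozygous in exactly one parent, absent in the
other) and is Binomial(n, 1/2) under clean Mendelian segregation.
Singleton profiles count cohort-wide AC = 1 alleles per sample;
cohort AC includes related samples, duo children are reported separately
from trio children, and the within-family private-variant breakdown
(AC 2–4) supports the parent-midpoint consistency check.

## Panel filtering

The cascade applies, with strict inequalities exactly as stated:
FILTER = PASS, missingness < 0.05, HWE exact p > 1e-10 in at least one
super-population, MER ≤ 0.05, MAC ≥ 2.  Verdicts are evaluated
independently and conjoined, so the retained set is order-independent;
the named first-failing criterion follows the cascade order for the
ledger.  The HWE exact test is the standard two-sided conditional test
(sum of heterozygote configurations whose conditional probability does
not exceed the observed one; no mid-p), computed by the symmetric
recurrence and verified exhaustively against direct enumeration for all
configurations with n ≤ 50.  Monomorphic sites return p = 1 by
convention.  A 1-df chi-square variant is provided for the
insertion-pipeline-style filter (p > 1e-6); which test SV panel
filtering uses is exposed as a config flag because established pipelines
differ on this point.  A post-phasing MAC ≥ 2 re-check
removes sites that phasing pushed below the threshold.  The male-X
ploidy fix converts male diploid genotypes to haploid outside the PAR
intervals (GRCh38 defaults, overridable) and leaves PARs and females
untouched.

## Phasing evaluation

SER follows the plain junction-count definition — phase-orientation
changes between consecutive assessed heterozygous pairs divided by the
number of pairs — so an isolated single-site flip contributes exactly
two switches; no flip correction is applied to SER because the
dedicated flip-rate metrics below handle that failure mode.  SER is
orientation-free (invariant to globally swapping either panel's
haplotypes) and undefined (reported n/a, never 0) below two assessed
sites.  MAF strata default to (0, 0.1%], (0.1%, 1%], (1%, 10%],
(10%, 50%], with a junction attributed to its right-hand site's bin.

The SV flip rate compares the cis/trans relationship of each assessed
SV with its nearest phased heterozygous flanking SNV on each side
(default search window 50 kb) in test vs truth; when both flanks are
usable the majority decides.  The pairing rule is a documented
implementation choice — the metric's usual statement does not fully
specify it — and SVs with no usable flank count toward the assessed-fraction
denominator only.  The parental flip rate assesses trio-unambiguous
sites (excluding all-heterozygous trios and de novos), chooses the
haplotype-to-parent orientation per chromosome per child by majority
vote, and reports the minority fraction, so a single orientation error
cannot masquerade as many flips.

## Imputation evaluation

Dosage is e = p_het + 2·p_homalt.  r² is the squared Pearson
correlation of imputed vs truth dosages; groups with zero variance on
either side are n/a (excluded from means and counted), never 0.  The
default aggregation computes per-sample r² within an AF bin and then
averages over samples; sites are binned by the reference panel's
unrelated-sample AF, while the info/MAF count matrix uses the
imputed-set MAF — both AFs are carried per site.  The info score is the
IMPUTE-style variance ratio 1 − Σ(f − e²)/(2Nθ(1−θ)), f = p_het +
4·p_homalt, θ the expected AF, with monomorphic sites at 1 by
convention; it equals the observed/expected dosage-variance formulation
to 1e-9 (two-formula cross-check).  Hard calls take the argmax triple
entry when its probability is at least 0.90 (exactly 0.90 is called),
otherwise missing; discordance is 1 − matching/non-missing per sample.

## Truth-set construction

Genotyper A contributes genotypes at GQ ≥ 200, genotyper B at
FILTER = PASS; agreement yields the integrated genotype and anything
else is missing.  A site absent from either genotyper is missing
(intersection semantics — whether single-source genotypes should be
admitted is not specified, and the stricter choice is flagged).  Site
matching uses closed ±50 bp start windows (|Δstart| ≤ 100 bp) and a
minimum shorter/longer length ratio of 0.80 within the same SV type,
reduced to one-to-one pairs greedily by smallest |Δstart| (ties by
larger ratio, then record ids) because a truth set must not
double-count.  Final truth sites drop monomorphic and HWE-violating
(exact p < 1e-10) sites.  Concordance is correct genotypes over the
validation site count; non-reference precision is correct het plus
correct hom-alt over non-reference test calls.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the *statistical structure* the analysis
assumes: trio pedigrees with Mendelian transmission and recorded
parental origin (child haplotype 1 paternal by construction), an
allele-frequency spectrum with a singleton point mass (default 0.15)
plus a Beta(0.5, 2) common component, five super-populations assigned
round-robin, per-child de novo rates defaulting to 0.3% (within the
0.2–0.5% envelope prior short-read WGS studies report), multi-caller
call sets with per-caller FP rate 5%, FN rate 5%, N(0, 10 bp)
breakpoint jitter, and a 1% per-sample genotype-error rate (carrier
status flipped, spurious carriers drawing false-class evidence),
evidence features with well-separated true/false distributions
(split-read and pair-end means 8 vs 1; deletion depth 0.55 vs 1.0) so
the boost model is learnable at small n, Markov switch errors and
isolated flips at configurable per-junction/per-site rates, and
posterior genotype triples concentrated on the truth with
uniform-mixture noise.  False-positive records model *recurrent
systematic artifacts*: their carrier sets follow the same allele-
frequency spectrum as real variants rather than appearing in isolated
genomes.  Both choices matter for the boost filter's validity: caller
genotype errors are what make the per-genome de novo fraction a noisy
feature rather than a label oracle, and artifact recurrence across
genomes — including children, where artifacts surface as apparent de
novos — is precisely the assumption that lets a de-novo-defined false
training set generalize to the false-positive population.  Rare
single-genome artifacts carried only by adults remain invisible to
that labelling by construction; they dominate the small residual FDR
of the integrated call set, which sits in the same few-percent range
as the de novo-rate FDR proxy reported for real ensemble call sets.  Default scale is 30 trios + 40 unrelated
samples, 800 small variants and 300 SVs on one synthetic chromosome —
SV counts per genome in the hundreds rather than the ~9,700 a real
genome carries, chosen so the full pipeline runs in seconds.

It does **not** emulate realistic sequence content, LD or coalescent
structure, read-level evidence, caller-correlated error modes, or
cell-line somatic artifacts.  Passing tests therefore demonstrate that
the *computations* are correct and that parameters injected under the
assumed structure are recovered; they do not certify performance on
real data, where evidence distributions overlap more and caller errors
correlate.

Every corruption emits a machine-readable injection log (FP/FN records
per caller, switch junctions and flips per sample, genotyper errors),
so tests recover true labels without re-deriving them, and all outputs
are byte-reproducible from (seed, config).

## Numerical and design choices

- Strict inequalities throughout follow the stated filter definitions: boost
  PASS > 0.448, retention < 48%, missingness < 5%, HWE p > 1e-10,
  MER ≤ 5%, MAC ≥ 2, hard-call ≥ 0.90, info counts > threshold.
- Probability triples must sum to 1 within 1e-6; HWE exact-test tail
  comparison uses a 1e-12 relative tolerance against the observed
  configuration's probability.
- Ties: clustering member order is canonical (chrom, start, id);
  final-record ties resolve by record id; matching ties by length
  ratio then record ids; hard-call argmax ties are defensively missing.
- Degenerate inputs return distinct n/a states rather than 0: MER with
  no complete trio, SER with <2 assessed sites, r² with zero variance,
  discordance with no calls.
- The de novo injector calibrates the per-candidate probability from
  each child's inherited non-ref count so the *measured* de novo
  fraction is centred on the configured rate; every draw is logged.
- Rounding of summary statistics follows printed precision: fold
  changes to 2 decimals, percentages to 1 decimal.

## Problem sizes used in the shipped checks

Oracle-equivalence checks run ≥10³ randomized cases per primitive
(HWE exhaustively for all n ≤ 50, ~23k configurations); parameter
recovery uses ≥10⁴ assessed events per rate (3-binomial-sd bands);
the end-to-end integration check runs the default 70-sample, 300-SV
cohort.  These sizes make the whole suite and the acceptance script
run in minutes on one CPU while keeping binomial error bands a few
times smaller than the effects being measured.

## Known limitations

- The boost model's hyperparameters and train/validation protocol are
  implementation choices (reference models of this kind are not
  reproducible from their descriptions); both are surfaced in the API.
- Small-variant benchmarking matches normalized (chrom, pos, ref, alt)
  and optionally unordered genotypes; full local-haplotype
  reconciliation (hap.py/vcfeval semantics) is out of scope.
- Statistical phasing and imputation themselves (SHAPEIT/Eagle/IMPUTE
  class tools) are out of scope: this package prepares their inputs and
  evaluates their outputs.
- MER is computed per biallelic record after splitting; per-locus
  multiallelic MER accounting is not provided.
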