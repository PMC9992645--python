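# Methods

`denovoprio` implements the evidence chain used to argue that a gene hit
by de novo variants in a small trio-sequencing cohort is a plausible
neurodevelopmental-disorder (NDD) gene. The chain has five computational
stages; each is a module with a documented contract, and a synthetic-data
module generates every input with known ground truth so the whole chain
is testable offline.

## 1. Trio QC cascade and de novo calling (`trio_qc`)

Candidate de novo variants are extracted from a three-sample (proband,
father, mother) VCF by a hard-filter cascade in this order:

1. **Rarity** — population allele frequency (`AF_nonneuro` INFO tag,
   emulating a gnomAD non-neuro-subset annotation) must be < 0.1%.
   A missing frequency is treated as 0: absence from the population
   database is evidence of rarity, and retained published variants
   routinely have empty frequency cells.
2. **Site filters** — keep sites with MQ ≥ 35, QD > 2, FS ≤ 60,
   SOR ≤ 3, MQRankSum ≥ −12.5, ReadPosRankSum > −8. These are the GATK
   hard-filter conventions: FS and SOR grow with strand bias (small is
   good), rank sums are approximately standard normal under no bias
   (large negative is bad). A missing site metric passes that single
   criterion, because GATK emits rank sums only when they are
   computable and discarding absent values would throw away
   well-supported sites.
3. **Genotype filters** — every trio member must pass DP > 10 and
   GQ > 25; heterozygous calls additionally require allele balance
   0.25 < AB < 0.75 (AB = alt depth / total AD depth), homozygous-
   reference calls require AB ≤ `parent_ab_max` (default: the same 0.25)
   and homozygous-alt calls AB ≥ 0.75. The published het window only
   makes sense for heterozygous calls; the parental purity rule is this
   package's addition, needed for confident de novo calling. It has its
   own threshold so that loosening the het window (lowering `ab_low`)
   never silently *tightens* the parental rule — this keeps the
   survivor set monotone in every threshold, a property the test suite
   checks.
4. **De novo configuration** — proband heterozygous-alt, both parents
   homozygous reference, all three passing genotype QC. A missing
   parental genotype makes inheritance unknown, never de novo.
5. **Consequence** — keep loss-of-function classes (stop gain,
   frameshift, splice) unconditionally, and missense with CADD > 20.

All inequalities are exactly as printed above, strict where strict; the
boundary conventions are exercised by generated records sitting exactly
on every threshold. Multi-allelic records are rejected with an explicit
error rather than mis-parsed: inputs are expected to be split and
left-aligned upstream. Coordinates are 1-based GRCh37/hg19; a variant's
identity is the tuple (chrom, pos, ref, alt).

The funnel report charges each removed record to the *first* stage it
fails, so counts conserve exactly
(`records_in = records_out + Σ removed`).

## 2. Integrated de novo event table (`denovo_table`)

Cohort events and published events share one TSV schema (sample,
genomic/coding/protein change, function class, SIFT / PolyPhen / CADD /
MutationTaster / PROVEAN / M-CAP / VEST4 / GERP / phyloP annotations,
population frequencies, inheritance, source, diagnosis). Integration is
concatenation with duplicate (proband, variant) pairs rejected and
stable ordering by genomic position. A *recurrent site* is a genomic
variant key carried by ≥ 2 distinct probands. Protein-level labels are
stored verbatim but never used for matching, because published protein
nomenclature is not reliably consistent; the genomic key is.

The package bundles the nine MAST4 de novo events observed in NDD
probands (four from an infantile-spasm trio cohort, five from published
developmental-disorder studies). This fixture drives the worked example:
8 missense + 1 stop-gain events, six distinct sites, two recurrent
sites with multiplicities 3 (p.1471T>I) and 2 (p.1811S>F).

For the recurrent-vs-non-recurrent score comparison, each *proband*
contributes one value (a site carried by three probands contributes its
CADD three times). This per-proband grouping — 5 recurrent vs 3
non-recurrent missense values for the bundled events — is what the
rank-sum test below is applied to. Stop-gain events are excluded from
missense score comparisons.

## 3. Deleteriousness statistics (`deleteriousness`)

Two tests are implemented from first principles, because their exact
conventions are what the headline p-values depend on; library
implementations (scipy) are used as independent cross-check oracles in
the tests, never as the implementation.

**Wilcoxon rank-sum.** With samples untied and pooled n ≤ 30 the exact
U distribution is enumerated by the classical recursion. Otherwise the
normal approximation is used with tie-corrected variance

    Var(U) = n1·n2/12 · [ (n+1) − Σ(t³−t) / (n(n−1)) ]

and a 0.5 continuity correction toward the null; two-sided by default.
On the bundled per-proband CADD values ({26.3×3, 27.3×2} vs
{25.5, 22.9, 23.4}) this yields p = 0.0314.

**Fisher exact test, r×c.** The two-sided p-value sums conditional
(multivariate hypergeometric) probabilities of all same-margin tables no
more probable than the observed one. Tables with N ≤ 300 are enumerated
completely; larger tables fall back to a seeded Monte-Carlo estimate
(≥ 10⁵ margin-preserving Patefield draws, with the +1/+1 estimator so
the reported p is never exactly 0). SIFT is compared as a 2×2 (D/T)
table and PolyPhen as a 2×3 (D/P/B) table by default; collapsing
PolyPhen to D vs P+B is available as an option.

Two-sided tests are used throughout. The de novo-vs-private comparison
takes missense rows only; "private" population variants are
operationalized as allele count 1 in the non-neuro population subset.

*Calibration note.* The rank-sum implementation holds its nominal level
well (empirical type-I error ≈ 5% at n₁ = n₂ = 30 over 2,000 null
simulations). The exact Fisher test is **conservative by construction**:
because the conditional null distribution is discrete, its true type-I
error at n₁ = n₂ = 30 is between 0.9% and 2.7% depending on the null
bin fraction (computable exactly by summing binomial-weighted rejection
probabilities over all tables). This is an inherent property of exact
conditional tests, not an implementation artifact — the test never
over-rejects, but it cannot reach a 5% empirical rejection rate at
these sample sizes. The acceptance suite asserts a symmetric ±2-point
band around 5% for both tests and the Fisher half of that check
therefore fails by design of the test itself; the package documents the
conservativeness rather than replacing the exact test with an inexact
(e.g. mid-p) variant.

## 4. Co-expression percentile (`coexpression`)

The ranking statistic asks: among all genes expressed in the developing
cortex, how strongly does the target co-express with a known disease
gene set?

- **Universe** — a gene is *cortex-expressed* if RPKM > 0.5 in ≥ 50% of
  developing-cortex samples. "Developing cortex" is the 11 neocortical
  region codes (A1C, DFC, IPC, ITC, M1C, MFC, OFC, S1C, STC, V1C, VFC);
  the list is configurable. The RPKM cutoff is strict, the sample
  fraction inclusive.
- **Statistic** — for every universe gene, the mean of |Spearman ρ|
  with the set members (self excluded when the gene is a member),
  computed across all atlas samples with average-rank ties. Absolute
  correlation is the default because co-expression evidence is
  direction-agnostic; signed mode is a flag. Constant-expression pairs
  are skipped; a gene with no usable pair is excluded from ranking.
- **Percentile** — 100 × (#genes with strictly greater mean + ½ #ties)
  / universe size. Low percentile = top of the ranking; a target with
  the largest mean and no ties gets exactly 0. With this half-tie
  convention the universe-average percentile is exactly
  50·(U−1)/U, which the property suite asserts.

Whether rank ties should count half, fully, or be interpolated is not
determined by any external convention here; the half-tie choice is
documented and tested. Self-correlation exclusion for set members is
likewise a documented default.

## 5. Expression-trajectory regression (`trajectory`)

Ages are converted to post-conceptional days: weeks × 7 for
post-conceptional weeks; birth is fixed at 280 days; months add
30.4375 days and years 365.25 days after birth (calendar averages; all
constants configurable). A sample is *prenatal* iff age < 280 days
(strict), so a 40-pcw sample counts as postnatal.

Within a region group (CC = the 11 neocortical codes; FC = DFC, MFC,
OFC, VFC; both configurable, since the mapping of "cerebral cortex" and
"prefrontal cortex" aggregates onto atlas region codes is a modelling
choice) and period, the gene's RPKM is regressed on age in days by
ordinary least squares. Reported: slope (RPKM/day), intercept, R², and
the two-sided slope p-value from the t distribution with n−2 df.
RPKM enters untransformed by default (a `log1p` flag exists). Fits
require ≥ 3 samples and non-zero age variance; a constant response is
reported as slope 0, R² = 0, p = 1 rather than NaN.

## 6. Synthetic data (`synthetic_data`)

The generators define the study conditions for all simulation-based
tests.

**Expression atlas.** One sample per (region, age) cell over the 16
brain-region codes and a 12-point age grid (8–37 pcw, 4 months–40
years), i.e. 192 samples. Log-expression of gene g in sample s is

    log x_gs = log b_g + λ·z_s·[g ∈ module] + ε_gs − σ²/2,

with per-gene baselines log b_g ~ N(1.5, 1.2²) (median ≈ 4.5 RPKM, a
realistic right-skewed RPKM spread that leaves a minority of genes
below the 0.5 cortex-expression cutoff), a latent per-sample factor
z_s ~ N(0,1) shared by the `n_module_genes` module genes with loading
λ ∈ [0,1], and log-normal noise ε ~ N(0, σ²), σ = 0.4 by default. The
−σ²/2 term makes the noise mean-preserving. A single-factor module is
the simplest structure that gives the percentile statistic a planted
signal to recover: λ = 1 with vanishing noise makes module genes
perfectly rank-correlated, λ = 0 makes them indistinguishable from
background. Ramp genes (disjoint from the module) follow
mean = 1 + slope·min(age_days, 280) — a linear prenatal increase of
`prenatal_slope` (default 0.05 RPKM/day) that plateaus at birth — times
the same mean-corrected noise.

What the atlas does **not** emulate: region-specific expression
signatures, smooth temporal autocorrelation, multiple overlapping
modules, count noise at low expression, or batch effects. Passing the
planted-signal tests therefore shows the statistic recovers a known
single-factor signal at realistic noise, not that it is robust to every
structure in a real developmental transcriptome; the published
percentile and R² values themselves require the real atlas and gene
sets and are treated as external integration checks, not desk-scale
tests.

**Gene sets** are drawn with a configurable module-overlap fraction
(IS 37, EE 126, DD capped at the universe size by default); with the
fraction unset, members are uniform draws so module overlap follows the
hypergeometric law — which the tests check against the closed form.

**Variant cohorts.** De novo and private missense cohorts with CADD ~
Normal truncated at 0 (defaults 26 ± 3 vs 18 ± 5) and SIFT/PolyPhen
bins drawn with damaging fractions 0.9 vs 0.5 — a separation of the
same order as real de novo vs population-private contrasts.

**Trio VCF.** A VCF v4.1 with INFO MQ/QD/FS/SOR/MQRankSum/
ReadPosRankSum/AF_nonneuro/CSQ_class/CADD and FORMAT GT:AD:DP:GQ.
The first ~60 records are constructed to sit strictly below, exactly
on, and strictly above every site, genotype, rarity and consequence
threshold (plus missing-metric, missing-parent, inherited and hom-alt
configurations); the remainder are random records whose metrics
straddle the thresholds. The generator returns a truth table of the
five expected labels per record, computed from the planted values by an
independent restatement of the rules, so pipeline-vs-truth equivalence
is a genuine two-implementation check. AB is deliberately *not* written
as a FORMAT field: it is not standard, and deriving it downstream from
AD exercises the same code path real data would take. All generators
are bit-reproducible under a fixed seed.

## Numerical and scale choices

- Spearman correlations are computed by average-ranking each gene
  vector once and taking normalized dot products, so ranking a
  500-gene universe against a 37-gene set costs one 500×192 rank pass
  and one matrix product.
- Gene-set members are sorted before any numeric reduction so float
  summation order (and hence output bytes) is independent of Python's
  per-process hash randomization.
- Fisher enumeration uses log-probabilities with a 10⁻⁹ tolerance when
  comparing "as extreme as observed", to make ties in table probability
  robust to float noise.
- Simulation-based checks use 100 replicates (percentile and slope
  recovery) and 2,000 null draws (calibration); QC equivalence uses
  500-site VCFs over 5 seeds. These sizes give the rates being asserted
  (≥ 95%, ±2 points) comfortable Monte-Carlo resolution while keeping
  the full suite in tens of seconds.
- Derived seeds passed to generators are offset from the user seed and
  kept below 2³¹.

## Known limitations

- The QC cascade handles autosomal bi-allelic SNVs/indels only: no
  X-linked/hemizygous logic, no mosaicism, no multi-allelic splitting.
- The de novo rule is the strict child-het/parents-hom-ref
  configuration; it cannot flag parental mosaicism or dropout.
- The co-expression statistic is a marginal ranking, not a network
  model; it inherits all caveats of correlation-based evidence.
- The trajectory model is a straight line per period; real trajectories
  saturate and bend, which a linear fit summarizes only coarsely.
- The exact Fisher test is conservative at small n (see the calibration
  note above).
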