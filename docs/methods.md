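# Methods

## Scope and data model

The package analyses a single trio — female parent, male parent, F1
hybrid — across three molecular layers: small-RNA expression (miRNAs and
siRNA clusters), gene expression, and whole-genome bisulfite methylation.
Everything upstream of count matrices and per-cytosine methylation calls
(trimming, alignment, cluster discovery, target prediction) is out of
scope; the package consumes the tabular outputs such tools produce.

All genomic intervals are held 0-based half-open; GFF3 (1-based closed)
and cytosine reports (1-based positions) are converted at the I/O boundary
only. Genes must be stranded; clusters, TEs and DMR bins may be
strandless.

## Expression patterns

Counts are normalized to reads per million over the features in the
matrix, per sample. Features are kept when normalized expression is
strictly above a threshold in at least `min_samples` samples (defaults:
RPM > 2 in ≥ 2 samples for small RNA, FPKM > 0.5 in ≥ 2 samples for
genes; the strict inequality is deliberate and tested).

The differential test is a negative-binomial Wald test in the DESeq2
family, not a wrapper around it: median-of-ratios size factors over
features positive in every sample; per-feature dispersion
(`var = μ + αμ²`) by method of moments from the pooled within-group
variance of size-factor-scaled counts, floored at 1e-8; a delta-method
Wald statistic on the log fold change. Two departures from the plain Wald
recipe matter at trio scale:

* **Student-t reference.** With 3 replicates per group the method-of-moments
  dispersion is noisy and a normal-reference Wald test rejects a true null
  ~12% of the time at p < 0.05. Referring the statistic to a Student-t with
  the residual degrees of freedom (n1 + n2 − 2 = 4) restores calibration
  (~4.5% empirically) without moderating dispersions across features.
  Combining the t-reference with cross-feature dispersion moderation
  overcorrects (type-I ~0.8%), so moderation is not applied.
* **Pseudo-mean 0.5** in the fold-change and its standard error keeps
  groups with zero counts finite.

Exact numerical parity with DESeq2 (shrinkage, outlier replacement,
independent filtering) is explicitly not claimed.

Heterosis candidates are features significant between the parents
(F vs M), or significant in both hybrid contrasts (H vs F and H vs M) with
the same sign of log fold change. Significance is FDR < 0.05 jointly with
|log2fc| > 1, reading "fold change > 2" literally against the unshrunken
Wald estimate (whether the original criterion used shrunken estimates is
not determinable; this choice is documented rather than hidden).

D/A classification uses replicate-mean RPM, not model-fitted means: D =
H − MPV, A = HP − MPV, and the five intervals partition the extended real
line with boundaries assigned to the less extreme class (exactly 2 →
DHPE, exactly 0.5 → AE, …), a conservative tie rule since the defining
inequalities are strict and leave boundaries open. When the parents are
numerically equal (A < 1e-9) the ratio is undefined: the feature is AE if
the hybrid also sits at the shared parental level, otherwise THPE/TLPE by
the sign of D with D/A recorded as ±∞. D, A, D/A and the pattern are
invariant under swapping the parent labels.

## Methylome

Replicates are pooled by summing reads per cytosine within each genotype
before any filtering (standard WGBS practice at n = 2; replicate handling
is otherwise under-determined). A cytosine counts toward a region's WML
only when its pooled coverage is ≥ 5 reads; a region with no passing
cytosine has an undefined WML (NaN, never 0). CG dyads are not
strand-collapsed: each cytosine is its own observation.

Differential methylation over predefined regions (siRNA clusters or fixed
100-bp bins) is a two-sided Mann–Whitney U between the two groups'
per-cytosine level vectors, restricted to cytosines covered ≥ 5 in both
groups, BH-corrected across regions within a context. The exact null
distribution is used for regions with ≤ 12 eligible cytosines and the
tie-corrected normal approximation above that. A region is a DMR when it
has ≥ 4 eligible cytosines, FDR < 0.05 and |mean level difference| above
the context threshold (0.1 CG, 0.1 CHG, 0.05 CHH). This re-implements the
region-mode statistic family of metilene; metilene's de novo segmentation
and exact parity are out of scope, and the tension between fixed 100-bp
bins and segmentation-based DMR calling is resolved here as fixed
regions only.

Met_d/a uses the max-of-parental-deviations denominator; for distinct
parents this equals 2(H − MPV)/|F − M| (asserted in tests at 1e-12
relative precision away from near-equal parents, where double-precision
evaluation of either form is ill-conditioned). Boundaries ±0.5 go to NIM,
consistent with the expression tie rule; equal parents are a separate
branch mirroring the expression one. Candidate regions mirror the
expression candidate rule with the hybrid as group 1 in hybrid contrasts,
so "hyper/hypo" is the sign of meth_diff.

The genome-wide hybrid-vs-MPV shift test is a two-sided Wilcoxon rank-sum
between the per-region hybrid WMLs and mid-parent WMLs, with the direction
reported as the sign of the median paired difference.

## Genomic context

Cluster annotation precedence is gene body > 5′-2kb > 3′-2kb > TE >
intergenic; any shared base counts as overlap; flanks are strand-aware
windows of 2 kb measured from the annotated gene start/end. Among several
genes in the same tier the nearest (then lexicographically smallest id) is
linked, making annotation total, deterministic and order-independent. An
"other/uncharacterized" category is not emitted; anything not captured by
the four feature classes is intergenic. Dominant size classes (18–24 nt)
are the histogram argmax, with exact ties reported as ambiguous and
excluded from summaries.

## Integration

Pattern groups cross the cluster's expression superclass (HPE/LPE/AE) with
its per-context methylation pattern; contexts are independent, so a
cluster contributes to at most one group per context. The six focal groups
are HPE-{CG,CHG,CHH}-TCM and LPE-{CG,CHG,CHH}-TCdM. Genes are associated
through gene body/flank annotations and deduplicated within a group.

Fisher's exact test is two-sided by summing hypergeometric probabilities
at most as large as the observed table's; a 0.5 Haldane correction is
applied only when reporting an odds ratio from a table with an empty cell,
never to the p-value. The background for cluster-level association is all
expressed siRNA clusters; for gene-level tests it is all pattern-called
genes associated with any of the tested groups' clusters (the gene-level
universe is otherwise under-specified; both conventions are mechanically
supported by passing a different universe). Term enrichment is a one-sided
hypergeometric upper tail per term with BH-FDR, against user-supplied
gene→term annotations — no bundled ontology. Expression differences among
TCM/TCdM/NIM clusters use Welch's t-test on log2(RPM + 1).

## Synthetic data

The generators plant effects on the scale the classifiers measure, which
makes recovery a well-posed test:

* **Expression.** Each feature gets a class by deterministic proportions,
  a base mean log-uniform in [100, 1000] expected counts, a 4-fold
  parental gap (high parent assigned at random), and a hybrid mean at the
  class's planted D/A (midpoints 1.25 / 0 / −1.25 for the finite classes,
  ±3 for the transgressive ones). Counts are negative-binomial with
  dispersion α = 0.05 (`var = μ + αμ²`), 3 replicates per genotype. A
  planted D/A below −(MPV/A) would need a negative hybrid mean; when the
  planted hybrid mean would fall under 0.25·MPV the parental gap of that
  feature is shrunk just enough to restore the margin (this touches TLPE
  at gaps above 2-fold), and the truth table records the D/A actually
  planted.
* **Methylome.** Regions on a toy chromosome carry 12–30 cytosines cycling
  through the three contexts; parental WML targets are 0.7/0.3 (assignment
  randomized), the hybrid target sits at Met_d/a +1 / 0 / −1 for
  TCM/NIM/TCdM. Coverage is Poisson(50) per cytosine and replicate;
  methylated reads are beta-binomial with overdispersion ρ = 0.05, 2
  replicates per genotype — replicate overdispersion being the realistic
  stress for the rank-based test.
* **Annotation.** One 20-kb slot per cluster holds (as needed) a stranded
  gene, a TE and the cluster itself, so requested categories are planted
  without interference and an over-crowded request errors out.

Everything is drawn from one `numpy.random.default_rng(seed)` stream per
generator in a fixed order, so outputs are bit-reproducible for a given
seed across platforms.

What the generators do *not* emulate: library-size imbalance between
samples, mean-dependent dispersion trends, spatial autocorrelation of
methylation, linked effects between the expression and methylation layers
beyond shared coordinates, and TE families. Passing recovery tests
therefore validates the estimators' geometry and the pipeline's plumbing,
not robustness to those real-data features.

## Problem sizes and observed behaviour

The test suite and the acceptance script run at 300–2000 features, 90–1000
regions and ≤ 100 annotation slots — sizes at which every stage completes
in seconds while keeping the statistical checks (type-I calibration on a
2000-feature null, recovery on 1000 regions) meaningful.

A quantitative limitation worth stating plainly: with 3 replicates and NB
dispersion 0.05 (per-replicate CV ≈ 22%), the D/A ratio estimated from
replicate-mean RPM has a standard error around 0.5 near the class
boundaries, against boundary margins of 0.75 under midpoint planting.
Five-class recovery is therefore ~87–88% in that regime (~99% at
dispersion 0.01, and it plateaus near 94% for arbitrarily large parental
gaps because both the margin and the noise scale with the gap). Recovery
above 95% at dispersion 0.05 would require more replicates or a planting
geometry further from the boundaries; the corresponding acceptance test is
left failing rather than quietly moving either. Methylation recovery at
coverage 50 and a 0.4 WML gap is ~98% per context, and the null rejection
rate of the NB test sits at 4–5%.
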