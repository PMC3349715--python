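# Methods

This note documents the models and procedures implemented in `ladomics`,
the synthetic study conditions they are tested under, the numerical choices
made where the design was open, and the limits of what the tests show.

## Study design

The analysis follows a discovery → validation design. All two-sided
association tests (mutation 2×3 exact tests, Kruskal–Wallis on CIN, region
CN and methylation) run in the discovery cohort; directions found there
(enriched subtype, GACN subtype, Magnoid CIN/methylation) are pre-registered
and re-tested one-sided in an independent validation cohort. Discovery and
validation sample sets must be disjoint; overlap is a hard error.

## Subtype discovery and prediction

*Consensus clustering.* Tumors are gene-median centered, the top 25% most
variable genes retained (variance ranking, ties broken by gene id), and the
Monti resampling procedure applied: `n_reps` = 500 subsamples of 80% of
tumors, each clustered by agglomerative average linkage on 1 − Pearson
correlation; the consensus value of a tumor pair is its co-clustering
frequency among subsamples containing both. For each k, final labels come
from average-linkage clustering of 1 − consensus. k is chosen by the
consensus-CDF area criterion: Δ(k) = (A(k) − A(k−1))/A(k−1), and the chosen
k is the largest with Δ(k) ≥ 0.1 (manual override supported). On the
default synthetic cohort the areas are ≈ 0.45 / 0.67 / 0.68 / 0.69 for
k = 2…5, so k = 3 by a wide margin.

*Nearest-centroid predictor.* Genes are scored per class by the one-vs-rest
standardized mean difference of centered expression; the top genes are
taken round-robin over classes until 506 distinct genes are selected
(balanced selection avoids class bias). Centroids are per-class means.
New cohorts are gene-median centered within-cohort — this absorbs platform
location effects — and each sample is assigned the centroid with smallest
1 − Pearson correlation over shared genes (≥ 50% of model genes required;
ties break in the fixed subtype order and are flagged). The selection rule
and distance are configurable; correlation distance is the default because
it is scale-robust across platforms.

*Cluster naming.* Consensus clusters are arbitrary integers. When reference
labels exist (synthetic cohorts), clusters are renamed by maximal overlap
(Hungarian assignment); the naming affects only which subtype name appears
in reports, never any test statistic. Without a reference, clusters are
named by size order and the report flags it.

## Statistical core

* 2×2 Fisher tests use the classical hypergeometric test; 2×3 tables are
  enumerated exactly over the margin-fixed fiber, with the two-sided p
  defined as the total probability of tables no more probable than the
  observed one (tolerance 1e−7 on the boundary). The test suite keeps
  independent enumeration oracles for both shapes.
* Rank-sum tests are exact (full enumeration) when the pooled size is ≤ 12
  with no ties, otherwise normal approximation with tie and continuity
  correction. The switchover is fixed for cross-platform reproducibility.
* Kruskal–Wallis uses midrank tie correction; an all-constant input returns
  H = 0, p = 1 by convention.
* BH q-values use the standard step-up; monotonicity is property-tested.
* Bootstrap CIs are percentile intervals from seeded resampling
  (1000 replicates by default).

## Mutation association

Mutation = non-synonymous or splice-site call. Genes are testable when ≥ 5
patients carry a mutation in the pooled discovery cohort. Denominators are
per-gene assayed counts, not cohort size, because cohorts differ in which
genes they sequenced. Discovery gate: two-sided P′ < 0.10 (configurable);
only gated genes acquire an enriched subtype and enter validation, where
the 2×2 test collapses the two non-enriched subtypes ("enriched vs rest",
per the registered null hypothesis) and keeps the registered direction even
if validation frequencies reverse. Genomewide rates divide each tumor's
non-synonymous count by its sequenced bases.

## Copy number

CIN is a two-stage median: per arm the median probe log-ratio, per tumor
the median of absolute arm values; arms need ≥ 5 probes (median stability;
the source of the statistic is silent on a floor). CIN can be computed on
raw or pre-binned probes (2 Mb median binning available); raw is the
default. GACN: for regions with BH-adjusted subtype association P < 0.05,
the three one-vs-rest partitions are compared by the absolute difference of
group medians **of per-sample region values**, and the winning partition's
side farther from zero names the subtype. If the two-subtype side is
farther from zero the single-subtype label is ambiguous; the implementation
names the pair member with the larger absolute median and flags the region.
Validation is a one-sided rank-sum on |region CN|, plus a directional
confirmation indicator independent of significance. Region discovery
itself (recurrent-peak detection) is out of scope: regions are inputs.

Coordination: per region, the CN difference (GACN subtype median − rest
median) is paired with the median over region genes of the same difference
in expression; Spearman correlation across regions tests coordination.

## Methylation

Percent change = (undigested − HpaII)/undigested, methylation-class sites
only; control sites are retained for QC but excluded from statistics.
Values are left unclamped (noise can push them outside [0, 1]); entries
with undigested abundance below the 1st percentile floor become missing
rather than amplifying division noise. "Genomewide methylation" is the
per-sample median over sites (the boxplot reading of the genomewide
comparison; the per-site median over samples is the other possible reading
— this one is an interpretation, flagged here). Per-site contrasts are
one-sided rank-sum tests (class A greater), BH-corrected; arm profiles
report the fraction of significant sites per arm, arms with < 4 tested
sites omitted.

## Integration and outcomes

Gene CN calls use the median log-ratio of probes within the gene locus ±
a flank, thresholds ±0.3 (the source states no numeric cutoffs; ±0.3
log-ratio is conventional and configurable, and recorded in the run
manifest). The flank default is 100 kb; the pipeline uses 500 kb so the
window always covers ≥ 1 probe at the synthetic platform's 500 kb spacing.
Expression calls use cohort tertiles. Evaluable denominators require
non-missing status on every axis a combination references.

Kaplan–Meier and the k-group log-rank test are implemented natively and
oracle-tested (hand product-limit computation; lifelines as an independent
cross-check); Cox fits delegate to lifelines, with per-subtype fits on the
treatment indicator and optional covariate adjustment. Patients with < 1
month follow-up are removed (attributed to surgical complications); exactly
1.0 month is retained. The gefitinib score is the difference of per-list
means over present signature genes (the o/u description implies a mean
difference; a sum-difference variant would differ only by a scale factor
when no genes are missing); missing genes are dropped per sample and
counted, not imputed.

## Synthetic study conditions

The generator is the package's test bed and defines its study conditions:

* Genome: 22 autosomes × 100 Mb, equal p/q arms; 100 CN probes and 50
  methylation sites per arm; 1200 genes evenly spaced. Small enough for
  seconds-scale simulation, large enough for stable arm medians.
* Expression: iid N(0, 1) log-scale noise; 300 informative genes split
  evenly across subtypes, each elevated 1.0 sd in its subtype. Informative
  genes exclude driver loci and genes inside true CN regions, keeping the
  clustering signal orthogonal to the regional-CN signal.
* Mutations: driver Bernoulli frequencies = the reported discovery-cohort
  values (EGFR 37/9/18%, KRAS 16/30/18%, TP53 22/40/33%, STK11 13/22/8%);
  background non-synonymous Poisson rates 1/4/2 ×10⁻⁶ per base for
  Bronchioid/Magnoid/Squamoid over 10⁶ sequenced bases (the observed
  low-to-high rate ordering, a 1:2:4 gradient).
* Copy number: per-arm Gaussian baseline scaled by subtype
  (σ = 0.1/0.4/0.2 for B/M/S — Magnoid most unstable), probe noise σ = 0.1;
  24 true 10 Mb regions (8 per subtype, mixed directions, effects cycling
  0.3–0.8 so that region effect size varies) with the GACN subtype carrying
  the full effect and other subtypes 20% of it. Driver mutations couple to
  focal CN (±0.5) and expression (±1.5) at the driver locus with
  probability 0.8 (EGFR/KRAS amplified+over, TP53 deleted, STK11
  deleted+under). Region CN feeds back into region-gene expression with
  coupling 1.0.
* Methylation: site baselines U(0.2, 0.6); subtype shifts +0.02/+0.10/+0.05
  (B/M/S) versus normal lung — Magnoid hypermethylation with the nested
  Squamoid/Bronchioid structure; site noise σ = 0.05, sample offsets
  σ = 0.02; the shift can be restricted to chosen arms.
* Survival: exponential event times, baseline hazards 0.012/0.035/0.025
  per month (Bronchioid best outcome), uniform censoring on 6–120 months;
  treatment (50% of tumors) multiplies the hazard by the per-subtype HR
  1.0/0.5/1.0 — benefit in Magnoid only.
* Defaults: 50 tumors/subtype + 30 normals per cohort; the default *study*
  uses 300/subtype discovery and 120/subtype validation, sizes at which the
  two-stage mutation design has per-gene validation power ≳ 0.75 for the
  weakest planted effect.

All randomness flows from one seeded generator, so a (config, seed) pair is
bitwise reproducible.

What the generator does **not** emulate: correlation between omics layers
beyond the subtype label and the explicit couplings above, batch or
platform effects, linkage/segmentation structure along chromosomes,
non-exponential survival, or informative censoring. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
model's assumptions, not robustness to real-data artifacts such as
normalization drift or segmentation noise.

## Problem sizes in the test suite

Recovery checks use the generator at the sizes above: 150-tumor cohorts for
subtype recovery, 300/120 per subtype for the mutation two-stage (50
replicate seeds), 50/subtype for CIN and GACN (50 seeds), 11/subtype for
the genomewide methylation shift (50 seeds), 80/subtype for hazard-ratio
recovery (150 replicates — the replicate median then has Monte-Carlo s.e.
≈ 0.035 against the ±10% recovery band, so the check reflects estimator
calibration rather than replicate noise), and one full 300+120 study for
the end-to-end run. Null configurations (equal frequencies, zero effects)
verify false-positive control at the same sizes.

## Known limitations

* The 2×3 exact test enumerates the fiber; it is fast for the two-row
  tables used here but not a general r×c network algorithm.
* GACN labelling is ambiguous when the two-subtype side of the best
  partition is farther from zero (flagged, see above).
* The consensus k rule ("largest k with relative area gain ≥ 0.1") matches
  the CDF-inspection logic but any automatic rule can mis-select on weakly
  structured data; the override exists for that case.
* Per-site methylation contrasts use the normal approximation throughout;
  at very small class sizes (< 5 per class) exact tests would be more
  conservative.
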