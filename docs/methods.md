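# Methods

## The model

The package predicts between-population differential expression of a gene
from population genetics alone. Assume a SNP's effect on expression is
additive per alternate allele with standardized slope β (the eQTL effect
size). In a population with alternate-allele frequency f the mean dosage is
2f, so between populations 1 and 2 the predicted standardized expression
difference is β·(2f₁ − 2f₂)/2 per allele-pair accounting — the package
follows the convention of reporting β·(f₁ − f₂) directly, the *calculated
differential expression* d. Treating d as the standardized mean difference
(X̄₁ − X̄₂)/s of a two-sample comparison with sizes n₁, n₂ gives the
approximate statistic t = d/√(1/n₁ + 1/n₂).

Assumptions worth stating plainly:

- β is taken at face value from the eQTL catalog and assumed portable across
  populations and from normal to tumor tissue;
- expression is treated as unit-variance after standardization — no
  gene-specific variance model is attempted, so d is a screening statistic,
  not an estimator with standard errors;
- the normal reference for the critical value is adequate at the cohort
  sizes involved (hundreds of samples); a Student-t reference with
  n₁+n₂−2 df is available via `TTestContext(reference="t")` and is
  marginally more conservative at small n.

### Threshold, sidedness

`min_effect_threshold` returns z₍₁₋α₎·√(1/n₁+1/n₂) one-sided by default.
One-sided is the natural choice because the screen is always run *after* the
direction of differential expression has been observed: the hypothesis is
directional by construction. At α = 0.01, n₁ = 552, n₂ = 138 the threshold
is 0.2214 (0.22 at two decimals); a two-sided screen would need 0.245.

### Candidate filtering

Discovery applies, in order: an eQTL p-value pre-filter (≤ 0.01, switchable,
`eqtl_p_max`), the |d| ≥ threshold test (switchable, `apply_threshold`), and
a sign-consistency requirement against the observed expression difference.
Both p-value-like filters are on by default since either reading of "records
with p below 0.01" is defensible; they act on different axes (catalog
association strength vs predicted population effect) and their conjunction
is the conservative choice. Candidates are ordered by |d| descending, ties
by genomic position.

### Validation

Validation in a held-out population is operationalized as sign agreement:
a candidate is validated when sign(β·(f_discovery − f_validation)) equals
the observed direction of differential expression in the corresponding
comparison. This is an interpretation — confirmatory analyses of this kind
are rarely specified exactly — and is flagged as such here; passing a
threshold test at the validation cohort's sizes can be additionally required
by supplying `ctx_val`.

### Proximity clustering

True linkage-disequilibrium clustering needs haplotypes; as a desk-scale
surrogate the package single-links SNPs whose sorted positions differ by at
most 40 kb (inclusive), per chromosome. The default gap was chosen as a
round value separating typical intra-LD-block spacing (tens of kb) from
between-block gaps (≥ 50 kb) in the worked example's region; it is a
configurable display aid, not an LD estimate.

### Distance annotation

`distance_to_gene` reports 0 inside the locus and distance to the nearer
boundary otherwise. The *display* convention (`tss_distance_kb`) measures
from the locus start coordinate and rounds to whole kb, matching how such
distances are conventionally tabulated for downstream SNPs.

## Cohort matching

Pairs are eligible when all exact fields agree (default: tumor stage) and
ages differ by ≤ 10 years. For a given ratio k, matching is
maximum-cardinality bipartite b-matching (smaller group capacity k, larger
group capacity 1), computed as min-cost max-flow in which a subject's first
pair is free and repeat use costs one unit. The cost term matters: among
equal-cardinality matchings it maximizes the number of distinct
smaller-group subjects n, which (with m fixed at the cardinality) maximizes
the objective nm/(n+m) and makes the returned optimum monotone under edge
addition and invariant to input order. The ratio k is swept 1..8
(`max_ratio`; the regimes of interest, e.g. 552:138 ≈ 4:1, are well within
this) and the k maximizing nm/(n+m) is kept, ties to smaller k. nm/(n+m) is
proportional to the harmonic mean of the matched group sizes, the quantity
that drives two-sample power at fixed effect size. Cardinality-only
optimality is implemented; minimizing total age distance among maximum
matchings is a possible refinement that is deliberately out of scope.

## Expression screen

Counts are normalized to reads per million per sample. The per-gene test is
Welch's unequal-variance t on log2(RPM+1) — a deliberately simple,
well-calibrated stand-in for count-model DE machinery; its null calibration
is verified by simulation (type-I rate at p ≤ 0.05 within the 99% binomial
band at 200 genes). Genes with zero variance in both groups get p = 1.
Fold changes are means of RPM with a pseudocount ε = 1, oriented to the
declared reference group; "fold change ≥ 2" is applied bidirectionally
(|log2FC| ≥ 1). BH adjustment is the standard step-up procedure. Strata:
All, early stage (I–II), late stage (III–IV), and the four molecular
subtypes; a stratum with fewer than two samples per group is skipped with a
logged reason. Enrichment is the upper-tail hypergeometric test of the
significant genes against each set, background defaulting to all genes in
the count matrix (configurable — published analyses rarely state their
background, and the choice materially affects p-values).

## Synthetic data

The generator emulates the joint structure the pipeline assumes:
ethnicity-labelled cohorts with uniform ages and categorical stage/subtype
mixes (defaults: stage 18/55/22/5%, subtype LA/LB/H2/TN 50/20/10/20%, cohort
sizes 552/138/57 mirroring a matched breast-cancer series); Hardy–Weinberg
genotypes per population; and negative-binomial counts (gamma–Poisson,
dispersion α = 0.1, var = μ + αμ²) with library sizes uniform in 0.8–1.2
million reads. Planted eQTLs act additively per allele on log2 relative
expression — the scale on which eQTL slopes are interpreted here, chosen
because a slope multiplying a frequency difference must live on the scale of
normalized expression; this convention is stated rather than assumed
elsewhere. Null SNPs share one frequency across populations, so their true
between-population effect is exactly zero. Per-gene baselines spread ±2 log2
units around `baseline_log_mean` = 5 to mimic dynamic range. Optional
per-population expression shifts (`population_shift`) inject non-genetic
confounding; they are off by default so that null calibration is clean.

What the simulation does *not* model: LD/haplotype structure (genotypes are
independent across SNPs), batch effects, somatic copy-number or mutation
effects on expression, admixture (population labels are clean), and
compositional extremes (planted effects slightly compress observed log2
fold changes through the library-size normalization — visible as ~0.5 vs a
nominal 0.6 in the recovery setting, harmless to sign and threshold
behavior at the planted effect sizes). Passing tests therefore demonstrate
internal correctness and calibration, not robustness to those real-data
complications.

## Numerical and design choices

- Seeds: a single pipeline seed fans out to per-stage seeds by SHA-256 of
  `"{seed}:{stage}"` (mod 2³¹), so stages are independently reproducible;
  fixed seed ⇒ byte-identical outputs (hash-checked in the manifest).
- Matching determinism: nodes and edges enter the flow network in sorted
  order; network simplex then yields a reproducible optimum.
- Problem sizes in the shipped recovery experiments (two cohorts of 200,
  30 genes, 51 SNPs, 20 seeds) were chosen as the smallest sizes at which
  the planted effect (d = 0.30) sits several estimation standard errors
  above the matched-cohort threshold (≈ 0.24), so recovery is a sharp
  pass/fail rather than a coin flip.
- Missing genotypes (VCF `./.`) are excluded from both numerator and
  denominator of allele frequencies; a SNP with no genotyped member in a
  population is dropped with a log entry.
- Boundary rules are inclusive throughout: age difference exactly 10
  matches, fold change exactly 2 and p_adj exactly 0.05 are significant,
  a positional gap exactly 40 kb shares a cluster.

## Known limitations

- The calculated effect ignores LD between candidate SNPs: clustered SNPs
  are near-duplicate signals, not independent hits — which is exactly why
  cluster membership is reported.
- Validation by sign agreement is weak evidence; with frequencies estimated
  from small panels it will mis-flag SNPs whose validation-population
  frequency sits near the discovery frequency.
- The Welch screen is not a count model; at very low counts or tiny group
  sizes its p-values are approximate, and gene-level agreement with
  count-based DE tools is not claimed.
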