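# Methods

`dsdm` studies recurrent, trisomy-associated differential CpG methylation
(DS-DM) with two complementary data types: fractional-methylation (β)
matrices from methylation arrays, and per-CpG read counts from whole-genome
bisulfite sequencing (WGBS) of single case/wild-type genome pairs. This note
records the statistical models, the defaults and why they are set where
they are, the synthetic-data assumptions, and the numerical choices made
where the design was genuinely open.

## Array model and DM criteria

A β value is the fraction of methylated alleles at a CpG, in [0, 1]. Probe
QC removes (i) sex-chromosome probes (confounded by sex composition),
(ii) probes overlapping common SNPs (minor allele frequency ≥ 1%, genotype
masquerading as methylation), and (iii) probes whose detection p-value
exceeds 0.05 in more than one sample of any status subgroup (subgroup =
status within tissue; the rule tolerates a single sporadic failure so that
one bad hybridization does not cost a probe). Downstream analysis is
complete-case per CpG: probes surviving QC must have values in every
sample.

DM calling is deliberately simple and supervised: per CpG, a two-sided
equal-variance Student's t-test between case and control groups, plus a
magnitude criterion. A CpG passes when |mean_case − mean_control| ≥ 0.15
and unadjusted p ≤ 0.001. The 0.15 floor discards statistically significant
but biologically negligible shifts; the fixed p cutoff makes lists
comparable across tissues, with Benjamini–Hochberg q-values (computed over
the tested, post-filter probes of each analysis, not a global manifest)
reported so the effective FDR of the cutoff can be read off per run. Welch's
test is available behind `equal_var=False`. Zero-variance CpGs are recorded
as untestable rather than dropped silently. Sex adjustment refits passing
CpGs with β ~ status + sex (ordinary least squares) and reports the status
coefficient's p-value. Gene aggregation lets a multi-gene probe count
toward each annotated gene — a declared convention; per-gene counts are
therefore not deduplicated across overlapping transcripts.

## Batch adjustment

`adjust_batch` implements a parametric empirical-Bayes location/scale
adjustment (Johnson-style): fit β ~ batch + status per probe, standardize
against the batch-free surface, estimate per-batch means and variances,
shrink them toward cross-probe priors (normal prior on means,
inverse-gamma on variances, moment-matched, fixed-point iteration),
remove the batch terms and restore the scale. Status is always in the
design, so a true case/control difference is preserved; a batch perfectly
confounded with status is refused as inestimable. `shrink=False` gives the
plain (no-pooling) location/scale adjustment, which removes an exact
additive batch shift to machine precision; the empirical-Bayes default
trades that exactness for stability when per-batch estimates are noisy,
leaving residual batch-mean differences on the order of the shrinkage
weight times the estimation noise. Output is re-clipped to [0, 1].

## 5mC/5hmC decomposition

Standard bisulfite conversion reads 5mC + 5hmC; oxidative bisulfite reads
5mC alone. The hydroxymethyl estimate is the per-entry difference,
5hmC = BS − OXBS, clamped at zero. Negative raw differences are pure assay
noise under the model and are retained (`hmc_raw`) for QC — a strongly
negative tail indicates conversion problems. Modality classification runs
the DM t-test separately on the 5mC and 5hmC components with the looser
screen used for this assay (uncorrected p < 0.05, component |Δ| > 0.15):
both marks passing ⇒ additive, one ⇒ mc_only/hmc_only, neither ⇒ none.
Direction concordance between marks is computed on CpGs where both
component |Δ| exceed 0.05 — a deliberately loose eligibility screen, since
the quantity of interest is the sign agreement, not significance.

## Maturation and aging

Age-dependence screens are per-CpG OLS fits of β on age, with slopes
reported per 10 age units (gestational weeks in fetal tissue, years in
adults). The fetal profile requires |slope| > 0.1 per 10 weeks, R² ≥ 0.8
and p < 0.05; adult methylation drift is an order of magnitude smaller, so
the adult profile requires only p < 0.05 and adjusted R² > 0.8. "R²" is
read as adjusted R² by default in both profiles (`use_adjusted_r2` flips
this) — the adjusted form is the conservative choice at these small n. All
thresholds are strict inequalities except the fetal R² bound; a slope of
exactly 0.1 per 10 weeks does not flag.

The interaction model is β ~ status + age + status:age. By OLS algebra the
interaction coefficient equals the case-minus-control slope difference from
two separate per-group fits (asserted to 1e-8 in tests), and the status
coefficient is the baseline offset. Differential-maturation flags add
p_interaction < 0.05 (plus the fetal magnitude criterion
|interaction| > 0.1 per 10 weeks). Trajectory summaries average the panel's
β per sample first and then fit one line per group — averaging before
regression, not averaging per-CpG fits, so the summary line is the line of
the panel mean.

## Enrichment statistics

All set-overlap p-values come from one upper-tail hypergeometric
implementation (P[X ≥ k]); fold = (k/n)/(K/N) and the odds ratio comes from
the 2×2 table. Genomic context uses BED-style 0-based half-open intervals:
island = inside a CGI, shore = within 2,000 bp of a CGI edge (the standard
convention; shores are not otherwise defined for these data), promoter =
TSS ± 1,000 bp. Chromatin states follow the usual histone-mark precedence:
H3K4me3 ∧ H3K27me3 ⇒ poised (bivalent) promoter, H3K4me3 ⇒ active promoter,
H3K4me1 ∧ H3K27ac ⇒ active enhancer, H3K4me1 ∧ H3K27me3 ⇒ poised enhancer,
H3K4me1 alone ⇒ intermediate enhancer, else none — total on all flag
combinations.

Known-motif enrichment is logistic: outcome = DM membership, predictor =
presence (≥ 1 bp overlap) of a motif instance in the half-open 200-bp
window [pos−100, pos+100) around each CpG; the odds ratio is
exp(coefficient), which for a single binary predictor equals the 2×2 sample
odds ratio exactly. Motifs present in none or all windows are reported as
inestimable rather than given a fake OR. Expression-pattern classes from
per-tissue Z-scores apply the four rules (brain-specific expression,
brain-specific repression, other-tissue-specific, multi-tissue) with
first-match precedence, which resolves their overlapping definitions;
genes with no tissue-restricted signal fall into the multi-tissue bucket.

## Windowed WGBS caller

Inputs are single-genome count tables (no biological replicates — evidence
comes from read depth). CpGs under 20× coverage are removed (the boundary
20× is kept). Engineered duplications are confirmed by the coverage ratio:
depths are normalized by each library's total read count, and the region
summary is the ratio of mean normalized depths inside the region (flanking
summary: same, outside the region on that chromosome). Ratio-of-means is
used rather than mean-of-ratios, which would carry a ~1/depth upward bias.

A 1-kb window is called DM when ≥ 3 member CpGs (case/wt shared, coverage-
surviving) have |Δfraction| > 0.15 and all such CpGs agree in direction —
one discordant DM CpG vetoes the window. Higher stringency additionally
requires ≥ 1 of the window's DM CpGs to reach two-sided Fisher exact
p ≤ α on its methylated/unmethylated 2×2 table; α runs down the ladder
{0.05, 0.01, 0.005, 0.001}, and because the gate is a threshold on the
window's minimum Fisher p, call sets are nested and counts are monotone
non-increasing. The Fisher p is computed by summing hypergeometric
probabilities ≤ the observed table's (with a 1+1e-7 relative tolerance for
ties, matching the conventional two-sided definition) and is memoized —
depth combinations recur constantly. The optional Wilcoxon gate is a paired
signed-rank test across the window's member-CpG fractions (exact
distribution for ≤ 25 non-zero differences, normal approximation above;
all-zero differences ⇒ p = 1). The composite confidence score of a called
window is √(median|Δ| over its DM CpGs × n_DM) — "its DM CpGs" means the
delta-passing CpGs at the active stringency level, a documented reading of
an ambiguous phrase. The Fisher-significant CpG must itself be one of the
DM CpGs (same reading).

## Cross-species concordance

Human probes with lifted-over mouse coordinates become 1-kb mouse windows
[pos−500, pos+500), duplicates collapsed, malformed rows rejected with a
log entry. Mouse DM genes are derived from called windows; when a gene has
both gain and loss windows, the direction of its highest composite-score
window wins (the per-gene direction rule is otherwise unconstrained).
Concordance counts genes DM on both sides with matching direction and
tests enrichment against the universe of mappable, coverage-surviving
genes. Note a calibration subtlety: the hypergeometric expectation governs
*membership* overlap, so for independent random sets the direction-matched
fold sits near 0.5 (the direction-match factor under symmetric directions),
not 1 — the direction requirement makes the default mode conservative
under the null. `require_direction=False` recovers the exactly calibrated
membership-only overlap; the test suite uses it for the independence null
and the direction-aware mode for planted signal.

## Synthetic cohorts: what they emulate, and what they do not

The generators produce the study's input shapes with planted truth.
Baseline per-CpG methylation is a 50/50 mixture of Beta(2,10) and
Beta(10,2) — a bimodal methylome. Noise is truncated-normal on the β scale
(default sd 0.05 for arrays), clipped to [0, 1]; this is a transparent
stand-in, not an inference about real inter-individual variability, which
is neither independent across CpGs nor homoscedastic. CpGs carrying planted
effects get baselines with headroom (e.g. uniform in [δ+0.05, 0.95−δ]) so
the planted delta survives clipping intact — otherwise "planted Δ = 0.25"
would be a lie at extreme baselines. Array defaults mirror the fetal-brain
arm of the study design: 10+10 samples, 2% DM CpGs at Δ = 0.25, gestational
ages 13–18 weeks, age slope 0.2 per 10 weeks, interaction −0.13 per 10
weeks, one batch (batch shift 0.05 when several are requested). The
BS/OXBS generator plants the full delta on each affected mark (both marks,
same direction, for the additive class) so the planted truth labels match
the modality screen's own thresholds. The WGBS generator uses Poisson
depth around 28× (the sequencing-depth scale of the mouse arm; acceptance
runs use 30×), binomial methylated counts, CpGs every 100 bp on one
contig, and plants regional DM across all CpGs of each chosen 1-kb window
— contiguous planted CpGs, as regional methylation differences affect CpG
runs, and a minimum of 3 per the window contract. The engineered
duplication is a 1.5× depth multiplier over ~2% of the contig: small, as a
sub-chromosomal duplication is relative to its chromosome, so total-read
normalization leaves flank ratios near 1. Coordinates are 0-based
half-open throughout; all generators are deterministic given their seed.

Passing tests on these cohorts demonstrate that the estimators recover
what they claim under the stated noise model at the stated sizes — they do
not demonstrate robustness to correlated probes, cell-type composition
drift, coverage biases, or batch-by-probe interactions, none of which are
simulated.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` size their simulations to make
the measured rates statistically meaningful: 10,000 CpGs for DM-caller
sensitivity/FDR and null calibration (200 planted DM CpGs), 3,000 CpGs
(180 planted) for modality recovery, 200 replicates for interaction-slope
recovery, 40,000 CpGs/200 planted windows for WGBS sensitivity, 1,000,000
CpGs (100,000 windows) for the WGBS false-call rate — that rate sits near
0.9%, so resolving it below 1% needs a standard error near 3×10⁻⁴ —
50,000 CpGs for the duplication ratio (1,000 CpGs inside the duplication),
and 30,000 CpGs/90 planted windows for the cross-species ladder. The
exact-test sweep covers all 5,370 2×2 tables with every margin ≤ 12. The
full acceptance run takes ≈ 90 s on one CPU.

## Known limitations

* Single-genome WGBS comparisons cannot separate biological from technical
  variation; the Fisher ladder quantifies read-level evidence only.
* The batch model assumes additive, probe-shared batch effects on the β
  scale; interaction-type batch artifacts pass through.
* BH q-values are per-analysis; combining tissues requires re-correction.
* The 5hmC subtraction estimator is noisier than either input and biased
  upward at 0 by clamping; modality classes near the Δ threshold are
  sensitive to that bias.
* Gene aggregation treats annotation multi-mapping as multiplicity, so
  gene counts depend on the annotation's transcript resolution.
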