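# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `cernax`, and states what the synthetic-data
generator does and does not emulate.

## Differential expression engine

The DE engine is a deliberately transparent approximation of the classic
count-based two-group workflow, not a re-implementation of any particular
package's internals. It is pluggable: any externally produced DE table
with columns `gene, rna_class, cancer, log2fc, pvalue, padj, direction`
can be substituted downstream.

**Normalization (TMM).** Library scaling factors are trimmed means of
M-values. The reference sample is the one whose 75th-percentile CPM is
closest to the across-sample mean of that percentile. For each sample
against the reference, genes positive in both libraries contribute
M = log2 ratio and A = mean log2 abundance of the CPM values; genes in the
upper/lower 30% of M-ranks or 5% of A-ranks are trimmed, and the remaining
M-values are averaged with inverse-asymptotic-variance weights. The weights
are computed on the proportion (CPM) scale, `(1−p_obs)/p_obs +
(1−p_ref)/p_ref`, which makes the factors exactly invariant to a pure
sequencing-depth change of either library (the library-size version of the
weights is only approximately so). Factors are rescaled to geometric
mean 1. A sample with zero total count is a hard error.

**Dispersion.** Counts are modelled NB with variance μ + φμ². φ is
estimated per gene by the method of moments on normalized counts,
`max(0, (s² − μ̄)/μ̄²)`, computed within each condition and pooled with
degree-of-freedom weights so a real tumor/normal difference does not
inflate it, then shrunk half-way (weight 0.5, configurable) toward the
across-gene median and floored at 1e−8. There is no abundance-trended
dispersion; for matrices of a few hundred to a few thousand genes the
median is a stable shrinkage target.

**Test.** For each gene a likelihood-ratio test compares the two-group-mean
NB model against the pooled-mean model with φ fixed at its estimate;
group means are fitted by Newton iterations on the log-mean with effective
library sizes as offsets (score and expected-information updates, step
clipped to ±5, ≤50 iterations, tolerance 1e−10). The statistic is referred
to χ²(1). log2FC is computed from normalized group means with a 0.5/n̄
pseudo-count (n̄ = mean group size) so zero groups stay finite. BH
adjustment is applied within each (cancer, RNA class) stratum — the runs
are performed separately per class and cancer, and the adjustment follows
that stratification (documented choice; the alternative of a joint
adjustment across classes is not used). Direction calls are strict
comparisons: up ⟺ log2FC > τ and padj < α, down symmetric. τ defaults to 1
and is per-cancer configurable (e.g. 0.585 ≈ log2 1.5 for a cancer whose
axis screen comes up empty under τ = 1); α defaults to 0.05.

Null calibration of this engine (NB data, no planted effects, n = 50/50,
φ = 0.1, 200 genes × 20 seeds) yields a p < 0.05 fraction within
[0.03, 0.07] and pooled p-values consistent with uniformity (KS p > 0.01);
the acceptance suite recomputes both.

## Cross-cancer categories

A signed DE gene's membership set is the set of cancers where it carries
that sign. Per sign: |members| = k (the panel size) → **shared**,
|members| = 1 → **specific**, otherwise **semi-shared**. Up and down
memberships are categorized independently, so one gene can hold one
up-assignment and one down-assignment; a gene dysregulated everywhere with
mixed signs is *not* shared — shared status requires one consistent sign.
The rules generalize to any panel size k ≥ 2. UpSet counts tally each gene
in exactly the combination equal to its member set.

## ceRNA network assembly

Candidate edges join genes of the requested category through the supplied
pair tables: lncRNA–miRNA pairs are used as given (family-level conserved
target predictions carry no per-pair evidence), miRNA–mRNA pairs must be
supported by at least `min_support_db` of the seven target-prediction
databases and at least `min_clip` CLIP experiments (both inclusive,
defaults 2 and 1). An edge requires opposite dysregulation signs and at
least one common member cancer; its cancer annotation is the intersection
of the endpoints' member sets. This common-cancer rule is what makes
per-cancer *portions* of the semi-shared network well-defined: the portion
for cancer c keeps edges whose annotation contains c and re-prunes.

After edge construction the graph is pruned to a fixed point: every miRNA
must retain at least one lncRNA-side and one mRNA-side edge, and no node
may be isolated. Pruning is a monotone node-removal process, so the fixed
point is unique and insertion-order independent, reached in at most
|nodes| sweeps.

If a gene carries two assignments of the requested category (possible for
specific and semi-shared), one is chosen deterministically — the larger
member set, ties resolved toward up — so node direction is single-valued.

**Sub-ceRNA extraction** around key genes keeps the key mRNAs, the miRNAs
adjacent to at least one of them, and the lncRNAs adjacent to those
miRNAs, then restores the invariants by pruning; key lncRNAs are flagged
in the node attributes rather than seeding the neighborhood (a
configurable interpretation — the alternative of also expanding from key
lncRNAs would add their miRNAs' other mRNA targets).

## Prognostic screening

Each network gene is screened with a univariate Cox proportional-hazards
model. The covariate is the z-score (population SD, which makes the fit
exactly invariant to record replication) of log2(normalized expression
+ 1) over the cancer's tumor samples, so β is the log hazard ratio per
1 SD. The Breslow partial likelihood is maximized by Newton–Raphson
(tolerance 1e−8 on |Δβ|, ≤50 iterations, step clipped to ±2 against
near-separation); the standard error comes from the observed information
and the p-value from the two-sided normal tail of β/se. Constant
covariates, zero events, and information-free risk sets are hard errors;
the pipeline logs and skips such genes. Efron tie handling is not
implemented; Breslow was chosen because it is directly checkable against
grid maximization of the likelihood, and the screening operates on
continuous survival times where heavy ties are rare.

The screen keeps genes with raw p < 0.05 — deliberately no multiplicity
adjustment, a faithful-but-liberal screening choice; the BH machinery is
available if a user wants to post-process the emitted tables. **Key genes**
pair the expression direction with prognosis: up-regulated with HR > 1
(oncogene candidates) and down-regulated with HR < 1 (suppressor
candidates). When a validation DE table from an independent cohort is
supplied, a key gene must show the same direction there at padj < α;
miRNAs skip this validation (typical validation resources do not cover
them). A median-split covariate variant is available (`dichotomize=True`
in the library, `--dichotomize` on the CLI) as a sensitivity analysis;
continuous is the default and the documented primary analysis.

## Axis mining

For every lncRNA–miRNA–mRNA path of a sub-network (a lncRNA–miRNA edge and
a miRNA–mRNA edge through the same miRNA), three Pearson correlations are
computed on log2(normalized expression + 1) over the tumor samples shared
by the three matrices (Spearman available behind a flag; tumor-only is the
default because the sponge competition is a property of the tumor tissue).
A triple passes iff r(mRNA, miRNA) < 0, r(miRNA, lncRNA) < 0,
r(mRNA, lncRNA) > 0, each with two-sided p < α (strict, default 0.05). The
filter also runs on externally computed correlation tables with the layout
`cancer, mRNA, miRNA, lncRNA, r_mm, p_mm, r_ml, p_ml, r_lm, p_lm`.

The packaged correlation table (`cernax/data/cerna_axis_correlations.tsv`)
is a curated transcription of reported TCGA tumor co-expression values for
26 candidate axes in STAD, LIHC and COAD; one mRNA–lncRNA p-value was
printed in its source with an impossible positive exponent and is recorded
with the corresponding negative exponent (flagged in the file header).

## Enrichment

Over-representation uses the upper hypergeometric tail P(X ≥ overlap)
via scipy's log-space survival function. The universe defaults to the
genes actually tested for DE in the run (not a whole-genome list), because
an honest background for a count-filtered experiment is the tested set;
it is configurable. Sets are kept at overlap ≥ 2 and raw p < 0.01; a BH
column is reported for information only.

## Synthetic-data generator

The generator emulates the *statistical* structure the pipeline assumes,
with a manifest of planted truth:

- **Counts**: NB(μ, φ) with variance μ + φμ²; per-gene baselines are
  log-normal (median 100 counts, log2-SD 2 — a typical bulk RNA-seq
  abundance spread) and one φ (default 0.1, a typical tumor-cohort value)
  is shared per design. Planted DE multiplies tumor means by 2^±log2fold
  in the configured cancer subset.
- **ceRNA coupling**: per planted axis and tumor sample a latent factor
  u ~ N(0, 1) shifts log2 means by +γ_L·u (lncRNA), −γ_m·u (miRNA),
  +γ_R·u (mRNA). This targets the predicted correlation signs directly
  rather than modelling titration kinetics — the pipeline's claims are
  about the sign pattern, so the generator plants exactly that, in tumor
  samples only.
- **Interaction tables**: all planted-axis pairs (miRNA–mRNA evidence
  drawn within the passing range) plus decoy triples whose evidence counts
  are uniform over the full valid-and-invalid range, so the evidence
  filter is genuinely exercised.
- **Survival**: exponential event times with hazard λ0·exp(Σ β_g z_g)
  over the planted prognostic genes (z = standardized expression),
  censored at a fixed horizon. Defaults λ0 = 5e−4/day and C = 1825 days
  give roughly 60% events over a five-year follow-up.

Randomness derives from one root seed split hierarchically by
`SeedSequence` spawn keys (stage → cancer → class → gene), so enlarging a
design leaves existing draws untouched and identical (design, seed) pairs
are byte-reproducible.

The default design plants 20 axes with γ = 0.8 in a 4-cancer panel at
100 tumor / 50 normal samples with 200 decoy pairs; axis members are also
planted DE with the ceRNA sign pattern (lncRNA up, miRNA down, mRNA up,
|log2FC| = 2) in all four cancers, and axis mRNAs (β = 0.5 per SD) and
lncRNAs (β = 0.4) carry survival effects, because the full workflow only
mines axes around genes that survive the prognostic screen. With 40
simultaneously prognostic genes per cancer, each univariate fit sees the
other 39 as omitted covariates, which attenuates per-gene power to
roughly 30–55% per cancer; an axis is counted as recovered when it passes
the filter in at least one of the four cancers, which the test suite
verifies happens for ≥80% of planted axes (it averages ≈90% over ten
seeds), while uncoupled decoy triples pass at no more than twice the
nominal α.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: batch and purity effects, library
composition bias beyond what TMM corrects, trended (abundance-dependent)
dispersion, miRNA isoform structure, copy-number confounding of
expression–survival links, non-proportional hazards, and the heavy
right-censoring patterns of registry data. Recovery rates on synthetic
data are upper bounds under a correctly specified noise model.

## Problem sizes in the shipped test suite

The suite runs the recovery analysis at the study conditions (4 cancers,
100/50 samples, 20 axes, 200 decoys) with a reduced background of
250/120/500 genes per class over 10 seeds, and the full workflow once at
the full default size (700/300/2000 genes per class); DE calibration uses
200 genes × 20 seeds at n = 50/50 and Cox calibration 1000 null
simulations at n = 100. These sizes were chosen to make the checks sharp
while keeping the suite quick to run on a laptop.

## Degenerate inputs and numerical conventions

- Counts must be non-negative integers; decimals are rejected, not
  rounded. Duplicate gene ids, unannotated samples, non-positive survival
  times and events outside {0, 1} are hard errors naming the offender.
- Expression matrices with a single gene cannot be library-normalized
  (the gene is its own library); correlation analyses on such inputs fail
  loudly with a zero-variance error.
- All threshold comparisons mirror their definitions: strict for p-values
  and |log2FC|, inclusive (≥) for interaction-evidence counts.
- Empty networks, empty pair tables and empty DE inputs propagate as
  empty results with warnings, never as crashes, so a cancer with no
  findings does not abort a panel run.
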