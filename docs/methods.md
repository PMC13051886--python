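# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `mircell`.

## Moderated differential expression

Each feature's log2 expression is regressed on an intercept, a case/control
indicator, and optional sample-level covariates (surrogate variables, and/or
user covariates), optionally with per-array observation weights.  Residual
variances s²_g with df d_g are shrunk toward a prior (d₀, s₀²) fit by moment
matching of log variances: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the
prior df solves ψ′(d₀/2) = Var(e) − ψ′(d_g/2) (Newton inversion of the
trigamma function) and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).  When the
excess variance is non-positive the prior df is reported at the cap 10⁶
(total shrinkage); d₀ = 0 reproduces the classical pooled t exactly and is
the closed-form oracle used in the tests.  A second, independent check
compares the full fit (t statistics, d₀, s₀²) to the reference
empirical-Bayes implementation in R on a small heteroscedastic instance.

Array quality weights are a simplified heuristic — weight_j ∝ inverse of
array j's mean squared residual from an unweighted first fit, normalized to
mean 1 — not the gene-by-gene REML estimator of the original method; exact
agreement with analyses that used the original weights is therefore not
expected.

### Surrogate variables

The residual matrix after removing the primary fit is decomposed by SVD; the
right singular vectors are candidate surrogates (orthogonal to the fitted
group structure by construction).  The count is chosen parallel-analysis
style: each observed singular value must exceed the 95th percentile of the
corresponding singular values of 20 within-row-permuted residual matrices.
The permuted matrices are residualized a second time so their rank matches
the observed residual, and rescaled by √(n/(n−p)) to restore the variance
the extra projection removes — without this the null is deflated and the
procedure over-reports surrogates on pure-noise data.  On null simulations
the procedure returns zero surrogates in ≳95% of runs; a planted batch shift
of 2× the noise sd on half the features is recovered with |r| > 0.8 to the
true batch label.

### Multiple testing

Storey q-values estimate π₀ on the grid λ = 0.05, …, 0.95 with a cubic
polynomial fit evaluated at λ = 0.95 (clipped to (0, 1]); q_i =
π₀·min over p_j ≥ p_i of p_j·m/rank_j.  Fixing π₀ = 1 reproduces
Benjamini–Hochberg exactly, which is asserted in the tests.

## Set enrichment

ORA uses the hypergeometric upper tail with an explicit universe (always an
argument, never implicit); sets with fewer than 8 members in the universe are
dropped by default.  The directional z-score is (u − d)/√n where u and d
count the up-/down-regulated DE members and n is the category size; the row
stores u, d and n so any variant of the summary is recomputable.

Preranked GSEA sorts features by statistic (ties by id), accumulates
|stat|^p (p = 1 by default) normalized by the in-set total at hits and
−1/(N−|S|) at misses; the ES is the signed extremum, with an exact
|extremum| tie resolving to the positive excursion.  The null permutes
feature labels (equivalently, resamples hit positions); NES divides ES by
the mean |null ES| of matching sign, and the p-value is the add-one-smoothed
fraction of same-sign null ES at least as extreme (the smoothing keeps p
positive at finite permutation counts).  Exhaustive evaluation of the
running-sum definition over all subsets of rankings with N ≤ 8 is the test
oracle.

## Binding-site enrichment and activity inference

Gene-level motif presence drives the 2×2 tables: a = DEGs of the tested
direction bearing the motif, b = other universe genes bearing it, c = DEGs
lacking it, d = the rest.  The two-sided p uses the minimum-likelihood
convention (sum of table probabilities ≤ the observed), matching the common
default for 2×2 exact tests and verified against full enumeration.  The
sample odds ratio gains +0.5 in every cell when any cell is zero
(Haldane–Anscombe) and is reported on the log2 scale.  The per-(motif, gene)
site counts are summed into a descriptive `site_overlap` column but do not
enter the test.  Significance is BH-adjusted p < 0.05 across all
motif × direction tests, with OR > 1 required (enrichment, not depletion).
Estimated activity maps enrichment among UP genes to "Downregulated" miRNA
activity and vice versa; the intersection step keeps motifs with at least
one DE-miRNA whose observed direction equals the estimated activity.

Network assembly keeps interaction edges whose miRNA is influential and
whose gene is DE opposite to the miRNA's activity (down-active miRNA → up
gene).  Predicted interactions can be pre-filtered by a confidence class
(default {very high, high}); validated interactions always pass.

## qPCR arithmetic

The 2^(−ΔΔCt) method averages replicate Cts per (sample, assay), subtracts
the reference assay, and baselines to the mean control ΔCt, which makes the
geometric mean of control folds exactly 1.  Efficiency is
E% = (10^(−1/slope) − 1)·100 from an OLS standard curve of Ct on
log10(dilution); a slope of −3.3219 Ct per decade gives E% = 100.0 (to one
decimal; −1/log10(2) is irrational).  Efficiency is reported but not used
to correct folds.  Housekeeping candidates are ranked by coefficient of
variation computed on the linear scale (2^log2 values; the scale is a
package choice — Ct-scale and log-scale CVs differ), with eligibility
filters "invariable between conditions" (Welch p > 0.5, a deliberately
conservative cut) and "highly expressed" (top quartile of mean expression).
Candidates constant in both groups count as maximally stable (p = 1).

## Single-cell stage

Gating requires a nonzero count of CD3G and of CD8A or CD8B ("expression"
has no published cutoff; > 0 is the package's rule).  QC flags cells more
than 3 MADs below the median of log1p(total) or log1p(detected), or above it
for mitochondrial percentage; the MAD is floored at 5% of the median so that
perfectly homogeneous (discrete) data, where the MAD degenerates to zero,
flags nothing.  Normalization scales each cell to the median library size
and applies log2(x+1).  HVGs are ranked by residual variance above a lowess
mean–variance trend (frac = 0.3), ties broken by gene id.

Batch alignment is an intentionally simplified mutual-nearest-neighbor
scheme: PCA on the HVG log layer (50 components by default), batches merged
in decreasing-size order, MNN pairs (k = 20) defining per-pair difference
vectors, and each incoming cell shifted by a Gaussian-kernel-smoothed
average of those differences (bandwidth = mean k-NN distance within the
incoming batch).  It removes translation-like batch effects (≥ 80% centroid
convergence on planted constant shifts, near-identity on null batches) but
performs no cosine normalization or per-gene correction; exact reproduction
of the original algorithm is out of scope.

Clustering builds a k = 5 nearest-neighbor graph (Euclidean in the corrected
embedding), weights edges by the Jaccard index of neighbor sets, drops
zero-weight edges, and runs seeded Louvain modularity optimization; labels
are ordered by descending cluster size.  At resolution 1 Louvain genuinely
sub-partitions large homogeneous point clouds (a known property of
modularity on geometric graphs); the blob-recovery tests therefore use a
low resolution, while the pipeline default stays at 1.0.  Label transfer is
a nearest-profile classifier (Spearman correlation over the HVG∩reference
genes, argmax over labels) without the original method's iterative
fine-tuning; in synthetic tests cluster identities come from planted truth
labels, not transfer.

### Pseudobulk NB quasi-likelihood DE

Counts are summed per donor (donors under 10 cells dropped), normalized by
TMM factors (reference column by 75th-percentile rule; M trimmed 30%, A
trimmed 5%; inverse-asymptotic-variance weights; geometric mean 1 — verified
against the reference R implementation to ~10⁻⁴), and filtered to genes with
≥ 1 CPM in at least the smaller group's number of donors.  Per-gene NB
dispersions are profiled on a 19-point log grid by exact NB likelihood at
IRLS-fitted means, then replaced by a lowess trend on log abundance: the
trended dispersion enters the GLM, and gene-wise departures are absorbed by
the quasi-dispersion, σ²_g = residual deviance / df, shrunk by the same
moment-matching empirical Bayes used for the moderated t.  The QL F
statistic is the one-df deviance drop over the shrunken σ², referred to
F(1, d₀ + df).  This is an approximation to the reference QL pipeline (no
Cox–Reid adjusted profile likelihood); its type-I error on null cohorts
(6 vs 6 donors) is calibrated to 3–7% at p < 0.05 and its power on planted
2-fold genes (μ = 100, φ = 0.1) exceeds 70% sensitivity at q < 0.1, both
asserted in the tests.

## Cell programs

TF activity fits, per cell, a seeded random-forest regression (100 trees,
depth 3, bootstrap over genes) predicting the cell's log expression vector
from the gene × TF signed membership matrix; activity is the normalized
impurity-reduction importance (sums to 1 per cell).  Whether importances
should be normalized per cell is a package choice; constant-expression cells
return uniform importances with a degenerate flag.  Per-TF donor-mean Welch
tests are deliberately uncorrected for multiplicity (a flag notes this; BH is
available on the result table).

AUCell-style scoring ranks each cell's genes by descending raw count with a
single seeded random permutation breaking ties (so zero-inflated counts do
not bias the ranking deterministically), builds the signature recovery curve
over the top 5% of ranks, and normalizes its area by the maximum achievable
area.  The 5% window is the customary default of the reference scorer; the
classification thresholds are fixed constants (CD8-Treg 0.17, Tc17 0.22,
boundary inclusive).  Brute-force step-curve integration on instances with
≤ 30 genes is the test oracle.

## Synthetic data generator

All randomness flows from one seeded generator per call (the config seed
plus a fixed per-generator stream id); identical configs give byte-identical
outputs, asserted in the tests.

*Bulk layers* are Gaussian on the log2 scale (microarray-like): feature
baselines N(8, 2), iid noise sd 0.3, n = 10 per group, 400 miRNAs.  Planted
DE features shift by a signed effect (default |1| log2) in cases; batch
effects are additive Gaussian shifts (sd `batch_sd`) shared within a batch
and applied to half the features, with batches balanced across groups so
surrogate-variable recovery is a meaningful test.  The regulated
transcriptome gives each planted down-regulated miRNA 60 disjoint target
genes shifted up by suppression·|effect| in cases; each regulator's 7-mer
motif decorates every target plus ~2% of background genes, and decoy motifs
and decoy predicted interactions provide realistic negatives.

*Single-cell layer*: 12 donors per group, 400 cells per donor, 1000 genes,
NB counts with dispersion 0.3, gene means log-normal around 0.5 counts/cell,
gating markers (CD3G/CD8A/CD8B) at mean 8 so nearly all cells pass the gate,
10 mitochondrial genes at mean 3, and per-cell size factors log-normal
(sd 0.3).  Signature genes have baseline mean 1.5 counts/cell and are
multiplied by signature_fold = 4 in program-positive cells.  The signature
baseline and dispersion were fixed at design time so that positive cells
place most signature genes inside the top-5% ranking window — the premise
under which fixed AUC thresholds separate the score distribution, mirroring
how such thresholds are chosen from real score distributions.  Default
planted frequencies are Tc17/Treg 2% in controls and 4% in cases.

*qPCR layer*: per-assay base Cts U(20, 28), per-sample loading offsets
(cancelled by the reference assay), replicate noise sd 0.2, and a planted
fold f appearing as a case Ct offset of −log2(f) (100% efficiency).
Standards follow Ct = intercept + slope·log10(dilution) with slope −3.3219
and, by default, no noise, so the efficiency round trip is exact.

**What the generator does not emulate** — probe-level microarray artifacts,
outlier arrays, mRNA–miRNA shared-donor correlation structure, single-cell
doublets, ambient RNA, batch-specific library chemistry, dropout beyond NB
sampling, or sequence-level motif discovery (sites are tabulated, not
scanned).  Passing tests therefore demonstrate correctness of the statistics
and recovery under the stated model, not robustness to every artifact of
real cohort data.

## Problem sizes and runtime

The test suite and the acceptance script run the study at desk scale: 100
null-array replicates, 1000 null motif-decoration draws, 50 null single-cell
cohorts of 2000 genes (6 vs 6 donors), 20 integrative-recovery seeds
(400 miRNAs, 4000 genes, 10 planted regulators), and 20 subpopulation
cohorts (9600 cells each).  These sizes give stable Monte-Carlo estimates of
the calibration fractions and recovery rates in a few minutes on one CPU.

## Known limitations

* Array weights, MNN correction, label transfer, and the QL dispersion
  machinery are documented simplifications of the methods they stand in for;
  analyses that depend on the exact original estimators will differ.
* The Louvain resolution, QC thresholds, and AUCell window are conventions;
  results on real data are sensitive to them.
* Fisher tables are gene-level; a site-count-level variant would weight
  multi-site targets differently.
* The qPCR CV scale (linear) and the housekeeping stability cut (Welch
  p > 0.5) are package choices where no published value exists.
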