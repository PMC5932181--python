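# Methods

## Model and procedure

The pipeline treats each (miRSNP, miRNA, gene) triple as a hypothesis
that the SNP's minor allele creates (C) or disrupts (D) a miRNA binding
site in the gene's 3′ UTR, and accumulates independent lines of evidence
for it.

**Evidence combination.** Raw scores from the three prediction tools are
not commensurable, so each tool's scores are z-standardized within the
tool's full score set in the current run (sample standard deviation,
n − 1). The combination rule

S = 1 − ∏ᵢ (1 − Sᵢ)

requires per-tool evidence values Sᵢ on [0, 1]; the mapping from the
harmonized z scale to the unit interval is a modeling choice of this
package, and we use the standard normal CDF, Sᵢ = Φ(z). It is monotone,
parameter-free, and treats the within-tool score distribution as the
null reference — a triple scoring at a tool's mean contributes Sᵢ = 0.5.
Rank- or min–max-based alternatives would serve too; the CDF was chosen
because it is smooth and does not depend on the extremes of the batch.
A triple scored by fewer than three tools is combined over the tools
present (an absent tool contributes the factor 1, i.e. no evidence either
way); at least one tool is required. The consensus effect is the
unanimous tool call, with any disagreement labelled `ambiguous`.
Candidates must exceed S > 0.7 strictly.

**Standardization scope.** z-scoring uses the candidate universe of the
current run, not a genome-wide reference distribution. Consequently S
values are relative to the analyzed batch; adding many strong triples to
a run shifts everyone's z downward. This mirrors how the integration was
set up originally and keeps the package self-contained.

**GWAS support.** Per disease, lead SNPs are those with P strictly below
5×10⁻⁸; multiple studies of one disease are merged by each rsid's
minimum P (the merge rule is our choice; the source cohorts do not state
one). A candidate gains support either directly or as an LD proxy of a
lead: r² ≥ 0.8 (inclusive) and D′ = 1 within 1e-6. The D′ requirement
can be switched off (`require_dprime=False`). Direct support is
preferred; proxy support picks the highest-r² qualifying lead, ties
broken by lead rsid lexicographically, and leaves P/OR missing — the SNP
itself was not evaluated by the study. Candidates then need ≥ 2 distinct
disease labels; inflammatory bowel disease, Crohn's disease and
ulcerative colitis are distinct labels and count separately.

**eQTL annotation.** Sources are pooled; matching is exact on
(rsid, gene). Records above FDR 0.05 are dropped at load time. Direction
labels must arrive minor-allele-oriented — the loader contract, since
public sources mix z-score, slope and allele-orientation conventions —
and tissue is annotation-only (no tissue filter). Concordance with the
predicted effect is evaluated only for single-direction annotations:
disrupt ⇒ up is concordant, create ⇒ down is concordant, the single
opposite direction is discordant, mixed directions are `ambiguous`
rather than majority-voted.

**Expression correlation.** Samples are matched by identifier
intersection (sorted). Correlation is sample Pearson r with the
two-sided t test, t = r·√((n−2)/(1−r²)) on n − 2 df, significant at
P < 0.05 per test. No multiple-testing correction is applied by default,
matching the plain per-test rule; `Config(bh_fdr=True)` switches the
significance flags to Benjamini–Hochberg rejection at the same alpha.
Genotype-stratified analysis restricts to dosage-0 (reference
homozygote) and dosage-2 (minor homozygote) samples; heterozygotes and
missing genotypes are excluded. Matrices declared log2 are passed
through; raw counts are transformed as log2(x + 1) on load.

Correlations reported by the source literature as negative "r²" values
are treated as Pearson r here; this package always reports r.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `nbc_threshold` | 0.7 | strict lower bound on the combined score S |
| `gwas_p_threshold` | 5e-8 | strict genome-wide significance limit |
| `ld_r2_min` | 0.8 | inclusive r² bound for LD proxies |
| `ld_dprime_required` | 1.0 (±1e-6) | required D′ for proxies |
| `min_shared_diseases` | 2 | distinct disease labels required |
| `eqtl_fdr_max` | 0.05 | load-time FDR cut on eQTL records |
| `corr_p_threshold` | 0.05 | two-sided significance limit for Pearson tests |
| `min_stratum_size` | 3 | smallest homozygote stratum tested (t test needs n ≥ 3) |

The source method states every default above except `min_stratum_size`,
which is the mathematical minimum for a defined t test.

## Synthetic data generator

`simulate()` emulates the statistical structure the pipeline assumes,
with a planted truth set whose members satisfy all pass conditions by
construction. Defaults define the study-scale conditions: 2,000
variants, 20 planted miRSNPs, 12 diseases, 300 samples; per-tool z-scale
signal shift 2.5 for true triples (so the combined score clears 0.7 with
probability > 0.99); planted lead P drawn log-uniform between 1e-9 and
1e-20; planted proxies at r² = 1, D′ = 1 and decoy LD pairs strictly
below r² = 0.8; genotypes Binomial(2, MAF) under Hardy–Weinberg with
MAF uniform on [0.1, 0.5] and 1% missingness; expression log2-scale
Gaussian with the target mRNA of a coupled truth linearly driven by its
miRNA (slope −0.8 for created sites, +0.8 for disrupted, unit noise)
among minor-allele homozygotes only; 80% of truths carry concordant eQTL
records at FDR 0.01; a subset of truths appears in the validated table.

Under these conditions a false positive requires a null triple to clear
the combined-score cut *and* to collect two diseases with significant
leads; null GWAS P is Uniform(0, 1), so the compound null probability is
negligible and the expected false-positive count per run is ~0. This is
why end-to-end recovery (≥ 19/20 truths, 0 false positives) is a
meaningful sensitivity measure.

What the generator does **not** emulate: realistic LD block structure,
population stratification or relatedness, read-count noise and
library-size effects, inter-gene expression correlation, winner's-curse
effect-size inflation, or allele-frequency differences between the GWAS
and expression cohorts. Passing tests therefore demonstrate the
pipeline's logic and calibration under its own assumptions, not
robustness to the confounders of real cohort data.

## Numerical choices

- All threshold comparisons on P and S are strict (`<`, `>`); the r²
  bound is inclusive. A fixture record printed exactly at 0.70 is
  accepted as published (it passed the original filter before rounding).
- z-scoring errors out (naming the tool) for < 2 predictions or zero
  spread rather than emitting NaN.
- Pearson r is clipped to [−1, 1] before the t transform; perfectly
  collinear inputs get P at the smallest positive float rather than 0 so
  the (0, 1] invariant holds. Zero-variance vectors and undersized
  strata yield flagged-undefined results (`ok=False`), not exceptions,
  so batch runs proceed.
- Proxy tie-break: highest r², then lexicographically smallest lead rsid
  — deterministic across runs and platforms.
- Generator determinism: one integer-seeded NumPy generator, fixed draw
  order; identical seeds produce byte-identical written bundles.

## Test problem sizes

The default suite exercises the study-scale bundle (2,000 variants / 20
truths / 300 samples) once per session plus a reduced bundle (200 / 6 /
150) for per-stage tests; oracle comparisons use 10,000 random score
sets for the combiner, 500 random vectors plus 1,000 null replicates
(n = 100) for the Pearson engine, and 30 random instances of ≤ 50 SNPs
for the association filter. The stratified planted-signal check is
evaluated on strata with n ≥ 20, where a planted |r| ≈ 0.6 is well
powered; smaller homozygote strata (n ≈ MAF²·300) are genuinely
underpowered and are exercised separately through the flagged-undefined
path.

## Known limitations

- Gene matching is by symbol string; no alias dictionary.
- miRNA name canonicalization strips the species prefix and case only;
  arm suffixes (-3p/-5p) are never collapsed, so a validated table
  using a different miRBase version may silently miss matches.
- Indel alleles are stored verbatim (no normalization), and positions
  are hg38 1-based with no liftover support.
- The packaged published table stores MAF > 0.5 for two variants as
  printed; which population defines "minor" is a data-source convention
  the package does not resolve (a warning is raised on construction).
- LD proxying is population-agnostic: one LD table per run; population
  choice is a data decision, not code.
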