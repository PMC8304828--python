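# Methods

This note documents the models, defaults and numerical choices behind
each stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Association scan

Summary statistics are consumed as (snp, chrom, 1-based pos, p); no
genotypes are touched. Windows are *fixed tiles* anchored at bp 1, not
sliding: tiling gives each SNP exactly one window, which keeps the
composite score interpretable and the scan order-invariant. Window
width defaults to 20 kb — the scale of a typical LD block in European
populations and of the reduced "top SNP per window" tables fed to locus
plotting tools.

The composite score `S = -log10(min_p) + λ·n_sig` (λ = 1 by default)
combines association strength with local significant-SNP density. `S`
is defined as 0 when `n_sig = 0` so empty or null windows can never be
flagged regardless of their best p-value. The score threshold has no
universal default and must be set in the pipeline config; a useful
mental anchor is `S = 9`, the score of a window holding five nominally
significant SNPs with best p = 1e-4, which on null simulations
(10,000 SNPs on a 40 Mb chromosome, α = 0.05) flags essentially nothing
(≤ 2 loci across 100 seeded replicates, asserted in the tests).

Flagged windows merge into loci when separated by at most one window
width (configurable). The locus index SNP is the top SNP of the member
window with the smallest p; ties anywhere break by (p, position,
snp_id) so results are reproducible across row orders.

Multiple GWAS are handled by scanning each table separately and
intersecting loci by coordinate overlap; no p-value combination rule is
applied, since any such rule would be an invention layered on top of
the summary statistics.

## Gene mapping

Annotation intervals are 1-based inclusive (NCBI convention); BED4
input is converted at the reader. Overlap requires ≥ 1 bp; nearest-gene
distance is 0 inside a gene and the gap to the nearer boundary outside,
with alphabetical tie-breaks. Strand is carried but ignored — mapping
is purely positional, matching how locus gene lists are built in
practice.

## Expression convergence

Per-probe testing uses Welch's unequal-variance t-test: public
expression datasets almost never have balanced groups, and Welch costs
nothing when variances happen to be equal. Probes with zero variance in
both groups and equal means are reported as t = 0, p = 1 rather than
NaN. Missing values abort with the probe name; imputation is a
preprocessing decision that should not happen silently inside a test.

The convergence rule is deliberately strict: directional alignment is
enforced over **all** probes of a gene in every dataset where the gene
is significant, not just over its significant probes. A gene whose
probes disagree in sign — even when the discordant probe is itself
non-significant — is not called. Direction-0 probes (exactly equal
means) are neutral. The gene-level summary p is the minimum probe p
across significant datasets; this choice is conservative about
evidence aggregation (no independence assumption is invoked, unlike
Fisher/Stouffer combination) and is recorded in the output metadata.
FDR (Benjamini–Hochberg step-up) and Bonferroni run over the called
genes' summary p-values; by construction every Bonferroni survivor also
survives FDR.

## eQTL overlap

`z_to_p` uses `erfc(|z|/√2)` because the naive `2·(1 − Φ(z))` loses all
precision by |z| ≈ 8 and underflows to zero shortly after, while
published blood-eQTL Z-scores exceed 10. The implementation agrees with
an arbitrary-precision oracle to 6 significant digits for |z| ≤ 37;
beyond |z| ≈ 37.5 the true probability (< 1e-308) leaves the normal
range of double precision and gradually loses digits to subnormal
representation — a limit of the float64 result type, not of the
algorithm.

SNPs fed to the overlap are the nominally significant ones (p < 0.05 by
default, configurable) inside called loci. Ranking is by GWAS p first,
then eQTL p, then snp_id: the pipeline's question is "which
*disease-associated* variants are regulatory", so genomic significance
dominates, while both p-values are reported so the opposite tension (a
very strong eQTL with marginal association) stays visible.

## qPCR statistics

2^−ΔΔCt: technical replicates are averaged per (sample, gene); the
sample's housekeeping reference is the *arithmetic* mean of
housekeeping Ct values, which on the expression scale is exactly the
geometric average of the housekeeping genes (Ct is log2 expression);
ΔΔCt is referenced to the control-group mean so control relative
expression has geometric mean 1. The housekeeping argument is a list:
normalizing against GAPDH alone or against the geometric average of
GAPDH and β-actin are both common protocols, and both are runnable with
the same operation. The whole quantity is invariant to global and
per-sample Ct offsets, which the tests assert exactly.

Group comparison always reports both a Welch t on log2 fold values
(fold changes are closer to log-normal) and the Mann–Whitney U with its
two-sided p — published qPCR "t-test" statistics are sometimes
rank-sum statistics in disguise, and reporting both removes the
ambiguity. ROC AUC is the rank-based U/(n₁n₂) (ties at ½), with the
Hanley–McNeil (1982) standard error, a symmetric normal 95% CI
truncated to [0, 1], and a normal test of AUC = 0.5. The normal
approximation matches the "AUC ± SE, CI95%" convention of clinical
reports; a resampling CI would be the alternative but was not needed.
P-P coordinates use plotting positions (i − ½)/n against the standard
normal CDF of the standardized sorted sample.

## Network analysis

Interaction tables in the wild carry scores either in [0, 1] or on a
0–1000 integer scale; the reader divides by 1000 whenever any score
exceeds 1. Edge retention follows the "either coexpression or
experimental evidence ≥ 0.15" convention; filtering on the combined
score is available by naming the `combined` channel. Clustering is
k-means (10 restarts, seeded) on the leading k eigenvectors of the
symmetric-normalized adjacency D^−1/2 A D^−1/2 — a standard spectral
relaxation chosen because the clustering used by interaction-database
websites is unpublished; this is declared in the output metadata.
Shortest paths are unweighted BFS with alphabetical neighbor expansion,
so tie-breaking is deterministic.

## Synthetic data

The generators are pure functions of a `SimConfig`; every stream is a
`numpy` `default_rng` seeded by (stage-tag, seed), so stages are
independent and the whole bundle is byte-reproducible. Defaults, with
rationale:

| parameter        | default | rationale |
|------------------|---------|-----------|
| n_snps           | 10,000  | desk-scale table; with the 40 Mb chromosome gives ~1 SNP / 4 kb, between genome-wide array density (~1/6 kb) and fine-mapping density |
| chrom_length_bp  | 40 Mb   | one chromosome arm; ~10 SNPs per 20 kb window |
| ld_cluster_size  | 10      | co-significant SNPs per planted peak, a modest LD block |
| planted -log10 p | peak ± N(0, 0.5), floored at 1.3 | scatter of a real association peak without genotype modelling; the floor keeps cluster members nominally significant |
| probes_per_gene  | 3       | typical expression-array redundancy (multiple probe sets per gene) |
| n_case/n_control | 20/20   | the scale of public case/control expression datasets and of qPCR validation cohorts |
| ct_sigma         | 0.25 cycles | routine qPCR technical replicate variation |
| ct_shift         | 1.0 cycle   | a twofold expression change |

LD is emulated *positionally* (co-located co-significant SNPs), not via
genotype correlation: the pipeline consumes summary statistics only, so
nothing downstream could observe a correlation matrix anyway.
Expression effects are mean shifts on Normal(0, 1) probes — no
array-normalization artifacts, batch effects, probe-affinity biases or
heavy tails; Ct tables carry technical replicate noise only. Passing
tests therefore demonstrate correctness of the statistical machinery
and calibration under clean sampling assumptions, not robustness to
platform artifacts in real accessions.

Null configurations reproduce nominal type-I behaviour downstream
(probe rejection ≈ α; the gene-level convergence rate matches a direct
Monte-Carlo enumeration of significance/direction outcomes), and
planted signals at |d| = 1.5 are recovered by convergence with high
sensitivity and ≤ 2 false calls per 500-gene run on average. The test
suite runs these at 100–200 seeded replicates with 100–500 genes —
sizes chosen to give tight binomial error bands while keeping the
default suite quick on one CPU.

## Pipeline

All randomness flows from the single config seed. The final report
ranks genes lexicographically by (called, fdr_pass, has_eQTL, ascending
gene_p) — an invented but declared rule (the underlying analysis style
narrates evidence rather than ranking it), recorded in the report
metadata together with the seed, parameter values and package version.
Stage failures abort with the stage name. When the config carries a
`simulate` block, all inputs are generated, written to
`<output_dir>/inputs/`, and then consumed through the same readers as
file inputs.

## Known limitations

- No p-value combination across GWAS, no genomic-control or
  stratification correction, no colocalization posterior for eQTLs.
- Gene-level summary p (min probe p) is conservative but not a
  calibrated gene-level test; the FDR/Bonferroni gates inherit this.
- The ROC CI is a normal approximation; for AUC near 0 or 1 with small
  n it truncates rather than transforms.
- `z_to_p` returns 0.0 for |z| ≳ 38 (double underflow); work on the
  log scale upstream if such Z-scores matter.
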