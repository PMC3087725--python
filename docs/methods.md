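# Methods

This note documents the models, the numerical choices, and what the
simulated-data validation does and does not establish.

## Data model

A cohort is a triple: a samples × variants dosage matrix (counts of
the designated *counted* allele, `int8`, missing = −1), a variant
table (rsid, chromosome, 1-based position, two alleles, counted
allele) and a sample table (group label, sex, age, BMI, semicolon-
separated diagnosis flags, genotyping batch, replicate flag).  All
internal indexing is 0-based half-open; file formats keep their native
1-based coordinates.  Missing dosages propagate and are never imputed,
with two documented exceptions: PCA mean-imputes per variant (the
standard choice for genotype PCA, where a missing call carries no
ancestry information beyond the variant mean), and the admixture EM
simply omits the corresponding likelihood terms.

When cohorts are merged on shared rsids, allele labels are harmonized
to the first cohort: swapped labels recode dosage d → 2 − d, purely
complementary labels are treated as strand flips, and variants that
are strand-ambiguous (A/T, C/G) or irreconcilable are dropped with
counts in the merge report.  Frequency-matching of ambiguous variants
was deliberately not attempted — it is error-prone near MAF 0.5 and
the number of palindromic SNPs lost is small.  Sample-id collisions
are resolved by prefixing the cohort label, since reference panels
routinely reuse ids.

## QC cascade

Order: declared-vs-genetic sex, sample call rate | SNP call rate, MAF,
batch deviation, diagnosis-linked differential missingness,
Hardy–Weinberg | inbreeding outliers.  Each step is evaluated on the
data surviving the previous steps, and the ledger asserts
`n_after = n_before − n_excluded` per step plus chaining per axis; the
same arithmetic replays a published exclusion chain, which is how the
package audits the source accounting (905,384 → 829,586).

Defaults: sample/SNP missingness ≤ 0.05, MAF ≥ 0.01, HWE p ≥ 0.001,
inbreeding outliers at 4 SD — the thresholds of the clinical-cohort
workflow this package re-implements.  Choices that the workflow left
unspecified are explicit parameters here:

- **HWE** is the exact conditional test (not χ²), computed on all
  surviving samples pooled; per-group testing is possible by
  subsetting.  The p-value sums the conditional probabilities of all
  heterozygote counts no more probable than the observed one.  The
  distribution is computed by the stable ratio recurrence
  `P(h+2)/P(h) = 4·nAA(h)·nBB(h) / ((h+1)(h+2))`, normalized; ties are
  matched with a 1 + 1e−12 relative tolerance.  An independent integer
  enumeration oracle (exact multinomial weights, `Fraction`
  normalization) agrees to ≤ 1e−12 for every table with n ≤ 200.
- **Differential missingness** uses Fisher's exact test on the 2 × 2
  (missing/called × flag) table, two-sided, with a raw p threshold
  (no Bonferroni) because the reference workflow reports a raw flagged
  count; the threshold is a parameter.
- **Batch deviation** is a reconstruction, not a published method: a
  per-SNP χ² on allele counts across batches with Bonferroni control.
- **Relatedness** is plain method-of-moments IBD: observed IBS-state
  counts inverted through their allele-frequency expectations, the
  (z0, z1, z2) estimate projected onto the simplex, PI-hat = z1/2 +
  z2.  No finite-sample bias correction is applied; at the marker
  counts used here (≥ 20,000) duplicates sit at PI-hat ≈ 1,
  parent–child at ≈ 0.5, unrelateds below 0.1.
- **Sex check** thresholds X-inbreeding F at > 0.8 (male) and < 0.2
  (female), undetermined between.

## Synthetic cohorts

The generator is the package's substitute for undeposited patient
genotypes; its defaults are the study conditions under which every
downstream stage is validated.

- **Frequencies**: ancestral p_j ~ U[0.05, 0.95]; population k draws
  Beta(p_j(1−F_k)/F_k, (1−p_j)(1−F_k)/F_k) (the Balding–Nichols
  drift model), clipped to [0.01, 0.99].  The drift parameter is the
  population's FST against the ancestral pool.
- **Admixture**: per-individual q ~ Dirichlet(α), per group.
- **Local ancestry**: each haplotype is a segment process along every
  chromosome — segment lengths Exp(switch_rate) in Mb, labels i.i.d.
  from q (the stationary distribution of the underlying Markov
  chain).  Global mode draws ancestry per locus independently (no
  spatial correlation); with switch_rate → 0 a haplotype belongs to a
  single population.
- **LD pools**: within blocks of `ld_block_size` SNPs, each haplotype
  copies one of H pool members whose carrier sets are *nested*: pool
  rank u carries SNP j iff u < round(H·f_kj).  A single uniform rank
  per haplotype per block then yields within-block D′ = 1 at the
  haplotype level while per-SNP frequencies track the population
  frequencies to rounding, and independent ranks across blocks give
  between-block equilibrium.  This is a stylized block structure —
  real LD decays continuously and D′ within real blocks is below 1 —
  chosen because it gives the block-detection experiments an
  unambiguous ground truth.
- **Nuisances**, in fixed order so ground truth is well defined:
  pools → MCAR missingness → diagnosis-linked missingness → batch
  corruption → duplicates/parent–child → sex-label mismatches →
  phenotype.  Batch corruption is a stylized cluster-calling failure:
  affected calls in one batch collapse to the homozygote of the rarer
  allele, which shifts the batch allele frequency at every affected
  SNP by rate·max(p, 1−p) ≥ rate/2 and is therefore reliably visible
  to the allele-count scan (a frequency-preserving corruption would be
  invisible to it by construction).  Duplicates copy the genotype
  vector as it stands at that stage, so replicate concordance is 1.0
  unless corruption was injected.  Children receive one transmitted
  allele per SNP and one population allele (so IBS ≥ 1 holds at every
  co-called autosomal SNP); on the X-like chromosome a male child is
  hemizygous for the transmitted allele.
- **Phenotype**: log BMI = μ + σ_env·(β_age·z(age) + β_sex·male +
  Σ_j β_j·z(g_j) + ε), ε ~ N(0,1); the β are therefore in residual-SD
  units and σ_env = 0 collapses BMI to exp(μ).  Ages are N(52.8,
  14.2²) clipped to [18, 95], matching the age profile of the clinical
  cohort being emulated.

What passing tests on these cohorts show: the estimators recover the
quantities they target under the stated generative model, at desk
scale.  What they do not show: robustness to genotyping-intensity
artifacts, real LD decay, non-Dirichlet admixture histories, or
population sizes and marker densities of a production biobank.

## Structure inference

PCA standardizes each variant by its sample allele frequency
(2p̂ centering, √(2p̂(1−p̂)) scale), drops monomorphic variants and
eigendecomposes the sample Gram matrix; component signs are fixed so
each loading vector's largest-magnitude entry is positive.  Classical
MDS double-centers the squared IBS-distance matrix.  The window scan
anchors 20 Mb half-open windows at position 0 of each autosome and
skips windows with fewer than 50 SNPs (a 10-PC local basis needs
comfortably more SNPs than PCs); ρ² is the largest singular value
squared of the product of the two centered orthonormal bases, with
rank-deficient inputs reduced to effective rank.

Admixture is maximum-likelihood EM under the binomial admixture
observation model, which assumes linkage equilibrium among markers —
hence it is fitted on pruned sets.  Updates alternate expected
counted/other allele counts per population; frequencies are clipped to
[1e−6, 1 − 1e−6] and Q rows renormalized.  The log-likelihood trace is
non-decreasing by construction and asserted to 1e−9.  Plain EM from a
symmetric random start converges extremely slowly (the symmetric
parameter point is a saddle), so the first restart is *anchored*:
k-means on the leading PC scores seeds soft cluster memberships and
cluster allele frequencies; remaining restarts are random.  Restarts
only affect which optimum is found, never the monotonicity of a run.
`loglik_by_k` additionally warm-starts K from the K−1 solution with a
split component — an initialization that reproduces the K−1 likelihood
exactly, which is what guarantees the reported profile is
non-decreasing in K.  No automatic K selection is performed; the table
is reported and the elbow is the user's judgement.  Label switching is
resolved only at evaluation time, by signed-correlation matching of Q
columns to reference columns (absolute correlation is degenerate at
K = 2, where the simplex columns are exact complements).

## LD blocks

Two-locus haplotype frequencies come from EM over the double-
heterozygote ambiguity (start at linkage equilibrium, relative
tolerance 1e−9, ≤ 1000 iterations).  D′ = |D|/D_max with the
sign-appropriate margin bound; the confidence interval profiles the
multinomial likelihood over a D′ grid (step 0.001) with margins fixed
at their estimates, normalizes the grid to unit mass and takes the
2.5/97.5 mass percentiles.  Pair classification and block acceptance
use the standard confidence-interval parameters (0.70/0.98 strong,
0.90 recombination, 95 % rule, MAF ≥ 0.05 informative).  The 95 % rule
counts only *conclusive* pairs — strong LD or strong recombination;
wide-CI pairs (typically rare × common combinations whose D′ the data
cannot pin down) carry no evidence either way and are excluded from
numerator and denominator, which is what keeps legitimate blocks from
fragmenting.  Candidates are accepted longest-bp-span first, ties
leftmost, overlaps discarded.  Multi-locus haplotype frequencies use
exact EM over all compatible phase configurations, capped at 12 SNPs
(2^12 haplotype states); samples with any missing call in the block
are dropped rather than summed over, a deliberate simplification at
block scale.

## Association

The two-stage procedure (residualize log BMI on age and sex within
group, standardize with the n−1 denominator, then regress on dosage
with optional within-group PC covariates) matches the workflow being
re-implemented; the statistically cleaner joint model is available as
`joint_association` and agrees with the two-stage p-values in ranking
(Spearman > 0.99) though not identically.  Sex is coded female = 0,
male = 1.  Genomic-control λ uses the exact null median
χ²₁(0.5) = 0.4549.  Calibration conditions: a null cohort (n = 500,
m = 5,000) must give uniform p-values; a two-population cohort with an
ancestry-confounded phenotype (one residual SD across the cline) must
inflate λ well above 1.2 unadjusted and return to ≈ 1 with two PCs.

## Problem sizes and determinism

Validation experiments run at fixed desk-scale conditions chosen once:
admixture recovery at n = 300, m = 5,000 pruned SNPs, FST 0.2,
α = (1,1), 10 seeds (observed mean |Q̂ − Q_true| ≈ 0.02 against a 0.05
bound); scan discrimination at n = 150, m = 3,000 over three 100 Mb
autosomes, 20 paired seeds; block recovery at n = 400 with six 10-SNP
pools, 10 seeds (observed Jaccard ≈ 0.95); EM fits capped at 120–200
iterations with a 1e−3 log-likelihood gain tolerance, which is far
past the point where Q stabilizes even though the likelihood itself
keeps creeping.  Every stochastic component takes an explicit integer
seed and identical seeds give bit-identical outputs, including the
end-to-end demo report.

## Known limitations

No genotype-intensity-level QC; no imputation or liftover; the X-like
chromosome exists solely to exercise the sex check (no X-specific HWE
or association); the admixture model ignores admixture LD (linked
ancestry segments), which is exactly the signal the window scan is
designed to expose; block detection above 12 SNPs requires
partitioning; and the simulator's LD pools are stylized, so block-
recovery results quantify detector correctness, not performance on
real haplotype structure.
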