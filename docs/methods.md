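# Methods

## Model and procedure

The package implements summary-statistics gene selection for TWAS with
finite-sample control of the modified false discovery rate
mFDR = E[#{false selections} / (#{selections} + 1/α)].

**Gene scores.** For gene *g*, given harmonized eQTL weights *W_g*, marginal
GWAS effects γ̂_j with standard errors se(γ̂_j), and the SNP LD matrix *R̂_g*,
the predicted-expression variance is σ̂_g² = W_g′R̂_gW_g and the gene Z-score
is Z_g = Σ_j (w_j ρ̂_j / σ̂_g)(γ̂_j / se(γ̂_j)), with ρ̂_j² the j-th LD
diagonal (1 when LD is a correlation matrix). This is the β̂_g/se(β̂_g) ratio
of the S-PrediXcan test up to an O(Z³/n) approximation in the standard-error
denominators; the test suite verifies correlation > 0.99 against the
individual-level regression t-statistic and agreement within 0.05 at moderate
signal.

**Knockoff copies.** With Σ the D×D gene correlation matrix, M knockoff
copies of Z are drawn as Z̃_m = ΘZ + Λ_m, Θ = I − ΦΣ⁻¹, Φ = diag(s), where
the stacked noise (Λ_1,…,Λ_M) is jointly Gaussian with diagonal blocks
V = 2Φ − ΦΣ⁻¹Φ and cross blocks C = Φ − ΦΣ⁻¹Φ. The resulting joint
covariance of (Z, Z̃_1,…,Z̃_M) has diagonal blocks Σ and every off-diagonal
block Σ − Φ, which is exactly the exchangeability pattern knockoff inference
needs. Drawing each Λ_m independently from N(0, V) would preserve each pair
(Z, Z̃_m) marginally but break exchangeability among copies for M > 1, so the
joint construction is used. Note C itself need not be PSD when M > 1; the
condition that matters is that the stacked noise covariance
I_M⊗Φ + J_M⊗C is PSD, which holds iff Φ + M·C ⪰ 0, i.e. exactly when
((M+1)/M)Σ − Φ ⪰ 0 — the sampler uses the orthogonal-rotation factorization
(a rotation mixing one (Φ + MC)^{1/2}-shaped component into M Φ^{1/2}-shaped
ones), so the block covariance is exact, not approximate.

**The s-vector.** Two solvers for Φ = diag(s):

- `equi`: the closed-form equicorrelated solution
  s_g = min(1, ((M+1)/M)·λ_min(Σ)).
- `sdp` (default): the semidefinite program minimize Σ_g|1 − s_g| subject to
  ((M+1)/M)Σ − Φ ⪰ 0, s ≥ 0. Any optimum has s ≤ 1, so the program is
  max Σ_g s_g over a downward-closed spectrahedron; it is solved by an
  interior-point scheme — coordinate ascent on the concave barrier objective
  Σ_g s_g + μ·log det(((M+1)/M)Σ − diag(s)), whose per-coordinate maximizer
  is closed-form (s_g = 1/(B⁻¹)_gg − μ via rank-one updates), over the
  barrier schedule μ = 0.3 → 1e-4. The barrier optimum is unique, so
  block-diagonal Σ decomposes into blockwise solutions (tested), and the
  result is kept only when it is feasible (eigenvalue check, with a bisection
  scale-back repair) and no worse than the equicorrelated objective;
  otherwise the solver falls back to `equi`. Above D = 2000 the fallback is
  used directly for bounded runtime.

**Filter.** Importance scores T_g = Z_g², T̃_g^m = (Z̃_g^m)². Per gene the
M+1 scores are pooled: κ_g indexes the maximal score (0 = original), and
τ_g = (max score) − (median of the remaining M scores). τ is a symmetric
function of the copies, so for a null gene κ_g is uniform on the M+1 copies
independently of τ_g — the property the FDP estimate relies on. The GReX
feature statistic is δ_g = τ_g when the original strictly attains the
maximum and 0 otherwise, i.e. δ_g = (T_g − median_m T̃_g^m)·1{T_g > max_m T̃_g^m}.
The data-dependent threshold is the smallest positive observed τ with
(1/M + #{κ_g ≥ 1, τ_g ≥ t}/M) / max(1, #{κ_g = 0, τ_g ≥ t}) ≤ α, and the
selection is {g : δ_g ≥ t̂} = {g : κ_g = 0, τ_g ≥ t̂}. With M = 1 this
reduces exactly to the classic knockoff+ filter on W = T − T̃ (tested against
an independent implementation).

Deliberate edge-case choices: the estimator denominator is guarded by
max(1, ·); ties T = max T̃ count as a knockoff win **and** zero δ (strict
inequality in the indicator) — the conservative direction; selection uses
δ ≥ t̂ rather than strict >, so the counted set in the FDP estimate and the
selected set coincide (the two differ only on ties, a measure-zero event for
continuous statistics); candidate thresholds are restricted to observed
positive τ values, where the minimum over t > 0 is attained.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | target mFDR of the selection |
| M | 5 | simultaneous knockoff copies; M > 1 stabilizes selection against knockoff sampling noise |
| s_method | "sdp" | knockoff decorrelation program (equi fallback) |
| eig_floor | 1e-3 | lower bound imposed on λ_min(Σ) by linear shrinkage toward I before inversion |
| sigma2_floor | 1e-8 | predicted-expression variance below which a gene is excluded as degenerate |

Linear shrinkage (Σ ← (1−λ)Σ + λI with the smallest adequate λ) is used
rather than eigenvalue clipping because it preserves the ordering of
correlations; the applied λ is recorded on the result.

## The baseline

S-PrediXcan + BH: β̂_g = Σ_j w_j γ̂_j ρ̂_j²/σ̂_g²,
se²(β̂_g) = (σ̂_Y² − β̂_g²σ̂_g²)/(n σ̂_g²), two-sided normal p-values
(large-n summary-statistics regime; σ̂_Y² defaults to 1 for a standardized
trait), Benjamini–Hochberg step-up at α_adj. Genes whose implied residual
variance σ̂_Y² − β̂_g²σ̂_g² is non-positive are flagged and excluded from the
ranking rather than selected.

## Harmonization

Weights, summary statistics and LD are intersected per gene and aligned to
the weight set's effect allele: swapped alleles (directly or as strand
complements) flip the sign of γ̂; strand-ambiguous SNPs (A/T, C/G) are
dropped by default (policy `keep` retains them); irreconcilable allele pairs
are dropped and logged; genes with an empty harmonized intersection are
marked unusable, not fatal. Column names of sumstat/weight files are
configurable with PLINK-ish defaults (snp, a1, a2, beta, se, n). LD may be a
correlation or a genotype-covariance matrix; a dialect flag records which,
since the Z-score formula uses the LD diagonal explicitly.

## The synthetic-study generator

The simulator emulates a complete TWAS study at desk scale; its defaults are
the study conditions used throughout the tests:

1. **Genotypes** (n = 5000, D = 200 genes × J = 10 SNPs): per individual two
   latent AR(1) Gaussian haplotypes (within-gene decay ρ_LD = 0.5) are
   thresholded at a per-SNP MAF ~ U(0.05, 0.5) and summed to 0/1/2 counts;
   20% of each gene's SNPs are shared with the next gene, inducing gene–gene
   correlation analogous to overlapping cis-windows. Columns are
   standardized; R̂_g is the sample SNP correlation.
2. **Weights/expression**: 3 nonzero N(0,1) weights per gene;
   X̂_g = G_g w_g rescaled to unit variance (expression equals its genetic
   prediction; no residual expression noise is added).
3. **Phenotype**: k = ⌈η·D⌉ causal genes with β_g ~ N(0, h²/k), others 0;
   Y = X̂β + ε, ε ~ N(0, 1 − h²), so Var(Y) ≈ 1 and the genes explain
   heritability h². Y is used as generated (not re-standardized).
4. **GWAS**: marginal regression of Y on each standardized SNP; slopes
   G_j′Y/n and moment standard errors √((σ̂_Y² − γ̂_j²)/n).

Σ for the pipeline is estimated from the predicted-expression matrix (the
generator's analogue of estimating it from reference expression data).
Per-replicate seeds derive from (master seed, scenario index, replicate
index) via `numpy.random.SeedSequence`, so results are independent of
execution order.

**What the generator does not emulate:** real LD block structure and allele
frequencies, expression noise and imperfectly estimated weights, population
stratification, case-control traits, and LD-reference mismatch. Passing
tests therefore demonstrate the statistical validity of the procedure under
its stated model (Gaussian Z with known correlation), not robustness to
reference-panel error — the main practical caveat for real data.

**Scale.** The replicated experiments run at D = 200, J = 10, n = 5000 with
50 replicates per scenario across h² ∈ {0.05, 0.1, 0.2} ×
η ∈ {0.02, 0.05, 0.1}, the package's desk-scale stand-in for biobank-scale
studies (which use 10⁵-scale n and ~900 genes on real genotypes). At this
scale the knockoff filter's scenario-mean mFDR stays below the nominal level
in every scenario while the BH baseline is only mildly miscalibrated; the
baseline's characteristic FDR inflation appears in the designated
correlated-gene scenario (overlap = 0.5, ρ_LD = 0.8), where BH exceeds the
nominal level several-fold and the knockoff filter remains controlled.
`scripts/acceptance.py` recomputes these quantities from scratch.

## Known limitations

- Gene Z-scores are treated as Gaussian with correlation Σ; heavy-tailed or
  misspecified Σ degrades the guarantee (mitigated, not removed, by the
  eig_floor shrinkage).
- The weights-LD estimator of Σ needs cross-gene LD blocks; pairs without
  them get correlation 0 with a warning.
- The SDP solver targets the ℓ1 objective only; entropy/MVR-style
  objectives, group knockoffs and derandomization across repeated draws are
  out of scope.
- No liftover, vendor database readers, or population-stratification
  handling; inputs are delimited text (plus an optional HDF5 LD container).
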