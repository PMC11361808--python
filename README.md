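# twas-knockoff

Gene selection for transcriptome-wide association studies (TWAS) from GWAS
summary statistics, with **finite-sample false discovery rate control** via
Ghostknockoff inference on gene-level Z-scores.

## The problem

A TWAS asks which genes' genetically regulated expression (GReX) is associated
with a trait. The conventional summary-statistics pipeline (S-PrediXcan-style)
computes, for each gene *g* with eQTL weight vector *W_g*, per-SNP GWAS
effects γ̂ and LD matrix *R̂_g*, an effect estimate and test statistic

```
β̂_g = Σ_j w_j γ̂_j ρ̂_j² / σ̂_g² ,     σ̂_g² = W_g' R̂_g W_g ,
Z_g  = β̂_g / se(β̂_g) ≈ Σ_j (w_j ρ̂_j / σ̂_g) · (γ̂_j / se(γ̂_j)),
```

then selects genes by Benjamini–Hochberg on normal p-values. Because genes are
correlated (shared and linked eQTLs), this provides no finite-sample FDR
guarantee and in practice badly overselects.

This package instead builds **M exchangeable Gaussian knockoff copies** of the
gene Z-score vector directly from summary statistics,

```
Z̃_m = Θ Z + Λ_m ,   Θ = I − Φ Σ⁻¹,   Φ = diag(s),
```

with Σ the gene–gene correlation matrix, the s-vector obtained from the
semidefinite program `min Σ_g |1 − s_g|` s.t. `((M+1)/M) Σ − Φ ⪰ 0, s ≥ 0`,
and jointly Gaussian noise giving the exchangeable covariance pattern
`Cov(Z, Z̃_m) = Cov(Z̃_m, Z̃_m′) = Σ − Φ`. Per gene it computes importance
scores `T_g = Z_g²`, `T̃_g^m = (Z̃_g^m)²`, the knockoff statistics (κ_g, τ_g),
the GReX feature statistic `δ_g = (T_g − median_m T̃_g^m)·1{T_g ≥ max_m T̃_g^m}`,
and a data-dependent threshold

```
t̂ = min{ t > 0 : (1/M + #{κ_g ≥ 1, τ_g ≥ t}/M) / max(1, #{κ_g = 0, τ_g ≥ t}) ≤ α }
```

selecting `Ŝ = {g : δ_g ≥ t̂}`. This controls the modified FDR
`mFDR = E[#false / (#selected + 1/α)]` at level α in finite samples.

## Worked example

```python
import numpy as np
from twas_knockoff import SimConfig, run_replicate

cfg = SimConfig(n=5000, D=200, h2=0.1, eta=0.05, alpha=0.05, M=5)
rep = run_replicate(cfg, seed=12345)
print(f"knockoff selected {len(rep.knockoff_selected)} genes, "
      f"mFDR contribution {rep.knockoff_mfdr:.3f}, TPP {rep.knockoff_tpp:.2f}")
print(f"baseline selected {len(rep.baseline_selected)} genes, "
      f"mFDR contribution {rep.baseline_mfdr:.3f}, TPP {rep.baseline_tpp:.2f}")
```

prints

```
knockoff selected 6 genes, mFDR contribution 0.000, TPP 0.60
baseline selected 6 genes, mFDR contribution 0.000, TPP 0.60
```

— the simulated study has 10 causal genes out of 200; on this replicate both
methods selected 6 of them with no false positives. The difference between
the methods shows up across replicates and in correlated-gene regimes, where
the BH baseline's mFDR inflates above the nominal level while the knockoff
filter's does not (see `docs/methods.md`).

The estimator interface composes with scikit-learn conventions:

```python
from twas_knockoff import GhostKnockoffFilter
filt = GhostKnockoffFilter(alpha=0.05, M=5, random_state=0).fit(Z, Sigma)
filt.selected_genes_   # gene ids with delta >= threshold
filt.get_support()     # boolean mask
```

For file-based runs there is a CLI:

```bash
twas-knockoff run --sumstats gwas.tsv --weights weights.tsv \
    --ld ld_dir/ --expr expression.tsv --fdr 0.05 --m 5 --seed 1 --out results/
twas-knockoff simulate --config scenarios.yaml --out results/
```

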