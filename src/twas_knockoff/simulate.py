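"""Synthetic TWAS studies: genotypes, eQTL weights, phenotypes and marginal
GWAS statistics, plus replicated mFDR/TPP experiments for the knockoff filter
and the S-PrediXcan baseline.

The generator follows a four-step design. (1) Block-correlated standardized
genotypes: per individual two latent AR(1) Gaussian haplotypes thresholded at
the per-SNP minor allele frequency give 0/1/2 counts; a fixed fraction of each
gene's SNPs is shared with the next gene, which induces gene-gene correlation.
(2) Sparse per-gene weights (a few N(0,1) entries) define the predicted
expression X^_g = G_g w_g, rescaled to unit variance. (3) k = ceil(eta * D)
causal genes get effects beta_g ~ N(0, h2/k); the phenotype is
Y = sum_g X^_g beta_g + eps with eps ~ N(0, 1 - h2), so Var(Y) is about 1 and
the simulated genes explain heritability h2. (4) Marginal per-SNP regressions
of Y on each standardized SNP give the GWAS effect sizes and standard errors.

Replicates feed the full pipeline (harmonize - gene Z-scores - gene
correlation - knockoffs - filter, and the baseline) and report modified FDR
and true positive proportion per scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import SPrediXcanBH
from .correlation import correlation_from_expression, regularize
from .filter import GhostKnockoffFilter, evaluate_selection
from .io import HarmonizedGeneData, LdBlock, write_ld
from .zscore import compute_zscores


@dataclass
class SimConfig:
    """Study conditions for one simulated scenario.

    Defaults are the desk-scale stand-in for the biobank-scale regime: D=200
    genes of J=10 SNPs each, n=5000 individuals, AR(1) within-gene LD 0.5,
    20% of SNPs shared between adjacent genes, heritability h2 split over
    k = ceil(eta*D) causal genes.
    """

    n: int = 5000
    D: int = 200
    snps_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho_ld: float = 0.5
    overlap: float = 0.2
    n_causal_weights: int = 3
    eta: float = 0.02
    h2: float = 0.1
    alpha: float = 0.05
    alpha_adj: float = 0.05
    M: int = 5
    replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if math.ceil(self.eta * self.D) < 1:
            raise ValueError("eta * D must give at least one causal gene")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid MAF range")

    @property
    def n_causal_genes(self) -> int:
        return math.ceil(self.eta * self.D)


@dataclass
class SimulatedStudy:
    config: SimConfig
    genotypes: np.ndarray  # n x P, standardized
    snp_ids: list[str]
    gene_ids: list[str]
    gene_windows: list[np.ndarray]  # per gene, SNP column indices
    ld_blocks: list[np.ndarray]  # per gene sample correlation R^_g
    weights: list[np.ndarray]  # per gene, aligned to its window
    xhat: np.ndarray  # n x D predicted expression, unit variance
    beta: np.ndarray = field(default=None)  # type: ignore[assignment]
    causal: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma_hat: np.ndarray = field(default=None)  # type: ignore[assignment]
    se_gamma: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def causal_gene_ids(self) -> set[str]:
        return {self.gene_ids[i] for i in self.causal}

    def harmonized_genes(self) -> list[HarmonizedGeneData]:
        """Package the study as the per-gene aligned inputs the pipeline
        consumes (alleles are trivially consistent by construction)."""
        out = []
        n = self.config.n
        for g, gid in enumerate(self.gene_ids):
            idx = self.gene_windows[g]
            out.append(
                HarmonizedGeneData(
                    gene_id=gid,
                    snp_ids=[self.snp_ids[j] for j in idx],
                    weights=self.weights[g],
                    gamma_hat=self.gamma_hat[idx],
                    se_gamma=self.se_gamma[idx],
                    n=np.full(idx.size, n, dtype=float),
                    ld=self.ld_blocks[g],
                    ld_dialect="correlation",
                )
            )
        return out


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], list[np.ndarray], list[np.ndarray]]:
    """Standardized genotype matrix with AR(1) within-gene LD and SNP sharing
    between adjacent genes; returns (G, snp_ids, gene_windows, ld_blocks)."""
    D, J = config.D, config.snps_per_gene
    shared = int(round(config.overlap * J))
    stride = J - shared
    if stride < 1:
        raise ValueError("overlap too large: genes would coincide")
    P = J + (D - 1) * stride
    maf = rng.uniform(*config.maf_range, size=P)
    cut = stats.norm.ppf(maf)
    rho = config.rho_ld
    scale = math.sqrt(1.0 - rho**2)
    G = np.zeros((config.n, P))
    for _hap in range(2):
        latent = rng.standard_normal((config.n, P))
        for j in range(1, P):
            latent[:, j] = rho * latent[:, j - 1] + scale * latent[:, j]
        G += latent < cut
    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    if np.any(sd == 0):
        # monomorphic columns are essentially impossible at the default MAF
        # range; jitter rather than abort a replicate
        sd[sd == 0] = 1.0
    G = (G - mean) / sd
    snp_ids = [f"snp{j}" for j in range(P)]
    windows = [np.arange(g * stride, g * stride + J) for g in range(D)]
    ld_blocks = [np.corrcoef(G[:, w], rowvar=False) for w in windows]
    return G, snp_ids, windows, ld_blocks


def simulate_weights_and_expression(
    genotypes: np.ndarray,
    gene_windows: Sequence[np.ndarray],
    config: SimConfig,
    rng: np.random.Generator,
    standardize: bool = True,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Sparse true eQTL weights per gene and the predicted expression
    X^ = G_g w_g; when ``standardize``, weights are rescaled so every X^_g
    has unit sample variance (Z-scores are scale-free, but the phenotype
    model assumes standardized expression)."""
    weights = []
    cols = []
    J = config.snps_per_gene
    for w_idx in gene_windows:
        w = np.zeros(J)
        nnz = min(config.n_causal_weights, J)
        pos = rng.choice(J, size=nnz, replace=False)
        w[pos] = rng.standard_normal(nnz)
        x = genotypes[:, w_idx] @ w
        sd = x.std()
        if standardize and sd > 1e-12:
            w = w / sd
            x = x / sd
        weights.append(w)
        cols.append(x)
    return weights, np.column_stack(cols)


def simulate_phenotype(
    xhat: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotype Y = X^ beta + eps with k = ceil(eta D) causal genes,
    beta_causal ~ N(0, h2/k) and eps ~ N(0, 1-h2)."""
    n, D = xhat.shape
    k = config.n_causal_genes
    causal = np.sort(rng.choice(D, size=k, replace=False))
    beta = np.zeros(D)
    beta[causal] = rng.normal(0.0, math.sqrt(config.h2 / k), size=k)
    eps = rng.normal(0.0, math.sqrt(1.0 - config.h2), size=n)
    y = xhat @ beta + eps
    return y, beta, causal


def marginal_gwas(
    genotypes: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal regression of Y on each standardized SNP: slope
    gamma_j = cov(G_j, Y) and moment-based se
    sqrt((sigma_Y^2 - gamma_j^2)/n)."""
    n = y.size
    yc = y - y.mean()
    gamma = genotypes.T @ yc / n
    sigma2_y = float(yc @ yc / n)
    resid = np.clip(sigma2_y - gamma**2, 1e-12, None)
    se = np.sqrt(resid / n)
    return gamma, se


def simulate_study(config: SimConfig, rng: np.random.Generator) -> SimulatedStudy:
    """Run the four generation steps and return the complete study."""
    G, snp_ids, windows, ld_blocks = simulate_genotypes(config, rng)
    weights, xhat = simulate_weights_and_expression(G, windows, config, rng)
    y, beta, causal = simulate_phenotype(xhat, config, rng)
    gamma, se = marginal_gwas(G, y)
    return SimulatedStudy(
        config=config,
        genotypes=G,
        snp_ids=snp_ids,
        gene_ids=[f"gene{g}" for g in range(config.D)],
        gene_windows=windows,
        ld_blocks=ld_blocks,
        weights=weights,
        xhat=xhat,
        beta=beta,
        causal=causal,
        y=y,
        gamma_hat=gamma,
        se_gamma=se,
    )


@dataclass
class ReplicateResult:
    """One replicate's selections, metrics, and the raw knockoff statistics
    (kept so selections can be re-thresholded at another alpha)."""

    causal: set[str]
    gene_ids: list[str]
    kappa: np.ndarray
    tau: np.ndarray
    knockoff_selected: set[str]
    baseline_selected: set[str]
    knockoff_mfdr: float
    knockoff_tpp: float | None
    baseline_mfdr: float
    baseline_tpp: float | None


def run_replicate(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
) -> ReplicateResult:
    """Generate one study and run both selection methods end to end."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    data_ss, knock_ss = ss.spawn(2)
    study = simulate_study(config, np.random.default_rng(data_ss))
    genes = study.harmonized_genes()
    zset = compute_zscores(genes, sigma2_y=1.0)
    sigma = correlation_from_expression(
        pd.DataFrame(study.xhat, columns=study.gene_ids),
        gene_ids=zset.gene_ids,
    )
    filt = GhostKnockoffFilter(
        alpha=config.alpha,
        M=config.M,
        random_state=np.random.default_rng(knock_ss),
    ).fit(zset.z, regularize(sigma))
    base = SPrediXcanBH(alpha=config.alpha_adj).fit(genes, n=config.n)
    truth = study.causal_gene_ids
    k_sel = set(filt.selected_genes_)
    b_sel = set(base.selected_genes_)
    k_mfdr, k_tpp = evaluate_selection(k_sel, truth, config.alpha)
    b_mfdr, b_tpp = evaluate_selection(b_sel, truth, config.alpha)
    return ReplicateResult(
        causal=truth,
        gene_ids=filt.gene_ids_,
        kappa=filt.kappa_,
        tau=filt.tau_,
        knockoff_selected=k_sel,
        baseline_selected=b_sel,
        knockoff_mfdr=k_mfdr,
        knockoff_tpp=k_tpp,
        baseline_mfdr=b_mfdr,
        baseline_tpp=b_tpp,
    )


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")


def replicate_seeds(config: SimConfig, scenario_index: int = 0) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seed sequences, independent of execution
    order, derived from (master seed, scenario, replicate)."""
    return [
        np.random.SeedSequence(entropy=(config.seed, scenario_index, r))
        for r in range(config.replicates)
    ]


def run_scenario(
    config: SimConfig, scenario_index: int = 0
) -> list[ReplicateResult]:
    return [
        run_replicate(config, ss)
        for ss in replicate_seeds(config, scenario_index)
    ]


def summarize_scenario(
    results: Sequence[ReplicateResult], config: SimConfig
) -> pd.DataFrame:
    """Per-method mean mFDR/TPP with Monte-Carlo standard errors."""
    rows = []
    for method in ("knockoff", "baseline"):
        mfdr = np.array([getattr(r, f"{method}_mfdr") for r in results])
        tpp_vals = [getattr(r, f"{method}_tpp") for r in results]
        tpp = np.array([t for t in tpp_vals if t is not None])
        rows.append(
            {
                "n": config.n,
                "h2": config.h2,
                "eta": config.eta,
                "method": method,
                "mfdr": float(mfdr.mean()),
                "mfdr_se": _sem(mfdr),
                "tpp": float(tpp.mean()) if tpp.size else float("nan"),
                "tpp_se": _sem(tpp),
                "replicates": len(results),
            }
        )
    return pd.DataFrame(rows)


def run_study(
    base: SimConfig,
    h2_values: Iterable[float] | None = None,
    eta_values: Iterable[float] | None = None,
    n_values: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Replicated experiments over a scenario grid; one row per
    (n, h2, eta, method) with mean and SE of mFDR and TPP."""
    h2s = list(h2_values) if h2_values is not None else [base.h2]
    etas = list(eta_values) if eta_values is not None else [base.eta]
    ns = list(n_values) if n_values is not None else [base.n]
    tables = []
    idx = 0
    for n in ns:
        for h2 in h2s:
            for eta in etas:
                cfg = replace(base, n=n, h2=h2, eta=eta)
                results = run_scenario(cfg, scenario_index=idx)
                tables.append(summarize_scenario(results, cfg))
                idx += 1
    return pd.concat(tables, ignore_index=True)


def export_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write one replicate in the standard input formats (sumstats, weights,
    per-gene LD, expression), so the file readers can ingest it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = study.config.n
    pd.DataFrame(
        {
            "snp": study.snp_ids,
            "a1": "A",
            "a2": "G",
            "beta": study.gamma_hat,
            "se": study.se_gamma,
            "n": n,
        }
    ).to_csv(out / "sumstats.tsv", sep="\t", index=False)
    rows = []
    for g, gid in enumerate(study.gene_ids):
        for j, w in zip(study.gene_windows[g], study.weights[g]):
            rows.append((gid, study.snp_ids[j], "A", "G", w))
    pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "a1", "a2", "weight"]
    ).to_csv(out / "weights.tsv", sep="\t", index=False)
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    for g, gid in enumerate(study.gene_ids):
        block = LdBlock(
            gene_id=gid,
            snp_ids=[study.snp_ids[j] for j in study.gene_windows[g]],
            matrix=study.ld_blocks[g],
        )
        write_ld(ld_dir / f"{gid}.tsv", block)
    pd.DataFrame(study.xhat, columns=study.gene_ids).to_csv(
        out / "expression.tsv", sep="\t", index=False
    )
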