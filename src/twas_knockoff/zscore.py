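"""Gene-level Z-scores from expression weights, per-SNP summary statistics and
LD.

For gene g with weight vector W_g and SNP LD matrix R_g, the variance of the
genetically predicted expression is sigma_g^2 = W_g' R_g W_g, and the gene
Z-score is the weighted combination of per-SNP Z-scores

    Z_g = sum_j  w_j * rho_j / sigma_g * (gamma_j / se(gamma_j)),

with rho_j^2 the j-th diagonal of R_g (1 in the correlation dialect). Genes
whose predicted expression has (numerically) zero variance carry no signal and
are excluded rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import HarmonizedGeneData

#: genes with W'RW below this (standardized-genotype scale) are degenerate
SIGMA2_FLOOR = 1e-8


class DegenerateGeneError(ValueError):
    """Predicted-expression variance at or below the floor."""


class DegenerateSnpError(ValueError):
    """Moment-based se undefined (non-positive residual variance)."""


@dataclass
class GeneZscore:
    gene_id: str
    z: float
    sigma2: float
    n_snps: int


@dataclass
class GeneZscoreSet:
    """Ordered gene Z-scores; the gene order here is the canonical order the
    gene correlation matrix and knockoff model must follow."""

    scores: list[GeneZscore]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.scores]

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.scores])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "z": self.z,
                "sigma2": [s.sigma2 for s in self.scores],
                "n_snps": [s.n_snps for s in self.scores],
            }
        )


def gene_variance(weights: Sequence[float], ld: np.ndarray) -> float:
    """Variance W'RW of the predicted expression of one gene."""
    w = np.asarray(weights, dtype=float)
    R = np.asarray(ld, dtype=float)
    if R.shape != (w.size, w.size):
        raise ValueError(f"weights ({w.size}) and LD {R.shape} not conformable")
    return float(w @ R @ w)


def snp_se_from_moments(
    gamma_hat: float, rho2: float, sigma2_y: float, n: float
) -> float:
    """Standard error of a marginal per-SNP effect from summary moments:
    se^2 = (sigma_Y^2 - gamma^2 rho^2) / (n rho^2).

    Fallback for sumstat files lacking an se column, and the generator used by
    the simulator.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if rho2 <= 0:
        raise DegenerateSnpError("non-positive SNP variance")
    num = sigma2_y - gamma_hat**2 * rho2
    if num <= 0:
        raise DegenerateSnpError(
            "residual variance sigma_Y^2 - gamma^2 rho^2 is not positive"
        )
    return float(np.sqrt(num / (n * rho2)))


def gene_zscore(
    data: HarmonizedGeneData, sigma2_y: float | None = None
) -> GeneZscore:
    """Gene Z-score for one harmonized gene.

    Uses the file-provided se(gamma) where available; ``sigma2_y`` is only
    needed when some se entries are missing (NaN) and must be reconstructed
    from moments.
    """
    rho2 = np.diag(data.ld)
    sigma2 = gene_variance(data.weights, data.ld)
    if sigma2 <= SIGMA2_FLOOR:
        raise DegenerateGeneError(
            f"gene {data.gene_id}: predicted-expression variance {sigma2:.3e} "
            f"at or below floor {SIGMA2_FLOOR:.0e}"
        )
    se = np.array(data.se_gamma, dtype=float)
    missing = ~np.isfinite(se)
    if missing.any():
        if sigma2_y is None:
            raise ValueError(
                f"gene {data.gene_id}: se(gamma) missing and sigma2_y not given"
            )
        for j in np.flatnonzero(missing):
            se[j] = snp_se_from_moments(
                data.gamma_hat[j], rho2[j], sigma2_y, data.n[j]
            )
    snp_z = data.gamma_hat / se
    z = float(np.sum(data.weights * np.sqrt(rho2) * snp_z) / np.sqrt(sigma2))
    return GeneZscore(
        gene_id=data.gene_id, z=z, sigma2=sigma2, n_snps=data.n_snps
    )


def compute_zscores(
    genes: Iterable[HarmonizedGeneData | None], sigma2_y: float | None = None
) -> GeneZscoreSet:
    """Score every usable gene; degenerate or unusable genes are excluded with
    a reason instead of aborting the run."""
    scores: list[GeneZscore] = []
    excluded: dict[str, str] = {}
    for i, g in enumerate(genes):
        if g is None:
            excluded[f"<gene #{i}>"] = "empty SNP intersection"
            continue
        try:
            scores.append(gene_zscore(g, sigma2_y=sigma2_y))
        except (DegenerateGeneError, DegenerateSnpError, ValueError) as err:
            excluded[g.gene_id] = str(err)
    return GeneZscoreSet(scores=scores, excluded=excluded)
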