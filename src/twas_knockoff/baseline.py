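"""S-PrediXcan gene association test with Benjamini-Hochberg selection.

For gene g the estimated effect of predicted expression on the trait and its
standard error are

    beta_g = sum_j w_j gamma_j rho_j^2 / sigma_g^2,
    se^2(beta_g) = (sigma_Y^2 - beta_g^2 sigma_g^2) / (n sigma_g^2),

with sigma_g^2 = W' R W and rho_j^2 the j-th LD diagonal. Z = beta/se is
referred to a standard normal (two-sided), and genes are selected by BH
step-up at a chosen adjusted level. This is the conventional TWAS procedure
used as the comparison method: it has no finite-sample FDR guarantee.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import HarmonizedGeneData
from .zscore import SIGMA2_FLOOR, DegenerateGeneError, gene_variance


def spredixcan_gene(
    data: HarmonizedGeneData,
    sigma2_y: float = 1.0,
    n: float | None = None,
) -> tuple[float, float, float, float]:
    """Per-gene (beta_hat, se, z, p).

    ``n`` defaults to the median per-SNP GWAS sample size of the gene. When
    the implied residual variance sigma_Y^2 - beta^2 sigma_g^2 is not
    positive (variance-order violation), se/z/p are returned as NaN and the
    gene should be treated as flagged rather than selected.
    """
    sigma2 = gene_variance(data.weights, data.ld)
    if sigma2 <= SIGMA2_FLOOR:
        raise DegenerateGeneError(
            f"gene {data.gene_id}: predicted-expression variance {sigma2:.3e}"
        )
    if n is None:
        n = float(np.median(data.n))
    rho2 = np.diag(data.ld)
    beta = float(np.sum(data.weights * data.gamma_hat * rho2) / sigma2)
    resid = sigma2_y - beta**2 * sigma2
    if resid <= 0:
        return beta, float("nan"), float("nan"), float("nan")
    se = float(np.sqrt(resid / (n * sigma2)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, z, p


def bh_select(
    pvals: Sequence[float], alpha_adj: float
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (selected flags, adjusted p-values).

    Missing p-values (NaN) are excluded from the ranking and never selected.
    """
    p = np.asarray(pvals, dtype=float)
    selected = np.zeros(p.size, dtype=bool)
    adjusted = np.full(p.size, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        rej, p_adj, _, _ = multipletests(p[ok], alpha=alpha_adj, method="fdr_bh")
        selected[ok] = rej
        adjusted[ok] = p_adj
    return selected, adjusted


class SPrediXcanBH(BaseEstimator):
    """Baseline TWAS selector: per-gene S-PrediXcan test + BH correction.

    Parameters
    ----------
    alpha : float, default 0.05
        Adjusted-p significance level for BH selection.
    sigma2_y : float, default 1.0
        Phenotype variance (1 for a standardized trait).
    """

    def __init__(self, alpha: float = 0.05, sigma2_y: float = 1.0) -> None:
        self.alpha = alpha
        self.sigma2_y = sigma2_y

    def fit(
        self,
        genes: Sequence[HarmonizedGeneData | None],
        n: float | None = None,
    ) -> "SPrediXcanBH":
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        rows = []
        self.excluded_: dict[str, str] = {}
        for i, g in enumerate(genes):
            if g is None:
                self.excluded_[f"<gene #{i}>"] = "empty SNP intersection"
                continue
            try:
                beta, se, z, p = spredixcan_gene(g, self.sigma2_y, n=n)
            except DegenerateGeneError as err:
                self.excluded_[g.gene_id] = str(err)
                continue
            rows.append((g.gene_id, beta, se, z, p))
        res = pd.DataFrame(
            rows, columns=["gene_id", "beta_hat", "se_beta", "z", "p"]
        )
        sel, p_adj = bh_select(res["p"], self.alpha)
        res["p_adj"] = p_adj
        res["selected"] = sel
        self.results_ = res
        self.pvalues_ = res["p"].to_numpy()
        self.support_ = sel
        self.gene_ids_ = res["gene_id"].tolist()
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    @property
    def selected_genes_(self) -> list[str]:
        return [g for g, keep in zip(self.gene_ids_, self.support_) if keep]
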