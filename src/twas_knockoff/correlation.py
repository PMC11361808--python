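"""The D x D gene-gene correlation matrix Sigma used to generate knockoffs.

Sigma is the correlation of genetically predicted expression across genes. It
can be estimated directly from an expression matrix, or from the weight sets
and cross-gene LD as Sigma_gh = W_g' R_gh W_h / (sigma_g sigma_h). A linear
shrinkage toward the identity guards the smallest eigenvalue, since the
knockoff construction needs Sigma^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

#: default lower bound on the smallest eigenvalue of Sigma
EIG_FLOOR = 1e-3


@dataclass
class GeneCorrelation:
    gene_ids: list[str]
    matrix: np.ndarray
    provenance: str = "expression"  # "expression" | "weights-ld" | "hybrid"
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = len(self.gene_ids)
        if self.matrix.shape != (d, d):
            raise ValueError("gene ids and matrix shape disagree")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def reorder(self, gene_ids: Sequence[str]) -> "GeneCorrelation":
        """Restrict/permute to the given gene order (id-checked)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from correlation matrix: {missing}")
        idx = [pos[g] for g in gene_ids]
        return GeneCorrelation(
            gene_ids=list(gene_ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            provenance=self.provenance,
            shrinkage=self.shrinkage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.gene_ids)


def correlation_from_expression(
    expression: pd.DataFrame | np.ndarray,
    gene_ids: Sequence[str] | None = None,
) -> GeneCorrelation:
    """Sample Pearson correlation of expression columns, in canonical order.

    Constant-expression genes have undefined correlation and raise; exclude
    them upstream (they are degenerate for scoring anyway).
    """
    if isinstance(expression, pd.DataFrame):
        cols = [str(c) for c in expression.columns]
        X = expression.to_numpy(dtype=float)
    else:
        X = np.asarray(expression, dtype=float)
        cols = [str(i) for i in range(X.shape[1])]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression for genes {bad}")
    corr = np.corrcoef(X, rowvar=False)
    gc = GeneCorrelation(gene_ids=cols, matrix=corr, provenance="expression")
    if gene_ids is not None:
        gc = gc.reorder(gene_ids)
    return gc


def correlation_from_weights_ld(
    gene_ids: Sequence[str],
    weights: Mapping[str, np.ndarray],
    ld_blocks: Mapping[str, np.ndarray],
    cross_ld: Mapping[tuple[str, str], np.ndarray] | None = None,
    shared_snps: Mapping[tuple[str, str], bool] | None = None,
) -> GeneCorrelation:
    """Correlation of predicted expressions from weights and (cross-)gene LD.

    ``cross_ld[(g, h)]`` holds R_gh with rows in gene g's SNP order and
    columns in gene h's; pairs without an entry get correlation 0 (with a
    warning when ``shared_snps`` marks them as actually sharing SNPs).
    """
    D = len(gene_ids)
    sigma = {
        g: float(np.sqrt(weights[g] @ ld_blocks[g] @ weights[g])) for g in gene_ids
    }
    out = np.eye(D)
    cross_ld = cross_ld or {}
    for i, g in enumerate(gene_ids):
        for j in range(i + 1, D):
            h = gene_ids[j]
            block = cross_ld.get((g, h))
            flip = False
            if block is None:
                block = cross_ld.get((h, g))
                flip = block is not None
            if block is None:
                if shared_snps and shared_snps.get((g, h), shared_snps.get((h, g), False)):
                    warnings.warn(
                        f"no cross-gene LD for ({g}, {h}) though they share "
                        "SNPs; correlation set to 0",
                        stacklevel=2,
                    )
                continue
            B = np.asarray(block, dtype=float)
            if flip:
                B = B.T
            val = float(weights[g] @ B @ weights[h]) / (sigma[g] * sigma[h])
            out[i, j] = out[j, i] = val
    np.fill_diagonal(out, 1.0)
    return GeneCorrelation(
        gene_ids=list(gene_ids), matrix=out, provenance="weights-ld"
    )


def regularize(
    sigma: GeneCorrelation, eig_floor: float = EIG_FLOOR
) -> GeneCorrelation:
    """Blend Sigma toward the identity just enough that its smallest
    eigenvalue reaches ``eig_floor``: Sigma <- (1-lam) Sigma + lam I.

    Linear shrinkage preserves the ordering of correlations (unlike eigenvalue
    clipping); the applied lam is recorded. A well-conditioned Sigma passes
    through unchanged.
    """
    A = (sigma.matrix + sigma.matrix.T) / 2.0
    lam_min = float(np.linalg.eigvalsh(A)[0])
    if lam_min >= eig_floor:
        return GeneCorrelation(
            gene_ids=sigma.gene_ids,
            matrix=A,
            provenance=sigma.provenance,
            shrinkage=sigma.shrinkage,
        )
    # smallest lam with (1-lam) lam_min + lam >= eig_floor
    lam = (eig_floor - lam_min) / (1.0 - lam_min)
    out = (1.0 - lam) * A + lam * np.eye(A.shape[0])
    # re-unit the diagonal (no-op when the input had a unit diagonal)
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return GeneCorrelation(
        gene_ids=sigma.gene_ids,
        matrix=out,
        provenance=sigma.provenance,
        shrinkage=sigma.shrinkage + lam,
    )
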