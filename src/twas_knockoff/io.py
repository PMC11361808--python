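"""Readers for GWAS summary statistics, expression weights, LD matrices, and
expression matrices, plus SNP-set intersection and allele harmonization.

All tabular inputs are delimited text with a header; the delimiter is sniffed
from the first line (tab or comma). Per-gene LD may alternatively live in an
HDF5 container keyed by gene id with ``snp_ids`` and ``matrix`` datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for summary-statistic files (PLINK-ish dialect)
DEFAULT_SUMSTAT_COLUMNS: Mapping[str, str] = {
    "snp_id": "snp",
    "effect_allele": "a1",
    "other_allele": "a2",
    "gamma_hat": "beta",
    "se_gamma": "se",
    "n": "n",
}

DEFAULT_WEIGHT_COLUMNS: Mapping[str, str] = {
    "gene_id": "gene_id",
    "snp_id": "snp_id",
    "effect_allele": "a1",
    "other_allele": "a2",
    "weight": "weight",
}


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass
class LdBlock:
    """LD matrix for the SNPs of one gene.

    ``dialect`` records whether entries are correlations or genotype
    covariances; the diagonal carries the per-SNP variances rho_j^2 in the
    covariance dialect and 1 in the correlation dialect.
    """

    gene_id: str
    snp_ids: list[str]
    matrix: np.ndarray
    dialect: str = "correlation"  # "correlation" | "covariance"
    degenerate_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = len(self.snp_ids)
        if self.matrix.shape != (d, d):
            raise FormatError(
                f"LD matrix for {self.gene_id}: shape {self.matrix.shape} "
                f"does not match {d} SNP ids"
            )
        asym = float(np.max(np.abs(self.matrix - self.matrix.T))) if d else 0.0
        if asym > 1e-6:
            warnings.warn(
                f"LD matrix for {self.gene_id} asymmetric (max {asym:.2e}); "
                "symmetrizing",
                stacklevel=2,
            )
        if asym > 0:
            self.matrix = (self.matrix + self.matrix.T) / 2.0
        diag = np.diag(self.matrix)
        bad = [sid for sid, v in zip(self.snp_ids, diag) if v <= 0]
        if bad:
            self.degenerate_snps = sorted(set(self.degenerate_snps) | set(bad))

    def subset(self, snp_ids: Sequence[str]) -> "LdBlock":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LdBlock(
            gene_id=self.gene_id,
            snp_ids=list(snp_ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            dialect=self.dialect,
        )


@dataclass
class HarmonizedGeneData:
    """Aligned weights, summary statistics and LD over one gene's SNP
    intersection; the allele coding of the sumstats is flipped where needed so
    every array refers to the weight set's effect allele."""

    gene_id: str
    snp_ids: list[str]
    weights: np.ndarray
    gamma_hat: np.ndarray
    se_gamma: np.ndarray
    n: np.ndarray
    ld: np.ndarray
    ld_dialect: str = "correlation"
    dropped_snps: dict[str, str] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=sep)


def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str], what: str
) -> Mapping[str, str]:
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for canonical, name in column_map.items():
        if name.lower() not in lower:
            raise FormatError(
                f"{what}: required column {name!r} (for {canonical}) not found; "
                f"available: {list(df.columns)}"
            )
        resolved[canonical] = lower[name.lower()]
    return resolved


def read_sumstats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read per-SNP GWAS summary statistics.

    Returns a DataFrame with canonical columns ``snp_id, effect_allele,
    other_allele, gamma_hat, se_gamma, n``. Rows with missing or non-finite
    required fields, non-positive standard errors, or alleles outside
    {A,C,G,T} are dropped and counted in a log message.
    """
    colmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = _read_table(path)
    cols = _resolve_columns(raw, colmap, "sumstats")
    df = raw[[cols[k] for k in colmap]].copy()
    df.columns = list(colmap)
    df["snp_id"] = df["snp_id"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    n0 = len(df)
    numeric = df[["gamma_hat", "se_gamma", "n"]].apply(
        pd.to_numeric, errors="coerce"
    )
    df[["gamma_hat", "se_gamma", "n"]] = numeric
    keep = (
        np.isfinite(numeric).all(axis=1)
        & (numeric["se_gamma"] > 0)
        & (numeric["n"] > 0)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["snp_id"].str.len() > 0)
    )
    df = df[keep].drop_duplicates(subset=["snp_id"], keep="first").reset_index(drop=True)
    if len(df) < n0:
        logger.info("read_sumstats(%s): dropped %d of %d rows", path, n0 - len(df), n0)
    return df


def read_weights(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read SNP-to-expression weights (gene_id, snp_id, a1, a2, weight)."""
    colmap = dict(DEFAULT_WEIGHT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = _read_table(path)
    cols = _resolve_columns(raw, colmap, "weights")
    df = raw[[cols[k] for k in colmap]].copy()
    df.columns = list(colmap)
    df["gene_id"] = df["gene_id"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    n0 = len(df)
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    keep = (
        np.isfinite(df["weight"])
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
    )
    df = df[keep]
    df = df.drop_duplicates(subset=["gene_id", "snp_id"], keep="first")
    if len(df) < n0:
        logger.info("read_weights(%s): dropped %d of %d rows", path, n0 - len(df), n0)
    return df.reset_index(drop=True)


def _infer_dialect(matrix: np.ndarray) -> str:
    diag = np.diag(matrix)
    return "correlation" if np.allclose(diag, 1.0, atol=1e-6) else "covariance"


def read_ld(
    path: str | Path, gene_id: str | None = None, dialect: str | None = None
) -> LdBlock:
    """Read a per-gene LD matrix.

    ``path`` is either a delimited matrix with a SNP-id header row (one gene),
    or an HDF5 container holding one group per gene id with ``snp_ids`` and
    ``matrix`` datasets (``gene_id`` required then).
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        import h5py

        if gene_id is None:
            raise FormatError("gene_id is required for an HDF5 LD container")
        with h5py.File(path, "r") as fh:
            if gene_id not in fh:
                raise FormatError(f"gene {gene_id!r} not present in {path}")
            grp = fh[gene_id]
            snp_ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in grp["snp_ids"][()]
            ]
            matrix = np.asarray(grp["matrix"][()], dtype=float)
    else:
        df = _read_table(path)
        snp_ids = [str(c) for c in df.columns]
        matrix = df.to_numpy(dtype=float)
        if gene_id is None:
            gene_id = path.stem
    return LdBlock(
        gene_id=gene_id or "",
        snp_ids=snp_ids,
        matrix=matrix,
        dialect=dialect or _infer_dialect(matrix),
    )


def write_ld(path: str | Path, block: LdBlock) -> None:
    pd.DataFrame(block.matrix, columns=block.snp_ids).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a samples x genes expression matrix (header = gene ids)."""
    df = _read_table(path)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise FormatError(f"expression matrix {path} is empty")
    return df.apply(pd.to_numeric)


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return COMPLEMENT.get(a1) == a2


def harmonize(
    gene_weights: pd.DataFrame,
    sumstats: pd.DataFrame,
    ld: LdBlock,
    strand_policy: str = "drop-ambiguous",
) -> HarmonizedGeneData | None:
    """Intersect the SNP sets of one gene's weights, the summary statistics and
    the LD block, and align allele coding.

    When a SNP's effect/other alleles are swapped between the weight set and
    the sumstats (directly or on the opposite strand), the sign of gamma_hat is
    flipped. Strand-ambiguous SNPs (A/T, C/G) are dropped under the default
    policy. Returns None when the harmonized intersection is empty (the gene is
    unusable, not an error).
    """
    if strand_policy not in {"drop-ambiguous", "keep"}:
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    gene_ids = gene_weights["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("harmonize expects the weights of exactly one gene")
    gene_id = gene_ids[0]

    ss = sumstats.set_index("snp_id")
    wt = gene_weights.set_index("snp_id")
    dropped: dict[str, str] = {}
    order: list[str] = []
    signs: list[float] = []
    ld_degenerate = set(ld.degenerate_snps)
    for snp in wt.index:
        if snp not in ss.index or snp not in ld.snp_ids:
            dropped[snp] = "not in intersection"
            continue
        if snp in ld_degenerate:
            dropped[snp] = "degenerate LD diagonal"
            continue
        w1, w2 = wt.at[snp, "effect_allele"], wt.at[snp, "other_allele"]
        s1, s2 = ss.at[snp, "effect_allele"], ss.at[snp, "other_allele"]
        if strand_policy == "drop-ambiguous" and (
            is_strand_ambiguous(w1, w2) or is_strand_ambiguous(s1, s2)
        ):
            dropped[snp] = "strand-ambiguous"
            continue
        c1, c2 = COMPLEMENT[s1], COMPLEMENT[s2]
        if (w1, w2) in {(s1, s2), (c1, c2)}:
            sign = 1.0
        elif (w1, w2) in {(s2, s1), (c2, c1)}:
            sign = -1.0
        else:
            dropped[snp] = f"irreconcilable alleles {w1}/{w2} vs {s1}/{s2}"
            continue
        order.append(snp)
        signs.append(sign)
    if dropped:
        logger.info(
            "harmonize(%s): dropped %d SNPs (%s)",
            gene_id,
            len(dropped),
            "; ".join(f"{k}: {v}" for k, v in dropped.items()),
        )
    if not order:
        return None
    sign_arr = np.array(signs)
    sub = ss.loc[order]
    return HarmonizedGeneData(
        gene_id=gene_id,
        snp_ids=order,
        weights=wt.loc[order, "weight"].to_numpy(dtype=float),
        gamma_hat=sub["gamma_hat"].to_numpy(dtype=float) * sign_arr,
        se_gamma=sub["se_gamma"].to_numpy(dtype=float),
        n=sub["n"].to_numpy(dtype=float),
        ld=ld.subset(order).matrix,
        ld_dialect=ld.dialect,
        dropped_snps=dropped,
    )
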