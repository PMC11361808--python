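"""Knockoff filtering of gene Z-scores: importance scores, kappa/tau
statistics, the GReX feature statistic (GFS), the data-dependent threshold and
the selected gene set with finite-sample FDR control.

Per gene the importance scores are T_g = Z_g^2 and T~_g^m = (Z~_g^m)^2. The
knockoff statistics pool the M+1 scores per gene:

    kappa_g = index of the maximal score (0 = original, 1..M = knockoff copy),
    tau_g   = max score - median of the remaining M scores,

and the GFS is delta_g = tau_g when the original strictly attains the maximum
(so delta_g = T_g - median_m T~_g^m on that event), 0 otherwise. Defining tau
through the pooled maximum rather than always through T_g is what makes
(kappa_g, tau_g) independent for null genes under knockoff exchangeability,
which the FDP estimate below relies on; the two definitions agree on every
selected gene. The threshold is the smallest t > 0 with

    (1/M + (1/M) #{kappa_g >= 1, tau_g >= t}) / max(1, #{kappa_g = 0,
    tau_g >= t}) <= alpha,

and the selection is S^ = {g : delta_g >= t} = {g : kappa_g = 0, tau_g >= t}.
With M = 1 this is the classic model-X knockoff+ filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .correlation import GeneCorrelation, regularize
from .knockoff import build_model, sample_knockoffs, solve_s_equi, solve_s_sdp


def importance_scores(
    z: np.ndarray, z_knock: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Squared Z-scores for the original and each knockoff copy."""
    z = np.asarray(z, dtype=float)
    z_knock = np.asarray(z_knock, dtype=float)
    if z_knock.shape[:-1] != z.shape:
        raise ValueError(
            f"z {z.shape} and z_knock {z_knock.shape} do not conform"
        )
    return z**2, z_knock**2


def kappa_tau(
    T: np.ndarray | float, T_knock: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Knockoff statistics (kappa, tau, delta) from importance scores.

    Scalar T with an M-vector T_knock, or a D-vector T with a (D, M) matrix.
    tau is the pooled maximum minus the median of the remaining M scores, a
    symmetric function of the copies, so that for a null gene kappa is
    uniform over the M+1 copies independently of tau. Ties between the
    original and the best knockoff count as a knockoff win (kappa > 0 and
    delta = 0), the conservative direction.
    """
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    TK = np.asarray(T_knock, dtype=float)
    scalar = np.isscalar(T) or np.ndim(T) == 0
    if TK.ndim == 1:
        TK = TK[None, :] if scalar else TK[:, None]
    if TK.shape[0] != T_arr.shape[0]:
        raise ValueError("T and T_knock do not conform")
    pooled = np.column_stack([T_arr, TK])  # (D, M+1), original first
    order = np.sort(pooled, axis=1)
    knock_max = TK.max(axis=1)
    knock_argmax = TK.argmax(axis=1)
    original_wins = T_arr > knock_max
    kappa = np.where(original_wins, 0, knock_argmax + 1)
    # median of the M scores left after removing the maximum
    tau = order[:, -1] - np.median(order[:, :-1], axis=1)
    delta = np.where(original_wins, tau, 0.0)
    if scalar:
        return int(kappa[0]), float(tau[0]), float(delta[0])
    return kappa, tau, delta


def estimated_fdp(
    kappa: np.ndarray, tau: np.ndarray, t: float, M: int
) -> float:
    """The knockoff plug-in FDP estimate at threshold t."""
    at_least = tau >= t
    n_knock = int(np.sum((kappa >= 1) & at_least))
    n_orig = int(np.sum((kappa == 0) & at_least))
    return (1.0 / M + n_knock / M) / max(1, n_orig)


def knockoff_threshold(
    kappa: np.ndarray, tau: np.ndarray, alpha: float, M: int
) -> tuple[float, float]:
    """Data-dependent threshold: the smallest positive observed tau at which
    the estimated FDP drops to alpha, +inf (empty selection) if none does.

    Returns (threshold, estimated FDP at the threshold).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if M < 1:
        raise ValueError("M must be >= 1")
    kappa = np.asarray(kappa)
    tau = np.asarray(tau, dtype=float)
    if kappa.size == 0:
        raise ValueError("no knockoff statistics supplied")
    for t in np.unique(tau[tau > 0]):
        fdp = estimated_fdp(kappa, tau, float(t), M)
        if fdp <= alpha:
            return float(t), fdp
    return float("inf"), float("nan")


@dataclass
class SelectionResult:
    gene_ids: list[str]
    threshold: float
    alpha: float
    M: int
    kappa: np.ndarray
    tau: np.ndarray
    delta: np.ndarray
    support: np.ndarray  # boolean mask over gene_ids
    fdp_estimate: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return [g for g, keep in zip(self.gene_ids, self.support) if keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "kappa": self.kappa,
                "tau": self.tau,
                "delta": self.delta,
                "selected": self.support,
            }
        )


def select(
    kappa: np.ndarray,
    tau: np.ndarray,
    delta: np.ndarray,
    t_hat: float,
    gene_ids: Sequence[str] | None = None,
    alpha: float = float("nan"),
    M: int = 0,
    fdp_estimate: float = float("nan"),
) -> SelectionResult:
    """Selected set {g : delta_g >= t_hat}; identical to
    {g : kappa_g = 0 and tau_g >= t_hat} since delta = tau exactly on the
    kappa = 0 genes and t_hat > 0."""
    kappa = np.asarray(kappa)
    tau = np.asarray(tau, dtype=float)
    delta = np.asarray(delta, dtype=float)
    support = np.isfinite(t_hat) & (delta >= t_hat)
    if gene_ids is None:
        gene_ids = [str(i) for i in range(kappa.size)]
    return SelectionResult(
        gene_ids=list(gene_ids),
        threshold=float(t_hat),
        alpha=alpha,
        M=M,
        kappa=kappa,
        tau=tau,
        delta=delta,
        support=np.asarray(support, dtype=bool),
        fdp_estimate=fdp_estimate,
    )


def evaluate_selection(
    selected: Collection[str],
    causal: Collection[str],
    alpha: float,
) -> tuple[float, float | None]:
    """Per-replicate contributions to mFDR and TPP.

    mFDR contribution = #false / (#selected + 1/alpha); TPP = #true / #causal
    (None when the causal set is empty). Study-level values are means over
    replicates.
    """
    selected = set(selected)
    causal = set(causal)
    n_false = len(selected - causal)
    mfdr = n_false / (len(selected) + 1.0 / alpha)
    tpp = len(selected & causal) / len(causal) if causal else None
    return mfdr, tpp


class GhostKnockoffFilter(BaseEstimator):
    """Gene selection from Z-scores with finite-sample FDR control.

    Fits on a D-vector of gene Z-scores and the D x D gene correlation matrix
    Sigma; generates M Gaussian knockoff copies of the Z-vector, computes the
    kappa/tau/GFS statistics and the data-dependent threshold at level
    ``alpha``, and exposes the selection as a boolean ``support_``.

    Parameters
    ----------
    alpha : float, default 0.05
        Target (modified) false discovery rate.
    M : int, default 5
        Number of simultaneous knockoff copies; M > 1 stabilizes the
        selection against knockoff sampling noise.
    s_method : {"sdp", "equi"}, default "sdp"
        How the knockoff diagonal Phi = diag(s) is obtained.
    eig_floor : float, default 1e-3
        Lower bound imposed on the smallest eigenvalue of Sigma (linear
        shrinkage toward the identity) before inversion.
    random_state : int, Generator or None
        Seed for the knockoff draw; fixed seed gives bit-identical results.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        M: int = 5,
        s_method: str = "sdp",
        eig_floor: float = 1e-3,
        random_state: int | np.random.Generator | None = None,
    ) -> None:
        self.alpha = alpha
        self.M = M
        self.s_method = s_method
        self.eig_floor = eig_floor
        self.random_state = random_state

    def fit(
        self,
        Z: np.ndarray,
        Sigma: GeneCorrelation | np.ndarray,
        gene_ids: Sequence[str] | None = None,
    ) -> "GhostKnockoffFilter":
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.s_method not in {"sdp", "equi"}:
            raise ValueError(f"unknown s_method {self.s_method!r}")
        Z = np.asarray(Z, dtype=float).ravel()
        if isinstance(Sigma, GeneCorrelation):
            gc = Sigma
            if gene_ids is None:
                gene_ids = gc.gene_ids
        else:
            S = np.asarray(Sigma, dtype=float)
            if S.shape != (Z.size, Z.size):
                raise ValueError(
                    f"Z has {Z.size} genes but Sigma has shape {S.shape}"
                )
            gc = GeneCorrelation(
                gene_ids=[str(i) for i in range(Z.size)], matrix=S
            )
        if gc.n_genes != Z.size:
            raise ValueError(
                f"Z has {Z.size} genes but Sigma is {gc.n_genes} x {gc.n_genes}"
            )
        gc = regularize(gc, eig_floor=self.eig_floor)
        solver = solve_s_sdp if self.s_method == "sdp" else solve_s_equi
        s = solver(gc.matrix, self.M)
        self.model_ = build_model(gc.matrix, self.M, s)
        draw = sample_knockoffs(self.model_, Z, random_state=self.random_state)
        self.z_ = Z
        self.z_knockoff_ = draw.z_knock
        T, TK = importance_scores(Z, draw.z_knock)
        self.kappa_, self.tau_, self.delta_ = kappa_tau(T, TK)
        self.threshold_, self.fdp_estimate_ = knockoff_threshold(
            self.kappa_, self.tau_, self.alpha, self.M
        )
        self.s_ = s
        self.shrinkage_ = gc.shrinkage
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else gc.gene_ids
        self.selection_ = select(
            self.kappa_,
            self.tau_,
            self.delta_,
            self.threshold_,
            gene_ids=self.gene_ids_,
            alpha=self.alpha,
            M=self.M,
            fdp_estimate=self.fdp_estimate_,
        )
        self.support_ = self.selection_.support
        self.n_features_in_ = Z.size
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    @property
    def selected_genes_(self) -> list[str]:
        return self.selection_.selected
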