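"""Ghostknockoff construction for a vector of gene Z-scores.

Given the gene correlation matrix Sigma and a diagonal Phi = diag(s) with
((M+1)/M) Sigma - Phi PSD, M exchangeable Gaussian knockoff copies of
Z ~ N(mu, Sigma) are drawn as

    Z~_m = Theta Z + Lambda_m,     Theta = I - Phi Sigma^{-1},

where the stacked noise (Lambda_1, ..., Lambda_M) is jointly Gaussian with
diagonal blocks V = 2 Phi - Phi Sigma^{-1} Phi and cross blocks
C = Phi - Phi Sigma^{-1} Phi. This yields the exchangeable joint covariance

    Cov(Z, Z~_m) = Cov(Z~_m, Z~_m') = Sigma - Phi,   Cov(Z~_m, Z~_m) = Sigma,

so any null coordinate can be swapped with its knockoff without changing the
joint distribution. Note C itself need not be PSD for M > 1; the stacked noise
covariance I_M (x) Phi + J_M (x) C is PSD exactly when the constraint above
holds, which is what the sampler's orthogonal-rotation factorization uses.

The s-vector comes either from the closed-form equicorrelated solution or from
a coordinate-ascent solver for the semidefinite program
minimize sum_g |1 - s_g| s.t. ((M+1)/M) Sigma - diag(s) >= 0, s >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .correlation import GeneCorrelation

logger = logging.getLogger(__name__)

#: numerical PSD tolerance for feasibility checks
PSD_TOL = 1e-8
#: above this dimension the SDP solver falls back to the equicorrelated form
SDP_MAX_SIZE = 2000


class InfeasibleError(ValueError):
    """s violates the knockoff semidefinite constraint."""


def _as_matrix(sigma: GeneCorrelation | np.ndarray) -> np.ndarray:
    if isinstance(sigma, GeneCorrelation):
        return sigma.matrix
    return np.asarray(sigma, dtype=float)


def _check_pd(sigma: np.ndarray) -> float:
    lam_min = float(np.linalg.eigvalsh(sigma)[0])
    if lam_min <= 0:
        raise ValueError(
            f"Sigma is not positive definite (lambda_min = {lam_min:.3e}); "
            "regularize it first"
        )
    return lam_min


def solve_s_equi(sigma: GeneCorrelation | np.ndarray, M: int) -> np.ndarray:
    """Equicorrelated s: s_g = min(1, ((M+1)/M) lambda_min(Sigma)) for all g."""
    S = _as_matrix(sigma)
    lam_min = _check_pd(S)
    s = min(1.0, (M + 1) / M * lam_min)
    return np.full(S.shape[0], s)


def knockoff_objective(s: np.ndarray) -> float:
    """The SDP objective sum_g |1 - s_g| (smaller = more powerful)."""
    return float(np.sum(np.abs(1.0 - np.asarray(s))))


def _feasibility_margin(sigma: np.ndarray, s: np.ndarray, M: int) -> float:
    return float(np.linalg.eigvalsh((M + 1) / M * sigma - np.diag(s))[0])


def solve_s_sdp(
    sigma: GeneCorrelation | np.ndarray,
    M: int,
    n_sweeps: int = 2,
    max_size: int = SDP_MAX_SIZE,
) -> np.ndarray:
    """Per-gene s maximizing knockoff power.

    Since any optimum has s <= 1, the program reduces to maximizing sum_g s_g
    over {0 <= s <= 1 : A(s) = ((M+1)/M) Sigma - diag(s) PSD}. This is solved
    by an interior-point scheme: coordinate ascent on the jointly concave
    barrier objective sum_g s_g + mu log det A(s), whose exact per-coordinate
    maximizer is s_g = 1/(B^{-1})_gg - mu (B = A with coordinate g's
    subtraction removed, tracked by Sherman-Morrison updates), followed over a
    decreasing barrier schedule mu -> 0. The barrier optimum is unique, so a
    block-diagonal Sigma decomposes into its blockwise solutions. The result
    is kept only if it is feasible and beats the closed-form equicorrelated
    solution; any numerical failure falls back to the equicorrelated form.
    """
    S = _as_matrix(sigma)
    D = S.shape[0]
    s_equi = solve_s_equi(S, M)
    if D > max_size:
        logger.info("solve_s_sdp: D=%d above %d, using equicorrelated s", D, max_size)
        return s_equi
    c = (M + 1) / M
    try:
        import warnings as _warnings

        s = np.zeros(D)
        mus = [0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4]
        with _warnings.catch_warnings(), np.errstate(all="ignore"):
            # near-boundary iterates are expected; garbage is caught by the
            # feasibility repair below
            _warnings.simplefilter("ignore", linalg.LinAlgWarning)
            for mu in mus:
                for _ in range(n_sweeps):
                    A = c * S - np.diag(s)
                    Ainv = linalg.inv(A, check_finite=False)
                    Ainv = (Ainv + Ainv.T) / 2.0
                    for g in range(D):
                        # B = A with coordinate g's subtraction removed
                        u = Ainv[:, g]
                        denom = 1.0 + s[g] * u[g]
                        Binv_gg = u[g] / denom
                        Binv_col = u / denom
                        if not np.isfinite(Binv_gg) or Binv_gg <= 0:
                            raise FloatingPointError(
                                "coordinate update degenerated"
                            )
                        s_new = float(np.clip(1.0 / Binv_gg - mu, 0.0, 1.0))
                        # Ainv for A_new = B - s_new e_g e_g'
                        dd = 1.0 - s_new * Binv_gg
                        Ainv = (
                            Ainv
                            + np.outer(Binv_col, Binv_col) * (s_new / dd)
                            - np.outer(u, u) * (s[g] / denom)
                        )
                        s[g] = s_new
        if not np.all(np.isfinite(s)):
            raise FloatingPointError("non-finite s from coordinate ascent")
        if _feasibility_margin(S, s, M) < -PSD_TOL:
            # scale back toward zero: margin(t*s) is monotone in t, bisect
            lo, hi = 0.0, 1.0
            for _ in range(50):
                mid = (lo + hi) / 2.0
                if _feasibility_margin(S, mid * s, M) >= PSD_TOL:
                    lo = mid
                else:
                    hi = mid
            s = lo * s
        if knockoff_objective(s) <= knockoff_objective(s_equi):
            return s
        logger.info("solve_s_sdp: coordinate ascent worse than equi; using equi")
        return s_equi
    except (FloatingPointError, np.linalg.LinAlgError, linalg.LinAlgError) as err:
        logger.warning("solve_s_sdp failed (%s); falling back to equicorrelated", err)
        return s_equi


@dataclass
class KnockoffModel:
    """Everything needed to sample M exchangeable knockoff copies of Z."""

    sigma: np.ndarray
    M: int
    s: np.ndarray
    theta: np.ndarray  # I - Phi Sigma^{-1}
    V: np.ndarray  # noise covariance, diagonal blocks
    C: np.ndarray  # noise covariance, cross blocks
    _sqrt_phi: np.ndarray  # sqrt(s)
    _sqrt_phi_mc: np.ndarray  # (Phi + M C)^{1/2}
    _rotation: np.ndarray  # M x M orthogonal, first column 1/sqrt(M)

    @property
    def n_genes(self) -> int:
        return self.sigma.shape[0]

    def save(self, path) -> None:
        """Persist (Sigma, M, s) so a selection can be reproduced exactly
        (together with the draw seed recorded in run metadata)."""
        np.savez(path, sigma=self.sigma, M=self.M, s=self.s)

    @classmethod
    def load(cls, path) -> "KnockoffModel":
        with np.load(path) as archive:
            return build_model(
                archive["sigma"], int(archive["M"]), archive["s"]
            )

    def joint_covariance(self) -> np.ndarray:
        """Covariance of the stacked (Z, Z~_1, ..., Z~_M): diagonal blocks
        Sigma, every off-diagonal block Sigma - Phi."""
        D, M = self.n_genes, self.M
        phi = np.diag(self.s)
        off = self.sigma - phi
        out = np.tile(off, (M + 1, M + 1))
        for b in range(M + 1):
            out[b * D : (b + 1) * D, b * D : (b + 1) * D] = self.sigma
        return out


@dataclass
class KnockoffDraw:
    z: np.ndarray
    z_knock: np.ndarray  # D x M (or batch x D x M)
    seed: object = None


def _psd_sqrt(A: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    if vals[0] < -tol:
        raise InfeasibleError(
            f"matrix square root of a non-PSD matrix (lambda_min = {vals[0]:.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def _rotation_matrix(M: int) -> np.ndarray:
    """Orthogonal M x M matrix whose first column is 1/sqrt(M) * ones."""
    A = np.eye(M)
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    if Q[0, 0] < 0:
        Q = -Q
    return Q


def build_model(
    sigma: GeneCorrelation | np.ndarray, M: int, s: np.ndarray
) -> KnockoffModel:
    """Assemble Theta, the noise covariance blocks, and the sampling
    factorization; validates feasibility of s."""
    S = _as_matrix(sigma)
    D = S.shape[0]
    s = np.asarray(s, dtype=float)
    if s.shape != (D,):
        raise ValueError(f"s has shape {s.shape}, expected ({D},)")
    if np.any(s < 0):
        raise InfeasibleError("s must be nonnegative")
    margin = _feasibility_margin(S, s, M)
    if margin < -PSD_TOL:
        raise InfeasibleError(
            f"((M+1)/M) Sigma - Phi has eigenvalue {margin:.3e} < 0; "
            "s is infeasible"
        )
    cho = linalg.cho_factor(S, check_finite=False)
    sig_inv_phi = linalg.cho_solve(cho, np.diag(s), check_finite=False)  # Sigma^{-1} Phi
    theta = np.eye(D) - sig_inv_phi.T
    phi_sig_inv_phi = s[:, None] * sig_inv_phi
    phi_sig_inv_phi = (phi_sig_inv_phi + phi_sig_inv_phi.T) / 2.0
    V = 2.0 * np.diag(s) - phi_sig_inv_phi
    C = np.diag(s) - phi_sig_inv_phi
    assert np.allclose(V - C, np.diag(s), atol=1e-10), "V - C must equal Phi"
    # stacked noise covariance I_M (x) Phi + J_M (x) C is PSD iff Phi + M C is
    sqrt_phi_mc = _psd_sqrt(np.diag(s) + M * C)
    return KnockoffModel(
        sigma=S,
        M=M,
        s=s,
        theta=theta,
        V=V,
        C=C,
        _sqrt_phi=np.sqrt(s),
        _sqrt_phi_mc=sqrt_phi_mc,
        _rotation=_rotation_matrix(M),
    )


def sample_knockoffs(
    model: KnockoffModel,
    z: np.ndarray,
    random_state: int | np.random.Generator | None = None,
) -> KnockoffDraw:
    """Draw the M knockoff copies Z~_m = Theta z + Lambda_m.

    ``z`` may be a single D-vector (returns z_knock of shape (D, M)) or a
    batch of shape (B, D) (returns (B, D, M)). Deterministic for a fixed seed.
    """
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    B, D = Z.shape
    M = model.M
    if D != model.n_genes:
        raise ValueError(f"z has {D} genes, model has {model.n_genes}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("z contains non-finite entries")
    xi = rng.standard_normal((B, M, D))
    rot_blocks = np.empty_like(xi)
    rot_blocks[:, 0, :] = xi[:, 0, :] @ model._sqrt_phi_mc
    rot_blocks[:, 1:, :] = xi[:, 1:, :] * model._sqrt_phi
    lam = np.einsum("ak,bkd->bad", model._rotation, rot_blocks)
    mean = Z @ model.theta.T
    z_knock = mean[:, None, :] + lam  # (B, M, D)
    z_knock = np.swapaxes(z_knock, 1, 2)  # (B, D, M)
    if single:
        z_knock = z_knock[0]
    return KnockoffDraw(z=z, z_knock=z_knock, seed=random_state)
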