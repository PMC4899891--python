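"""Genomic relationship matrices, AI-REML variance components and GBLUP.

The additive relationship matrix follows VanRaden's first method:
``G = W_a W_a' / (2 sum_k p_k q_k)`` with ``W_a`` the allele-count
matrix centred by twice the counted-allele frequency.  The dominance
relationship matrix uses the breeding-model (classical) parameterisation
``D = W_d W_d' / (4 sum_k p_k^2 q_k^2)``, whose dominance-deviation
coding is orthogonal to the allele-substitution coding under
Hardy-Weinberg proportions, so the resulting variance components are
comparable to pedigree-based additive and dominance variances.

Variance components for y = mu + u + v + e with V(u) = G sigma2_a,
V(v) = D sigma2_d are estimated by average-information REML with an
EM-REML fallback whenever an AI step would leave the parameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .io_genotypes import GenotypeTable
from .qc import AlleleFrequencySet

VARIANCE_FLOOR = 1e-10


@dataclass
class RelationshipMatrices:
    """Additive (G) and dominance (D) genomic relationship matrices."""

    G: np.ndarray
    D: np.ndarray
    denom_a: float
    denom_d: float


@dataclass
class VarianceComponents:
    """REML estimates of additive, dominance and residual variances."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    h2_a: float
    h2_d: float
    se_sigma2_a: float = np.nan
    se_sigma2_d: float = np.nan
    se_sigma2_e: float = np.nan
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    boundary: list[str] = field(default_factory=list)


class RemlNonConvergence(RuntimeError):
    """Raised when REML fails to converge; carries the log-likelihood path."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


def center_additive(table: GenotypeTable, freqs: AlleleFrequencySet) -> np.ndarray:
    """Allele-substitution design W_a: code minus 2p per SNP.

    Entries are 2-2p, 1-2p and -2p for genotypes AA, Aa and aa, so
    columns have mean zero when p is estimated from the same animals.
    """
    if table.has_missing():
        raise ValueError("genotype table contains missing codes; impute first")
    p = np.asarray(freqs.p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies outside [0, 1]")
    return table.codes.astype(float) - 2.0 * p


def center_dominance(table: GenotypeTable, freqs: AlleleFrequencySet) -> np.ndarray:
    """Dominance-deviation design W_d.

    Entries are -2q^2 (AA), 2pq (Aa) and -2p^2 (aa); the expected column
    mean under Hardy-Weinberg proportions is exactly zero.
    """
    if table.has_missing():
        raise ValueError("genotype table contains missing codes; impute first")
    p = np.asarray(freqs.p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies outside [0, 1]")
    q = 1.0 - p
    codes = table.codes
    W = np.where(codes == 2, -2.0 * q * q, np.where(codes == 1, 2.0 * p * q, -2.0 * p * p))
    return W.astype(float)


def make_G(W_a: np.ndarray, freqs: AlleleFrequencySet) -> np.ndarray:
    """VanRaden additive relationship matrix W_a W_a' / (2 sum p q)."""
    p = freqs.p
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: additive denominator is zero")
    return (W_a @ W_a.T) / denom


def make_D(W_d: np.ndarray, freqs: AlleleFrequencySet) -> np.ndarray:
    """Dominance relationship matrix W_d W_d' / (4 sum p^2 q^2)."""
    p = freqs.p
    q = 1.0 - p
    denom = 4.0 * float((p * p * q * q).sum())
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: dominance denominator is zero")
    return (W_d @ W_d.T) / denom


def genomic_relationships(
    table: GenotypeTable, freqs: AlleleFrequencySet | None = None
) -> RelationshipMatrices:
    """Build G and D from a table, defaulting to observed frequencies."""
    from .qc import allele_frequencies

    if freqs is None:
        freqs = allele_frequencies(table)
    W_a = center_additive(table, freqs)
    W_d = center_dominance(table, freqs)
    p = freqs.p
    q = 1.0 - p
    return RelationshipMatrices(
        G=make_G(W_a, freqs),
        D=make_D(W_d, freqs),
        denom_a=2.0 * float((p * q).sum()),
        denom_d=4.0 * float((p * p * q * q).sum()),
    )


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def _reml_core(
    y: np.ndarray,
    kernels: list[np.ndarray],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float], list[bool]]:
    """AI-REML over variance components for V = sum_i theta_i K_i.

    The last kernel must be the identity (residual).  Returns estimates,
    the final AI matrix, the final log-likelihood, the iteration count,
    the log-likelihood trajectory and per-component boundary flags.
    """
    n = y.size
    X = np.ones((n, 1))
    n_comp = len(kernels)
    vy = float(np.var(y))
    theta = np.full(n_comp, vy / n_comp)
    trajectory: list[float] = []
    ll_old = -np.inf
    ai = np.eye(n_comp)
    at_floor = np.zeros(n_comp, dtype=bool)
    small_count = np.zeros(n_comp, dtype=int)
    small_cut = vy * 1e-6

    for it in range(1, max_iter + 1):
        V = sum(t * K for t, K in zip(theta, kernels))
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RemlNonConvergence(f"V not positive definite: {exc}", trajectory)
        Vinv_y = linalg.cho_solve(cf, y)
        Vinv_X = linalg.cho_solve(cf, X)
        XtVinvX = X.T @ Vinv_X
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ np.linalg.solve(XtVinvX, X.T @ Vinv_y)
        logdet_v = 2.0 * float(np.log(np.diag(cf[0])).sum())
        logdet_x = float(np.log(np.linalg.det(XtVinvX)))
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        trajectory.append(ll)

        # P K_i Py and traces tr(P K_i); P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv
        KPy = [K @ Py for K in kernels]
        PKPy = []
        for v in KPy:
            w = linalg.cho_solve(cf, v)
            w -= Vinv_X @ np.linalg.solve(XtVinvX, X.T @ w)
            PKPy.append(w)
        Vinv = linalg.cho_solve(cf, np.eye(n))
        P = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
        tr_PK = np.array([float((P * K.T).sum()) for K in kernels])

        score = np.array(
            [-0.5 * (tr_PK[i] - float(Py @ KPy[i])) for i in range(n_comp)]
        )
        ai = np.array(
            [[0.5 * float(KPy[i] @ PKPy[j]) for j in range(n_comp)] for i in range(n_comp)]
        )
        ai = 0.5 * (ai + ai.T)

        free = ~at_floor
        step = np.zeros(n_comp)
        try:
            step[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            step[free] = np.nan
        proposal = theta + step
        if not np.isfinite(proposal).all():
            # EM-REML update keeps estimates positive
            em = theta + theta**2 * np.array(
                [(float(Py @ KPy[i]) - tr_PK[i]) / n for i in range(n_comp)]
            )
            proposal = np.where(free, em, theta)
        # components the AI step drives negative are shrunk toward zero
        # (EM-style geometric decay) instead of rejecting the whole step
        bad = free & (proposal <= 0)
        proposal[bad] = np.maximum(theta[bad] * 0.1, VARIANCE_FLOOR)
        proposal[~free] = VARIANCE_FLOOR
        theta = np.maximum(proposal, VARIANCE_FLOOR)

        small_count = np.where(theta < small_cut, small_count + 1, 0)
        at_floor = at_floor | (small_count >= 3)
        theta[at_floor] = VARIANCE_FLOOR

        if abs(ll - ll_old) < tol:
            return theta, ai, ll, it, trajectory, list(at_floor)
        ll_old = ll
    raise RemlNonConvergence(
        f"AI-REML did not converge in {max_iter} iterations", trajectory
    )


def reml_ad(
    y: np.ndarray,
    G: np.ndarray,
    D: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_d, sigma2_e) by AI-REML.

    With ``D=None`` a two-component additive model is fitted and
    sigma2_d is reported as 0.  A small ridge is added to G and D
    diagonals for numerical stability.  Standard errors come from the
    inverse of the final average-information matrix; components that hit
    the variance floor are reported as 0 with a boundary flag and no SE.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.shape != (n, n):
        raise ValueError("G dimension does not match phenotype length")
    kernels = [G + ridge * np.eye(n)]
    names = ["sigma2_a"]
    if D is not None:
        if D.shape != (n, n):
            raise ValueError("D dimension does not match phenotype length")
        kernels.append(D + ridge * np.eye(n))
        names.append("sigma2_d")
    kernels.append(np.eye(n))
    names.append("sigma2_e")

    theta, ai, ll, n_iter, _traj, floored = _reml_core(y, kernels, max_iter, tol)

    se = np.full(len(theta), np.nan)
    free = ~np.asarray(floored)
    if free.any():
        try:
            cov = np.linalg.inv(ai[np.ix_(free, free)])
            se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass

    est = {name: (0.0 if fl else float(t)) for name, t, fl in zip(names, theta, floored)}
    ses = {name: float(s) for name, s in zip(names, se)}
    boundary = [name for name, fl in zip(names, floored) if fl]
    s2a = est["sigma2_a"]
    s2d = est.get("sigma2_d", 0.0)
    s2e = est["sigma2_e"]
    total = s2a + s2d + s2e
    return VarianceComponents(
        sigma2_a=s2a,
        sigma2_d=s2d,
        sigma2_e=s2e,
        h2_a=s2a / total,
        h2_d=s2d / total,
        se_sigma2_a=ses["sigma2_a"],
        se_sigma2_d=ses.get("sigma2_d", np.nan),
        se_sigma2_e=ses["sigma2_e"],
        loglik=ll,
        n_iter=n_iter,
        converged=True,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# GBLUP and SNP-effect back-solving
# ---------------------------------------------------------------------------

def build_mme(
    y: np.ndarray, G: np.ndarray, D: Optional[np.ndarray], vc: VarianceComponents,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-model equations for y = 1 mu + u (+ v) + e.

    Unknown order: [mu, u, v].  Relationship matrices are ridged before
    inversion.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if vc.sigma2_a <= 0 or vc.sigma2_e <= 0 or (D is not None and vc.sigma2_d <= 0):
        raise ValueError("GBLUP requires strictly positive variance components")
    ones = np.ones((n, 1))
    Ginv = np.linalg.inv(G + ridge * np.eye(n))
    lam_a = vc.sigma2_e / vc.sigma2_a
    blocks = 2 if D is None else 3
    size = 1 + n * (blocks - 1)
    lhs = np.zeros((size, size))
    rhs = np.zeros(size)
    lhs[0, 0] = n
    lhs[0, 1 : n + 1] = 1.0
    lhs[1 : n + 1, 0] = 1.0
    lhs[1 : n + 1, 1 : n + 1] = np.eye(n) + Ginv * lam_a
    rhs[0] = y.sum()
    rhs[1 : n + 1] = y
    if D is not None:
        Dinv = np.linalg.inv(D + ridge * np.eye(n))
        lam_d = vc.sigma2_e / vc.sigma2_d
        lhs[0, n + 1 :] = 1.0
        lhs[n + 1 :, 0] = 1.0
        lhs[1 : n + 1, n + 1 :] = np.eye(n)
        lhs[n + 1 :, 1 : n + 1] = np.eye(n)
        lhs[n + 1 :, n + 1 :] = np.eye(n) + Dinv * lam_d
        rhs[n + 1 :] = y
    return lhs, rhs


def gblup_solve(
    y: np.ndarray,
    G: np.ndarray,
    D: Optional[np.ndarray],
    vc: VarianceComponents,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, Optional[np.ndarray], float]:
    """Solve the mixed-model equations; returns (u_hat, v_hat, mu_hat)."""
    lhs, rhs = build_mme(y, G, D, vc, ridge=ridge)
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular mixed-model equations: {exc}")
    n = y.size
    mu_hat = float(sol[0])
    u_hat = sol[1 : n + 1]
    v_hat = sol[n + 1 :] if D is not None else None
    return u_hat, v_hat, mu_hat


def backsolve_snp_effects(
    u_hat: np.ndarray,
    W_a: np.ndarray,
    v_hat: Optional[np.ndarray] = None,
    W_d: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Back-solve GBLUP animal solutions into per-SNP effects.

    a_hat = W_a' (W_a W_a')^- u_hat, with a Moore-Penrose generalized
    inverse, so W_a a_hat reproduces u_hat exactly whenever W_a has full
    row rank.  Dominance effects are back-solved analogously from v_hat.
    """
    WWt = W_a @ W_a.T
    rank = np.linalg.matrix_rank(WWt)
    if rank < WWt.shape[0]:
        warnings.warn(
            f"W_a W_a' is rank deficient ({rank} < {WWt.shape[0]}); "
            "using a pseudo-inverse",
            RuntimeWarning,
        )
    a_hat = W_a.T @ (np.linalg.pinv(WWt) @ np.asarray(u_hat, dtype=float))
    d_hat = None
    if v_hat is not None:
        if W_d is None:
            raise ValueError("v_hat given without W_d")
        d_hat = W_d.T @ (np.linalg.pinv(W_d @ W_d.T) @ np.asarray(v_hat, dtype=float))
    return a_hat, d_hat


def relationship_diagnostics(G: np.ndarray, groups: list[str]) -> dict:
    """Off-diagonal variance of G overall and within groups, plus mean
    cross-group relationships.

    Small off-diagonal variance indicates weak family structure among
    the animals; the mean cross-group relationship measures how related
    two groups (e.g. validation boars and training sows) are.
    """
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 animals")
    if len(groups) != n:
        raise ValueError("one group label per animal required")
    off_mask = ~np.eye(n, dtype=bool)
    out: dict = {
        "offdiag_variance": float(G[off_mask].var()),
        "offdiag_variance_within": {},
        "mean_cross_group": {},
    }
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(groups))
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size >= 2:
            sub = G[np.ix_(idx, idx)]
            mask = ~np.eye(idx.size, dtype=bool)
            out["offdiag_variance_within"][g] = float(sub[mask].var())
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1 :]:
            idx1 = np.flatnonzero(labels == g1)
            idx2 = np.flatnonzero(labels == g2)
            out["mean_cross_group"][f"{g1}|{g2}"] = float(
                G[np.ix_(idx1, idx2)].mean()
            )
    return out
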