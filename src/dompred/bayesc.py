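"""BayesC marker-effect estimation for additive and additive+dominance models.

Two single-trait marker models are supported:

* MA  : y_i = mu + sum_j X_ij a_j + e_i
* MAD : y_i = mu + sum_j X_ij a_j + sum_j Z_ij d_j + e_i

where X_ij counts copies of the counted allele (0/1/2) and Z_ij is the
heterozygosity indicator.  Effects in each class (additive, dominance)
follow a spike-and-slab prior: with probability pi a SNP effect is drawn
from N(0, sigma^2_class), otherwise it is exactly zero.  pi is given a
Beta(1, 1) prior per class and sampled; class and residual variances get
scaled-inverse-chi-square priors.  Estimation is by single-site Gibbs
sampling with effects updated in fixed index order, so chains are fully
reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from numba import njit
from scipy import stats

from .io_genotypes import GenotypeTable


@dataclass
class DesignPair:
    """Additive design X (codes 0/1/2) and dominance design Z (het indicator)."""

    X: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.Z = np.ascontiguousarray(self.Z, dtype=np.float64)
        if self.X.shape != self.Z.shape:
            raise ValueError("X and Z must have identical shape")
        if not np.all((self.Z == 0) | (self.Z == 1)):
            raise ValueError("Z must be a 0/1 indicator matrix")
        if np.any((self.X == 1) != (self.Z == 1)):
            raise ValueError("Z must indicate exactly the heterozygous entries of X")


@dataclass
class BayesCConfig:
    """Sampler settings and prior hyper-parameters.

    ``r2`` is the prior share of var(y) attributed to markers; it is
    split equally across the effect classes of the model and converted
    into the scale of each class's scaled-inverse-chi-square variance
    prior (df ``df_effect``) assuming half of the markers are included.
    ``pi_additive`` / ``pi_dominance`` fix the inclusion probability of
    a class instead of sampling it (None = sample with a Beta(1,1) prior).
    """

    n_iter: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    df_effect: float = 5.0
    df_resid: float = 5.0
    r2: float = 0.5
    pi_additive: Optional[float] = None
    pi_dominance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MarkerEffectPosterior:
    """Posterior summaries of a BayesC fit."""

    model: str
    a_hat: np.ndarray
    pip_a: np.ndarray
    mu_hat: float
    sigma2_e_hat: float
    sigma2_a_hat: float
    pi_a_hat: float
    d_hat: Optional[np.ndarray] = None
    pip_d: Optional[np.ndarray] = None
    sigma2_d_hat: Optional[float] = None
    pi_d_hat: Optional[float] = None
    deviance_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu_chain: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2_e_chain: np.ndarray = field(default_factory=lambda: np.empty(0))
    snp_ids: Optional[list[str]] = None


def build_designs(table: GenotypeTable) -> DesignPair:
    """Build X (additive codes) and Z (heterozygosity indicators) from a table."""
    if table.has_missing():
        raise ValueError("genotype table contains missing codes; impute first")
    X = table.codes.astype(np.float64)
    Z = (table.codes == 1).astype(np.float64)
    return DesignPair(X, Z)


@njit(cache=True)
def _gibbs(y, X, Z, use_dom, n_iter, burn_in, thin, seed,
           nu_eff, s2_a, s2_d, nu_e, s2_e0,
           pi_a_fixed, pi_d_fixed):
    """Single-site Gibbs sampler; returns posterior sums and kept chains."""
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    ztz = np.empty(m)
    for j in range(m):
        sx = 0.0
        sz = 0.0
        for i in range(n):
            sx += X[i, j] * X[i, j]
            sz += Z[i, j] * Z[i, j]
        xtx[j] = sx
        ztz[j] = sz

    a = np.zeros(m)
    d = np.zeros(m)
    inc_a = np.zeros(m, dtype=np.int8)
    inc_d = np.zeros(m, dtype=np.int8)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    sigma2_a = s2_a
    sigma2_d = s2_d
    sigma2_e = s2_e0
    pi_a = pi_a_fixed if pi_a_fixed >= 0.0 else 0.5
    pi_d = pi_d_fixed if pi_d_fixed >= 0.0 else 0.5

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    n_keep = (n_iter - burn_in) // thin
    sum_a = np.zeros(m)
    sum_d = np.zeros(m)
    sum_inc_a = np.zeros(m)
    sum_inc_d = np.zeros(m)
    sum_mu = 0.0
    sum_s2e = 0.0
    sum_s2a = 0.0
    sum_s2d = 0.0
    sum_pi_a = 0.0
    sum_pi_d = 0.0
    dev = np.empty(n_keep)
    mu_chain = np.empty(n_keep)
    s2e_chain = np.empty(n_keep)
    kept = 0

    for it in range(n_iter):
        # intercept
        se = 0.0
        for i in range(n):
            se += e[i]
        mu_new = mu + se / n + np.random.normal() * math.sqrt(sigma2_e / n)
        delta = mu_new - mu
        for i in range(n):
            e[i] -= delta
        mu = mu_new

        # additive effects, fixed index order
        log_odds_base_a = math.log(pi_a / (1.0 - pi_a)) if 0.0 < pi_a < 1.0 else 0.0
        k_in_a = 0
        ssq_a = 0.0
        for j in range(m):
            old = a[j]
            if xtx[j] == 0.0:
                # constant column: effect unidentifiable, sample inclusion from prior
                a[j] = 0.0
                inc_a[j] = 1 if np.random.random() < pi_a else 0
                if inc_a[j] == 1:
                    k_in_a += 1
                continue
            r = 0.0
            for i in range(n):
                r += X[i, j] * e[i]
            r += xtx[j] * old
            v0 = xtx[j] * sigma2_e
            v1 = xtx[j] * xtx[j] * sigma2_a + v0
            if pi_a <= 0.0:
                include = False
            elif pi_a >= 1.0:
                include = True
            else:
                log_bf = 0.5 * math.log(v0 / v1) + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
                lo = log_odds_base_a + log_bf
                if lo > 35.0:
                    include = True
                elif lo < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + math.exp(-lo))
            if include:
                c = xtx[j] + sigma2_e / sigma2_a
                mean = r / c
                new = mean + np.random.normal() * math.sqrt(sigma2_e / c)
                inc_a[j] = 1
                k_in_a += 1
                ssq_a += new * new
            else:
                new = 0.0
                inc_a[j] = 0
            if new != old:
                diff = old - new
                for i in range(n):
                    e[i] += X[i, j] * diff
            a[j] = new

        # dominance effects
        k_in_d = 0
        ssq_d = 0.0
        if use_dom:
            log_odds_base_d = math.log(pi_d / (1.0 - pi_d)) if 0.0 < pi_d < 1.0 else 0.0
            for j in range(m):
                old = d[j]
                if ztz[j] == 0.0:
                    d[j] = 0.0
                    inc_d[j] = 1 if np.random.random() < pi_d else 0
                    if inc_d[j] == 1:
                        k_in_d += 1
                    continue
                r = 0.0
                for i in range(n):
                    r += Z[i, j] * e[i]
                r += ztz[j] * old
                v0 = ztz[j] * sigma2_e
                v1 = ztz[j] * ztz[j] * sigma2_d + v0
                if pi_d <= 0.0:
                    include = False
                elif pi_d >= 1.0:
                    include = True
                else:
                    log_bf = 0.5 * math.log(v0 / v1) + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
                    lo = log_odds_base_d + log_bf
                    if lo > 35.0:
                        include = True
                    elif lo < -35.0:
                        include = False
                    else:
                        include = np.random.random() < 1.0 / (1.0 + math.exp(-lo))
                if include:
                    c = ztz[j] + sigma2_e / sigma2_d
                    mean = r / c
                    new = mean + np.random.normal() * math.sqrt(sigma2_e / c)
                    inc_d[j] = 1
                    k_in_d += 1
                    ssq_d += new * new
                else:
                    new = 0.0
                    inc_d[j] = 0
                if new != old:
                    diff = old - new
                    for i in range(n):
                        e[i] += Z[i, j] * diff
                d[j] = new

        # inclusion probabilities
        if pi_a_fixed < 0.0:
            pi_a = np.random.beta(1.0 + k_in_a, 1.0 + m - k_in_a)
        if use_dom and pi_d_fixed < 0.0:
            pi_d = np.random.beta(1.0 + k_in_d, 1.0 + m - k_in_d)

        # variances (scaled-inverse-chi-square full conditionals)
        sigma2_a = (ssq_a + nu_eff * s2_a) / np.random.chisquare(nu_eff + k_in_a)
        if use_dom:
            sigma2_d = (ssq_d + nu_eff * s2_d) / np.random.chisquare(nu_eff + k_in_d)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (sse + nu_e * s2_e0) / np.random.chisquare(n + nu_e)

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            sum_mu += mu
            sum_s2e += sigma2_e
            sum_s2a += sigma2_a
            sum_s2d += sigma2_d
            sum_pi_a += pi_a
            sum_pi_d += pi_d
            for j in range(m):
                sum_a[j] += a[j]
                sum_inc_a[j] += inc_a[j]
                if use_dom:
                    sum_d[j] += d[j]
                    sum_inc_d[j] += inc_d[j]
            dev[kept] = n * math.log(2.0 * math.pi * sigma2_e) + sse / sigma2_e
            mu_chain[kept] = mu
            s2e_chain[kept] = sigma2_e
            kept += 1

    return (sum_a / kept, sum_inc_a / kept, sum_d / kept, sum_inc_d / kept,
            sum_mu / kept, sum_s2e / kept, sum_s2a / kept, sum_s2d / kept,
            sum_pi_a / kept, sum_pi_d / kept, dev[:kept], mu_chain[:kept],
            s2e_chain[:kept])


def fit_bayesc(
    y: np.ndarray,
    designs: DesignPair,
    model: Literal["MA", "MAD"] = "MA",
    config: BayesCConfig | None = None,
    snp_ids: Optional[list[str]] = None,
) -> MarkerEffectPosterior:
    """Fit model MA or MAD by BayesC Gibbs sampling.

    Returns posterior means over the kept, thinned samples.  The chain
    is bitwise reproducible given the configuration seed.
    """
    config = config or BayesCConfig()
    y = np.ascontiguousarray(y, dtype=np.float64)
    if y.size != designs.X.shape[0]:
        raise ValueError("phenotype length does not match design rows")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes contain non-finite values")
    vy = float(np.var(y))
    if vy == 0.0:
        raise ValueError("phenotypes have zero variance")
    if model not in ("MA", "MAD"):
        raise ValueError(f"unknown model {model!r}")
    use_dom = model == "MAD"

    # prior scales: prior-mean class variance implies r2*var(y) explained,
    # split across classes, assuming half of the markers included
    n_classes = 2 if use_dom else 1
    nu = config.df_effect
    var_x = designs.X.var(axis=0)
    var_z = designs.Z.var(axis=0)
    msx = max(float(var_x.sum()), 1e-12) * 0.5
    msz = max(float(var_z.sum()), 1e-12) * 0.5
    share = config.r2 * vy / n_classes
    s2_a = share / msx * (nu - 2.0) / nu
    s2_d = share / msz * (nu - 2.0) / nu
    nu_e = config.df_resid
    s2_e0 = (1.0 - config.r2) * vy * (nu_e - 2.0) / nu_e

    pi_a_fixed = -1.0 if config.pi_additive is None else float(config.pi_additive)
    pi_d_fixed = -1.0 if config.pi_dominance is None else float(config.pi_dominance)

    (a_hat, pip_a, d_hat, pip_d, mu_hat, s2e, s2a, s2d, pi_a, pi_d,
     dev, mu_chain, s2e_chain) = _gibbs(
        y, designs.X, designs.Z, use_dom,
        config.n_iter, config.burn_in, config.thin, config.seed,
        nu, s2_a, s2_d, nu_e, s2_e0, pi_a_fixed, pi_d_fixed,
    )
    post = MarkerEffectPosterior(
        model=model,
        a_hat=a_hat,
        pip_a=pip_a,
        mu_hat=float(mu_hat),
        sigma2_e_hat=float(s2e),
        sigma2_a_hat=float(s2a),
        pi_a_hat=float(pi_a),
        deviance_samples=dev,
        mu_chain=mu_chain,
        sigma2_e_chain=s2e_chain,
        snp_ids=snp_ids,
    )
    if use_dom:
        post.d_hat = d_hat
        post.pip_d = pip_d
        post.sigma2_d_hat = float(s2d)
        post.pi_d_hat = float(pi_d)
    return post


def _plugin_residuals(y: np.ndarray, designs: DesignPair, posterior: MarkerEffectPosterior) -> np.ndarray:
    fitted = posterior.mu_hat + designs.X @ posterior.a_hat
    if posterior.d_hat is not None:
        fitted = fitted + designs.Z @ posterior.d_hat
    return y - fitted


def log_likelihood(y: np.ndarray, designs: DesignPair, posterior: MarkerEffectPosterior) -> float:
    """Gaussian log-likelihood at the plug-in posterior-mean parameters."""
    e = _plugin_residuals(np.asarray(y, dtype=float), designs, posterior)
    n = e.size
    s2 = posterior.sigma2_e_hat
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + e @ e / s2))


def dic(posterior: MarkerEffectPosterior, y: np.ndarray, designs: DesignPair) -> float:
    """Deviance information criterion: mean deviance + p_D.

    p_D = mean posterior deviance minus the deviance at the posterior
    means of (mu, effects, sigma^2_e), under the Gaussian likelihood.
    """
    if posterior.deviance_samples.size == 0:
        raise ValueError("posterior carries no deviance samples")
    mean_dev = float(posterior.deviance_samples.mean())
    dev_at_mean = -2.0 * log_likelihood(y, designs, posterior)
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d


def likelihood_ratio_compare(
    fit_ma: MarkerEffectPosterior,
    fit_mad: MarkerEffectPosterior,
    y: np.ndarray,
    designs: DesignPair,
) -> tuple[float, float]:
    """Chi-square statistic and p-value for MAD against MA.

    The statistic is 2*(logL_MAD - logL_MA) with both likelihoods
    evaluated at plug-in posterior means, referred to a 1-df chi-square
    distribution.  This is an approximation to a formal likelihood-ratio
    test, not a maximised ratio.
    """
    if fit_ma.model != "MA" or fit_mad.model != "MAD":
        raise ValueError("expected an MA fit and a MAD fit, in that order")
    if fit_ma.a_hat.size != fit_mad.a_hat.size:
        raise ValueError("fits come from different SNP panels")
    y = np.asarray(y, dtype=float)
    if y.size != designs.X.shape[0]:
        raise ValueError("phenotype length does not match design rows")
    chi2 = 2.0 * (log_likelihood(y, designs, fit_mad) - log_likelihood(y, designs, fit_ma))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), p


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a series at frequency zero, Bartlett-windowed."""
    n = x.size
    xc = x - x.mean()
    if n < 2:
        return 0.0
    max_lag = max(1, int(np.floor(n ** 0.5)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, max_lag + 1):
        gamma = float(xc[lag:] @ xc[:-lag]) / n
        s += 2.0 * (1.0 - lag / (max_lag + 1.0)) * gamma
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Segment-mean variances use spectral density estimates at frequency
    zero, so autocorrelation within the chain is accounted for.  A
    constant chain returns 0 by convention.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    if n < 20:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 20)")
    n1 = max(int(np.floor(first_frac * n)), 2)
    n2 = max(int(np.floor(last_frac * n)), 2)
    first = chain[:n1]
    last = chain[n - n2:]
    if np.ptp(chain) == 0.0:
        return 0.0
    var1 = _spectral_density_zero(first) / n1
    var2 = _spectral_density_zero(last) / n2
    denom = np.sqrt(var1 + var2)
    if denom == 0.0:
        return 0.0
    return float((first.mean() - last.mean()) / denom)
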