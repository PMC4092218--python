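"""Weighted spike-and-slab Bayesian variable selection by Gibbs sampling.

Model for a deregressed-EBV response y (length n) and dosage matrix X
(n x p):

    y = mu + X beta + e,      e_i ~ N(0, sigma2_e / w_i)

with a two-component Gaussian mixture prior on each SNP effect,

    beta_j | gamma_j = 0 ~ N(0, sigma2_0)        (null: small effects)
    beta_j | gamma_j = 1 ~ N(0, sigma2_1)        (slab: large effects)
    gamma_j ~ Bernoulli(pi1),   sigma2_1 = kappa * sigma2_0,

pi1 fixed (default 0.001, i.e. one SNP in a thousand carries a large
effect).  Each cycle jointly updates (gamma_j, beta_j) per SNP from the
full conditional with beta_j integrated out of the component choice, then
mu, then the variance components from scaled-inverse-chi-square
conditionals (an optional random-walk Metropolis-Hastings step can replace
the Gibbs draw for sigma2_0).  Residuals are maintained incrementally so a
cycle costs O(np); a recomputation identity for the deviance guards the
bookkeeping.

The per-SNP posterior inclusion frequency p_hat_j is the post-burn-in
fraction of cycles with gamma_j = 1; downstream it becomes a Bayes factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "BVSConfig",
    "ChainState",
    "PosteriorSummary",
    "run_chain",
    "compute_deviance",
    "gelman_rubin",
    "enumerate_inclusion_probabilities",
    "grouped_variance_shares",
]


@dataclass
class BVSConfig:
    """Sampler configuration.

    Defaults follow the dense-chip GWAS setting this package targets:
    prior inclusion probability pi1 = 0.001 (pi0 = 0.999), 500,000 cycles
    with a 5,000-cycle burn-in.  ``desk_scale`` gives a profile sized for
    laptop-scale synthetic runs.
    """

    pi1: float = 0.001
    n_iter: int = 500_000
    burn_in: int = 5_000
    thin: int = 50
    n_chains: int = 2
    kappa: float = 100.0
    prior_df_e: float = 4.0
    prior_scale_e: float | None = None  # None: 0.5 * Var(y)
    prior_df_beta: float = 4.0
    prior_scale_beta: float | None = None  # None: matched to 0.5 * Var(y) genomic variance
    sample_mu: bool = True
    fix_sigma2_e: float | None = None
    fix_sigma2_0: float | None = None
    mh_sigma0: bool = False
    mh_step: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError(f"pi1 must be in (0, 1), got {self.pi1}")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.kappa <= 1.0:
            raise ValueError("kappa (slab/spike variance ratio) must exceed 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "BVSConfig":
        """Profile for synthetic desk-scale runs (n ~ 1,000, p ~ 5,000)."""
        defaults = dict(n_iter=20_000, burn_in=2_000, thin=20)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ChainState:
    """Complete sampler state at one cycle."""

    mu: float
    beta: np.ndarray
    gamma: np.ndarray
    sigma2_0: float
    sigma2_e: float
    kappa: float = 100.0

    @property
    def sigma2_1(self) -> float:
        return self.kappa * self.sigma2_0


@dataclass
class PosteriorSummary:
    """Posterior inclusion frequencies, effect summaries and diagnostics."""

    p_hat: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    deviance_traces: np.ndarray  # (n_chains, n_stored)
    sigma2_0_traces: np.ndarray
    sigma2_e_traces: np.ndarray
    beta_samples: np.ndarray  # (n_stored_total, p) float32, pooled over chains
    gamma_samples: np.ndarray  # (n_stored_total, p) uint8
    n_kept: int
    gelman_rubin_deviance: float | None
    final_deviances: tuple[float, ...] = ()  # incrementally maintained, per chain
    final_states: list[ChainState] = field(repr=False, default_factory=list)
    config: BVSConfig | None = None
    chain_seeds: tuple[int, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.n_kept


@njit(cache=False, fastmath=True)
def _bvs_kernel(
    X,  # (n, p) float32, Fortran order
    y,  # (n,) float64
    w,  # (n,) float64
    xtwx,  # (p,) float64
    pi1,
    kappa,
    n_iter,
    burn_in,
    thin,
    nu_e,
    scale_e,
    nu_b,
    scale_b,
    sample_mu,
    fix_s2e,
    s2e_init,
    fix_s20,
    s20_init,
    mh_sigma0,
    mh_step,
    seed,
):
    np.random.seed(seed)
    n, p = X.shape
    n_store = (n_iter - burn_in) // thin

    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.uint8)
    sumw = w.sum()
    sumlogw = np.log(w).sum()
    # intercept starts at the weighted mean; with sample_mu off it stays
    # fixed at zero (no-intercept model, as the enumeration oracle assumes)
    mu = 0.0
    if sample_mu:
        for i in range(n):
            mu += w[i] * y[i]
        mu /= sumw
    ew = np.empty(n)
    for i in range(n):
        ew[i] = w[i] * (y[i] - mu)

    s2e = s2e_init
    s20 = s20_init
    log_prior_odds = math.log(pi1) - math.log(1.0 - pi1)

    incl = np.zeros(p)
    bsum = np.zeros(p)
    bsumsq = np.zeros(p)
    dev_trace = np.empty(n_store)
    s20_trace = np.empty(n_store)
    s2e_trace = np.empty(n_store)
    beta_samples = np.zeros((n_store, p), dtype=np.float32)
    gamma_samples = np.zeros((n_store, p), dtype=np.uint8)
    kept = 0
    stored = 0

    for it in range(n_iter):
        v0 = s20
        v1 = kappa * s20
        lv0 = math.log(v0)
        lv1 = math.log(v1)
        for j in range(p):
            bj = beta[j]
            r = 0.0
            for i in range(n):
                r += X[i, j] * ew[i]
            r += xtwx[j] * bj
            rhs = r / s2e
            prec = xtwx[j] / s2e
            V0 = 1.0 / (prec + 1.0 / v0)
            V1 = 1.0 / (prec + 1.0 / v1)
            lm0 = 0.5 * (math.log(V0) - lv0 + rhs * rhs * V0)
            lm1 = 0.5 * (math.log(V1) - lv1 + rhs * rhs * V1)
            logit = log_prior_odds + lm1 - lm0
            if logit > 35.0:
                p1 = 1.0
            elif logit < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + math.exp(-logit))
            if np.random.random() < p1:
                g = 1
                V = V1
            else:
                g = 0
                V = V0
            bnew = V * rhs + math.sqrt(V) * np.random.normal()
            gamma[j] = g
            beta[j] = bnew
            delta = bnew - bj
            if delta != 0.0:
                for i in range(n):
                    ew[i] -= w[i] * X[i, j] * delta

        if sample_mu:
            m_mean = mu + ew.sum() / sumw
            mu_new = m_mean + math.sqrt(s2e / sumw) * np.random.normal()
            dmu = mu_new - mu
            for i in range(n):
                ew[i] -= w[i] * dmu
            mu = mu_new

        if not fix_s2e:
            ssr = 0.0
            for i in range(n):
                ssr += ew[i] * ew[i] / w[i]
            chi2 = 2.0 * np.random.gamma(0.5 * (n + nu_e), 1.0)
            s2e = (nu_e * scale_e + ssr) / chi2

        if not fix_s20:
            ssb = 0.0
            n_slab = 0
            for j in range(p):
                if gamma[j] == 1:
                    ssb += beta[j] * beta[j] / kappa
                    n_slab += 1
                else:
                    ssb += beta[j] * beta[j]
            if mh_sigma0:
                # random-walk MH on log sigma2_0; target = beta likelihood x
                # scaled-inv-chi2 prior (plus log-scale Jacobian)
                prop = s20 * math.exp(mh_step * np.random.normal())
                lt_prop = (
                    -0.5 * (p * math.log(prop) + ssb / prop)
                    - (1.0 + 0.5 * nu_b) * math.log(prop)
                    - 0.5 * nu_b * scale_b / prop
                )
                lt_cur = (
                    -0.5 * (p * math.log(s20) + ssb / s20)
                    - (1.0 + 0.5 * nu_b) * math.log(s20)
                    - 0.5 * nu_b * scale_b / s20
                )
                log_acc = lt_prop - lt_cur + math.log(prop) - math.log(s20)
                if math.log(np.random.random() + 1e-300) < log_acc:
                    s20 = prop
            else:
                chi2 = 2.0 * np.random.gamma(0.5 * (p + nu_b), 1.0)
                s20 = (nu_b * scale_b + ssb) / chi2

        if it >= burn_in:
            kept += 1
            for j in range(p):
                incl[j] += gamma[j]
                bsum[j] += beta[j]
                bsumsq[j] += beta[j] * beta[j]
            if (it - burn_in) % thin == 0 and stored < n_store:
                ssr = 0.0
                for i in range(n):
                    ssr += ew[i] * ew[i] / w[i]
                dev_trace[stored] = n * math.log(2.0 * math.pi * s2e) - sumlogw + ssr / s2e
                s20_trace[stored] = s20
                s2e_trace[stored] = s2e
                for j in range(p):
                    beta_samples[stored, j] = beta[j]
                    gamma_samples[stored, j] = gamma[j]
                stored += 1

    ssr = 0.0
    for i in range(n):
        ssr += ew[i] * ew[i] / w[i]
    dev_final = n * math.log(2.0 * math.pi * s2e) - sumlogw + ssr / s2e

    return (
        incl,
        bsum,
        bsumsq,
        dev_trace,
        s20_trace,
        s2e_trace,
        beta_samples,
        gamma_samples,
        kept,
        mu,
        beta,
        gamma,
        s20,
        s2e,
        dev_final,
    )


@njit(cache=False, fastmath=True)
def _grouped_ridge_kernel(
    X,  # (n, p) float32, Fortran order
    y,
    w,
    xtwx,
    group_of,  # (p,) int64 group index per SNP
    n_groups,
    n_iter,
    burn_in,
    thin,
    nu_e,
    scale_e,
    nu_g,
    scale_g,
    seed,
):
    """Gibbs sampler for the grouped re-estimation model: every SNP keeps a
    nonzero effect drawn from its group's variance component (no selection),
    so group variances are not shrunk by an inclusion prior."""
    np.random.seed(seed)
    n, p = X.shape
    n_store = (n_iter - burn_in) // thin

    beta = np.zeros(p)
    sumw = w.sum()
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= sumw
    ew = np.empty(n)
    for i in range(n):
        ew[i] = w[i] * (y[i] - mu)
    s2e = scale_e
    s2g = np.full(n_groups, scale_g)
    p_g = np.zeros(n_groups)
    for j in range(p):
        p_g[group_of[j]] += 1.0

    # per-sample variance shares: Var(X_g b_g) / Var(X b)
    group_shares = np.zeros((n_store, n_groups))
    total_var = np.zeros(n_store)
    stored = 0

    g_vals = np.zeros((n, n_groups))
    for it in range(n_iter):
        for j in range(p):
            bj = beta[j]
            r = 0.0
            for i in range(n):
                r += X[i, j] * ew[i]
            r += xtwx[j] * bj
            rhs = r / s2e
            prec = xtwx[j] / s2e
            V = 1.0 / (prec + 1.0 / s2g[group_of[j]])
            bnew = V * rhs + math.sqrt(V) * np.random.normal()
            beta[j] = bnew
            delta = bnew - bj
            if delta != 0.0:
                for i in range(n):
                    ew[i] -= w[i] * X[i, j] * delta

        m_mean = mu + ew.sum() / sumw
        mu_new = m_mean + math.sqrt(s2e / sumw) * np.random.normal()
        dmu = mu_new - mu
        for i in range(n):
            ew[i] -= w[i] * dmu
        mu = mu_new

        ssr = 0.0
        for i in range(n):
            ssr += ew[i] * ew[i] / w[i]
        chi2 = 2.0 * np.random.gamma(0.5 * (n + nu_e), 1.0)
        s2e = (nu_e * scale_e + ssr) / chi2

        for g in range(n_groups):
            ssg = 0.0
            for j in range(p):
                if group_of[j] == g:
                    ssg += beta[j] * beta[j]
            chi2 = 2.0 * np.random.gamma(0.5 * (p_g[g] + nu_g), 1.0)
            s2g[g] = (nu_g * scale_g + ssg) / chi2

        if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_store:
            for i in range(n):
                for g in range(n_groups):
                    g_vals[i, g] = 0.0
            for j in range(p):
                g = group_of[j]
                for i in range(n):
                    g_vals[i, g] += X[i, j] * beta[j]
            tot = np.zeros(n)
            for g in range(n_groups):
                for i in range(n):
                    tot[i] += g_vals[i, g]
            var_tot = np.var(tot)
            total_var[stored] = var_tot
            for g in range(n_groups):
                var_g = np.var(g_vals[:, g])
                group_shares[stored, g] = var_g / var_tot if var_tot > 0 else 0.0
            stored += 1

    return group_shares, total_var


def grouped_variance_shares(
    debv_vector: np.ndarray,
    dosage_matrix: np.ndarray,
    weights: np.ndarray,
    group_of: np.ndarray,
    n_groups: int,
    n_iter: int = 5_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Posterior mean share of genetic variance per SNP group (two-pass).

    Fits the grouped re-estimation model — every SNP effect drawn from its
    group's own variance component, no inclusion indicator — and returns
    the across-sample mean of Var(X_g beta_g) / Var(X beta) per group.
    Used to quantify the variance explained by called QTL regions without
    the shrinkage the selection prior puts on inclusion-averaged effects.
    """
    y = np.ascontiguousarray(np.asarray(debv_vector, dtype=np.float64).ravel())
    X = np.asarray(dosage_matrix, dtype=np.float64)
    w = np.ascontiguousarray(np.asarray(weights, dtype=np.float64).ravel())
    group_of = np.ascontiguousarray(np.asarray(group_of, dtype=np.int64))
    n, p = X.shape
    if group_of.size != p or group_of.max() >= n_groups or group_of.min() < 0:
        raise ValueError("group_of must assign each SNP a group in [0, n_groups)")
    var_y = float(np.var(y)) or 1.0
    vx = X.var(axis=0)
    scale_g = 0.5 * var_y / max(float(vx.sum()), 1e-12)
    X32 = np.asfortranarray(X, dtype=np.float32)
    xtwx = np.array([float(w @ (X[:, j] ** 2)) for j in range(p)])
    shares, _ = _grouped_ridge_kernel(
        X32, y, w, xtwx, group_of, n_groups, n_iter, burn_in, thin,
        4.0, 0.5 * var_y, 4.0, scale_g, seed,
    )
    return shares.mean(axis=0)


def run_chain(
    debv_vector: np.ndarray,
    dosage_matrix: np.ndarray,
    weights: np.ndarray,
    config: BVSConfig | None = None,
    diagnostics: bool = True,
) -> PosteriorSummary:
    """Fit the weighted spike-and-slab model by MCMC.

    Runs ``config.n_chains`` independent chains from one root seed and
    pools post-burn-in inclusion frequencies and effect summaries; the
    per-chain deviance traces feed the Gelman-Rubin diagnostic.

    Parameters
    ----------
    debv_vector : response (deregressed EBVs), length n.
    dosage_matrix : complete post-QC dosage matrix, n x p.
    weights : positive residual weights, length n.
    config : :class:`BVSConfig`; defaults to the full-length profile.
    diagnostics : require >= 2 chains and compute the PSRF on deviance.
    """
    cfg = config or BVSConfig()
    y = np.ascontiguousarray(np.asarray(debv_vector, dtype=np.float64).ravel())
    X = np.asarray(dosage_matrix, dtype=np.float64)
    w = np.ascontiguousarray(np.asarray(weights, dtype=np.float64).ravel())
    if X.ndim != 2 or X.shape[0] != y.size or w.size != y.size:
        raise ValueError(
            f"dimension mismatch: y {y.size}, X {X.shape}, weights {w.size}"
        )
    if not (np.isfinite(y).all() and np.isfinite(X).all() and np.isfinite(w).all()):
        raise ValueError("inputs must be finite (run QC/imputation first)")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if diagnostics and cfg.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")

    n, p = X.shape
    var_y = float(np.var(y)) if n > 1 else 1.0
    var_y = var_y if var_y > 0 else 1.0
    scale_e = cfg.prior_scale_e if cfg.prior_scale_e is not None else 0.5 * var_y
    if cfg.prior_scale_beta is not None:
        scale_b = cfg.prior_scale_beta
    else:
        vx = X.var(axis=0)
        denom = float(vx.sum()) * ((1.0 - cfg.pi1) + cfg.pi1 * cfg.kappa)
        scale_b = 0.5 * var_y / denom if denom > 0 else 1e-4
    s2e_init = cfg.fix_sigma2_e if cfg.fix_sigma2_e is not None else 0.5 * var_y
    s20_init = cfg.fix_sigma2_0 if cfg.fix_sigma2_0 is not None else scale_b

    X32 = np.asfortranarray(X, dtype=np.float32)
    xtwx = np.array([float(w @ (X[:, j] ** 2)) for j in range(p)])

    root = np.random.default_rng(cfg.seed)
    chain_seeds = tuple(int(s) for s in root.integers(0, 2**31 - 1, size=cfg.n_chains))

    incl = np.zeros(p)
    bsum = np.zeros(p)
    bsumsq = np.zeros(p)
    dev_traces = []
    s20_traces = []
    s2e_traces = []
    b_samples = []
    g_samples = []
    states: list[ChainState] = []
    final_devs: list[float] = []
    kept_total = 0
    for cs in chain_seeds:
        out = _bvs_kernel(
            X32,
            y,
            w,
            xtwx,
            cfg.pi1,
            cfg.kappa,
            cfg.n_iter,
            cfg.burn_in,
            cfg.thin,
            cfg.prior_df_e,
            scale_e,
            cfg.prior_df_beta,
            scale_b,
            cfg.sample_mu,
            cfg.fix_sigma2_e is not None,
            s2e_init,
            cfg.fix_sigma2_0 is not None,
            s20_init,
            cfg.mh_sigma0,
            cfg.mh_step,
            cs,
        )
        (
            ic, bs, bq, dev, s20t, s2et, bsam, gsam, kept,
            mu_f, beta_f, gamma_f, s20_f, s2e_f, dev_f,
        ) = out
        incl += ic
        bsum += bs
        bsumsq += bq
        kept_total += kept
        dev_traces.append(dev)
        s20_traces.append(s20t)
        s2e_traces.append(s2et)
        b_samples.append(bsam)
        g_samples.append(gsam)
        final_devs.append(float(dev_f))
        states.append(
            ChainState(
                mu=float(mu_f),
                beta=np.asarray(beta_f),
                gamma=np.asarray(gamma_f),
                sigma2_0=float(s20_f),
                sigma2_e=float(s2e_f),
                kappa=cfg.kappa,
            )
        )

    p_hat = incl / kept_total
    beta_mean = bsum / kept_total
    beta_var = np.maximum(bsumsq / kept_total - beta_mean**2, 0.0)
    dev_arr = np.vstack(dev_traces)
    psrf = gelman_rubin(dev_arr) if diagnostics and cfg.n_chains >= 2 else None

    return PosteriorSummary(
        p_hat=p_hat,
        beta_mean=beta_mean,
        beta_sd=np.sqrt(beta_var),
        deviance_traces=dev_arr,
        sigma2_0_traces=np.vstack(s20_traces),
        sigma2_e_traces=np.vstack(s2e_traces),
        beta_samples=np.vstack(b_samples),
        gamma_samples=np.vstack(g_samples),
        n_kept=kept_total,
        gelman_rubin_deviance=psrf,
        final_deviances=tuple(final_devs),
        final_states=states,
        config=replace(cfg),
        chain_seeds=chain_seeds,
    )


def compute_deviance(
    state: ChainState,
    debv_vector: np.ndarray,
    dosage_matrix: np.ndarray,
    weights: np.ndarray,
) -> float:
    """-2 x weighted Gaussian log-likelihood at a sampler state.

    D = sum_i [ log(2 pi sigma2_e / w_i) + w_i e_i^2 / sigma2_e ] with
    e = y - mu - X beta, evaluated from scratch (the oracle for the
    incrementally maintained residuals inside the kernel).
    """
    y = np.asarray(debv_vector, dtype=float).ravel()
    X = np.asarray(dosage_matrix, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    e = y - state.mu - X @ state.beta
    return float(
        np.sum(np.log(2.0 * np.pi * state.sigma2_e / w) + w * e**2 / state.sigma2_e)
    )


def gelman_rubin(traces_per_chain: np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 equal-length traces.

    Classic between/within-variance form: with m chains of length n,
    W = mean within-chain variance, B/n = variance of chain means,
    V = (n-1)/n W + B/n and PSRF = sqrt(V / W), floored at 1 so that
    identical chains report exactly 1.
    """
    traces = np.asarray(traces_per_chain, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    m, n = traces.shape
    if n < 2:
        raise ValueError("traces must have length >= 2")
    chain_means = traces.mean(axis=1)
    W = float(np.mean(np.var(traces, axis=1, ddof=1)))
    B_over_n = float(np.var(chain_means, ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    v_hat = (n - 1) / n * W + B_over_n
    return float(max(np.sqrt(v_hat / W), 1.0))


def enumerate_inclusion_probabilities(
    debv_vector: np.ndarray,
    dosage_matrix: np.ndarray,
    weights: np.ndarray,
    pi1: float,
    kappa: float,
    sigma2_0: float,
    sigma2_e: float,
    mu: float = 0.0,
) -> np.ndarray:
    """Exact posterior inclusion probabilities by enumerating all 2^p models.

    For fixed variance components and intercept the marginal likelihood of
    each gamma configuration is a zero-mean Gaussian with covariance
    X D_gamma X' + sigma2_e W^-1, so the posterior over configurations -
    and hence each SNP's inclusion probability - is available in closed
    form.  Feasible only for small p; serves as the ground truth the Gibbs
    sampler is checked against.
    """
    from itertools import product

    from scipy.stats import multivariate_normal

    y = np.asarray(debv_vector, dtype=float).ravel() - mu
    X = np.asarray(dosage_matrix, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    n, p = X.shape
    if p > 16:
        raise ValueError("enumeration is limited to p <= 16")
    base_cov = sigma2_e * np.diag(1.0 / w)
    log_post = []
    configs = list(product([0, 1], repeat=p))
    for gamma in configs:
        d = np.where(np.array(gamma) == 1, kappa * sigma2_0, sigma2_0)
        cov = base_cov + (X * d) @ X.T
        ll = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        lp = np.sum(np.where(np.array(gamma) == 1, np.log(pi1), np.log(1.0 - pi1)))
        log_post.append(ll + lp)
    log_post = np.array(log_post)
    post = np.exp(log_post - log_post.max())
    post /= post.sum()
    p_incl = np.zeros(p)
    for prob, gamma in zip(post, configs):
        p_incl += prob * np.array(gamma)
    return p_incl
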