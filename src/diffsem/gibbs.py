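"""Gibbs sampler for the hierarchical fused shrinkage prior.

The integrated per-gene regression y = W beta + e (length-n response,
2 p_i coefficients) is given a scale-mixture-of-normals prior that mimics
a fused lasso penalty: each coefficient beta_j carries a local variance
tau_j^2 ~ Exp(psi_1j), and each cross-condition difference
beta_{p_i+k} - beta_k carries a fusion variance omega_k^2 ~ Exp(psi_2k).
Conditionally on the scales, beta is multivariate normal with precision

    Sigma_beta^-1 = diag(1/tau_j^2) + fusion terms,

a matrix whose only off-diagonal entries couple each coefficient with its
counterpart in the other condition.  Adaptive per-coordinate Gamma(a, b)
hyperpriors on the psi's play the role of the lasso tuning parameters.
The error variance sigma^2 gets an Inverse-Gamma(nu0/2, eta0/2) prior.

All full conditionals are standard: a multivariate normal for beta, an
inverse gamma for sigma^2, inverse-Gaussian draws for the reciprocal
scales 1/tau^2 and 1/omega^2, and Gamma draws for the psi's.  Convergence
is monitored with the potential scale reduction factor (R-hat) across
independent chains; sampling stops once every monitored scalar satisfies
R-hat < 1.1, after which a fixed number of posterior draws is collected
and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from diffsem.reparam import (
    SubproblemDesign,
    build_subproblem,
    extract_network_column,
    insert_structural_zero,
)
from diffsem.simulate import PairedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "GibbsState",
    "PosteriorSamples",
    "NetworkPosterior",
    "build_sigma_beta_inv",
    "sample_inverse_gaussian",
    "sample_beta",
    "sample_sigma2",
    "sample_scales",
    "sample_psi",
    "gibbs_sweep",
    "gibbs_run",
    "gelman_rubin",
    "infer_all_genes",
]

# reciprocal scales are confined to this range to keep the chain finite
_SCALE_MIN = 1e-10
_SCALE_MAX = 1e10
_CHOL_JITTER = 1e-8


@dataclass
class HyperParams:
    """Prior and sampler settings.

    a, b : shape/rate of the Gamma hyperprior on the adaptive tuning
        parameters psi (essentially noninformative by default).
    nu0, eta0 : Inverse-Gamma hyperparameters for the error variance.
    n_chains : independent chains used for the R-hat diagnostic (>= 2).
    check_interval : sweeps between convergence checks.
    max_iter : per-chain sweep budget before giving up on convergence.
    post_draws : per-chain draws collected after convergence.
    rhat_threshold : convergence once max R-hat falls below this.
    """

    a: float = 1.0
    b: float = 0.1
    nu0: float = 1.0
    eta0: float = 1.0
    n_chains: int = 3
    check_interval: int = 500
    max_iter: int = 20000
    post_draws: int = 1000
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.nu0, self.eta0) <= 0:
            raise ValueError("a, b, nu0, eta0 must all be positive")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are needed for R-hat")


@dataclass
class GibbsState:
    """All latent variables of one chain at one sweep."""

    beta: np.ndarray  # 2 p_i coefficients
    sigma2: float
    tau2: np.ndarray  # 2 p_i local scales
    omega2: np.ndarray  # p_i fusion scales
    psi1: np.ndarray  # 2 p_i adaptive sparsity rates
    psi2: np.ndarray  # p_i adaptive fusion rates


@dataclass
class PosteriorSamples:
    """Pooled post-convergence draws and summaries for one gene."""

    beta: np.ndarray  # (n_chains * post_draws, 2 p_i)
    sigma2: np.ndarray
    rhat: np.ndarray  # per beta coordinate, then sigma2
    converged: bool
    beta_mean: np.ndarray
    beta_ci_low: np.ndarray
    beta_ci_high: np.ndarray
    n_sweeps: int


@dataclass
class NetworkPosterior:
    """Posterior-mean networks for both conditions with 95% equal-tailed
    credible intervals, plus the raw per-gene samples."""

    B1: np.ndarray
    B2: np.ndarray
    ci_low1: np.ndarray
    ci_high1: np.ndarray
    ci_low2: np.ndarray
    ci_high2: np.ndarray
    per_gene: list[PosteriorSamples]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.per_gene if s is not None)


def build_sigma_beta_inv(tau2: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """Prior precision of beta given the scales.

    Diagonal entry j is 1/tau_j^2 + 1/omega_m^2 with m = j mod p_i, and the
    only off-diagonals are -1/omega_k^2 at the cross-condition pairs
    (k, p_i + k).  Symmetric positive definite for any positive inputs.
    """
    tau2 = np.asarray(tau2, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    m = len(omega2)
    if len(tau2) != 2 * m:
        raise ValueError(f"tau2 has length {len(tau2)}, expected {2 * m}")
    if np.any(tau2 <= 0) or np.any(omega2 <= 0):
        raise ValueError("all scale parameters must be strictly positive")
    inv_omega = 1.0 / omega2
    prec = np.diag(1.0 / tau2 + np.tile(inv_omega, 2))
    idx = np.arange(m)
    prec[idx, idx + m] = -inv_omega
    prec[idx + m, idx] = -inv_omega
    return prec


def sample_inverse_gaussian(
    mu: np.ndarray | float, lam: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray | float:
    """Draw from the inverse-Gaussian (Wald) distribution with mean ``mu``
    and shape ``lam``, via the chi-square transformation with the uniform
    acceptance correction of Michael, Schucany & Haas."""
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(mu <= 0) or np.any(lam <= 0):
        raise ValueError("inverse-Gaussian parameters must be positive")
    return rng.wald(mu, lam)


def _chol_with_jitter(A: np.ndarray):
    try:
        return cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("Cholesky failed; retrying with %.0e jitter", _CHOL_JITTER)
        return cho_factor(A + _CHOL_JITTER * np.eye(A.shape[0]), lower=True)


def sample_beta(
    WtW: np.ndarray,
    Wty: np.ndarray,
    prec: np.ndarray,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact multivariate-normal draw of beta from its full conditional
    N(A^-1 W'y, sigma^2 A^-1) with A = W'W + Sigma_beta^-1.

    Uses a Cholesky factorization of A; no explicit inverse is formed.
    """
    A = WtW + prec
    c, low = _chol_with_jitter(A)
    mean = cho_solve((c, low), Wty)
    z = rng.standard_normal(len(Wty))
    # A = L L'  =>  cov = sigma2 A^-1 = sigma2 L'^-1 L^-1; draw L'^-1 z
    dev = solve_triangular(c, z, lower=True, trans="T")
    return mean + np.sqrt(sigma2) * dev


def sample_sigma2(
    resid_ss: float,
    prior_quad: float,
    n: int,
    n_kernels: int,
    hp: HyperParams,
    rng: np.random.Generator,
) -> float:
    """Inverse-gamma draw for the error variance: shape nu/2, scale eta/2
    with nu = n + n_kernels + nu0 and eta = ||y - W beta||^2 +
    beta' Sigma_beta^-1 beta + eta0.

    ``n_kernels`` counts every Gaussian kernel the scale-mixture prior
    ties to sigma^2: one per coefficient (2 p_i local terms) plus one per
    cross-condition difference (p_i fusion terms), i.e. 3 p_i in total.
    Together with the n likelihood terms and the nu0 prior
    pseudo-observations this is the exact conjugate update for the
    product-form fused prior (see docs/methods.md for the degree-of-freedom
    accounting).
    """
    nu = n + n_kernels + hp.nu0
    eta = resid_ss + prior_quad + hp.eta0
    if eta <= 0:
        raise ValueError("inverse-gamma scale must be positive")
    return eta / 2.0 / rng.gamma(nu / 2.0)


def sample_scales(
    beta: np.ndarray,
    sigma2: float,
    psi1: np.ndarray,
    psi2: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-Gaussian draws for the reciprocal local and fusion scales.

    1/tau_j^2 has conditional mean sqrt(2 psi_1j sigma^2 / beta_j^2); when
    a coefficient (or difference) is numerically zero the mean is capped at
    1e10 — the strong-shrinkage regime — instead of overflowing.
    """
    m = len(psi2)

    def _draw(psi: np.ndarray, sq: np.ndarray) -> np.ndarray:
        mu = np.sqrt(2.0 * psi * sigma2 / np.maximum(sq, 1e-300))
        mu = np.minimum(mu, _SCALE_MAX)
        mu = np.maximum(mu, _SCALE_MIN)
        inv = sample_inverse_gaussian(mu, 2.0 * psi, rng)
        return 1.0 / np.clip(inv, _SCALE_MIN, _SCALE_MAX)

    tau2 = _draw(psi1, beta**2)
    diff = beta[m:] - beta[:m]
    omega2 = _draw(psi2, diff**2)
    return tau2, omega2


def sample_psi(
    tau2: np.ndarray,
    omega2: np.ndarray,
    hp: HyperParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Gamma updates of the adaptive tuning parameters:
    psi_1j ~ Gamma(a + 1, rate b + tau_j^2) and likewise for psi_2k with
    omega_k^2 (rate parameterization)."""
    psi1 = rng.gamma(hp.a + 1.0, 1.0 / (hp.b + tau2))
    psi2 = rng.gamma(hp.a + 1.0, 1.0 / (hp.b + omega2))
    return psi1, psi2


class _DesignCache:
    """Precomputed products of a fixed design, shared across sweeps."""

    def __init__(self, design: SubproblemDesign):
        self.W = design.W
        self.y = design.y
        self.WtW = design.W.T @ design.W
        self.Wty = design.W.T @ design.y
        self.n = design.n
        self.dim = design.W.shape[1]
        self.p_i = design.p_i

    def refresh_y(self, y: np.ndarray) -> None:
        self.y = y
        self.Wty = self.W.T @ y


def gibbs_sweep(
    state: GibbsState, cache: _DesignCache, hp: HyperParams, rng: np.random.Generator
) -> GibbsState:
    """One full sweep through the conditionals, in the order beta, sigma^2,
    scales, psi.  Mutates and returns ``state``."""
    prec = build_sigma_beta_inv(state.tau2, state.omega2)
    state.beta = sample_beta(cache.WtW, cache.Wty, prec, state.sigma2, rng)
    resid = cache.y - cache.W @ state.beta
    prior_quad = float(state.beta @ prec @ state.beta)
    state.sigma2 = sample_sigma2(
        float(resid @ resid), prior_quad, cache.n, cache.dim + cache.p_i, hp, rng
    )
    state.tau2, state.omega2 = sample_scales(
        state.beta, state.sigma2, state.psi1, state.psi2, rng
    )
    state.psi1, state.psi2 = sample_psi(state.tau2, state.omega2, hp, rng)
    return state


def _init_state(
    cache: _DesignCache, hp: HyperParams, chain: int, rng: np.random.Generator
) -> GibbsState:
    """Overdispersed initializations: chain 0 starts at beta = 0, the
    others at jittered ridge estimates."""
    dim = cache.dim
    if chain == 0:
        beta = np.zeros(dim)
    else:
        ridge = np.linalg.solve(cache.WtW + np.eye(dim), cache.Wty)
        beta = ridge + 0.1 * chain * rng.standard_normal(dim)
    sigma2 = max(float(np.var(cache.y)), 1e-6)
    m = cache.p_i
    return GibbsState(
        beta=beta,
        sigma2=sigma2,
        tau2=np.ones(dim),
        omega2=np.ones(m),
        psi1=np.ones(dim),
        psi2=np.ones(m),
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor R-hat.

    ``chains`` is (n_chains, n_draws).  Returns 1.0 if all draws are
    identical, +inf if the chains are internally constant but disagree.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    m, n = chains.shape
    if n < 4:
        raise ValueError("chains must have length >= 4")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def gibbs_run(
    design: SubproblemDesign, hp: HyperParams, rng: np.random.Generator
) -> PosteriorSamples:
    """Run the multi-chain sampler for one gene until R-hat convergence.

    Every ``check_interval`` sweeps, R-hat is computed for each beta
    coordinate and for sigma^2 over the second half of each chain.  Once
    all fall below ``rhat_threshold``, ``post_draws`` further sweeps per
    chain are pooled into the returned posterior summaries.  If
    ``max_iter`` is exhausted first, the last draws are returned with
    ``converged=False``.
    """
    if design.n <= 3:
        raise ValueError(
            "need n > 3 samples for geometric ergodicity of the sampler"
        )
    cache = _DesignCache(design)
    dim = cache.dim
    chain_rngs = rng.spawn(hp.n_chains)
    states = [
        _init_state(cache, hp, c, chain_rngs[c]) for c in range(hp.n_chains)
    ]
    beta_hist = [np.empty((hp.max_iter, dim)) for _ in range(hp.n_chains)]
    sig_hist = [np.empty(hp.max_iter) for _ in range(hp.n_chains)]

    t = 0
    converged = False
    rhat = np.full(dim + 1, np.inf)
    while t < hp.max_iter:
        chunk = min(hp.check_interval, hp.max_iter - t)
        for c in range(hp.n_chains):
            st, bh, sh, crng = states[c], beta_hist[c], sig_hist[c], chain_rngs[c]
            for s in range(t, t + chunk):
                gibbs_sweep(st, cache, hp, crng)
                bh[s] = st.beta
                sh[s] = st.sigma2
        t += chunk
        half = t // 2
        if t - half < 4:
            continue
        beta_block = np.stack([bh[half:t] for bh in beta_hist])  # (m, n, dim)
        rhat_beta = np.array(
            [gelman_rubin(beta_block[:, :, j]) for j in range(dim)]
        )
        rhat_sig = gelman_rubin(np.stack([sh[half:t] for sh in sig_hist]))
        rhat = np.append(rhat_beta, rhat_sig)
        if np.max(rhat) < hp.rhat_threshold:
            converged = True
            break
    if not converged:
        logger.warning(
            "gene %d: sampler not converged after %d sweeps (max R-hat %.3f)",
            design.gene_index,
            t,
            float(np.max(rhat)),
        )

    post_beta = np.empty((hp.n_chains, hp.post_draws, dim))
    post_sig = np.empty((hp.n_chains, hp.post_draws))
    for c in range(hp.n_chains):
        st, crng = states[c], chain_rngs[c]
        for s in range(hp.post_draws):
            gibbs_sweep(st, cache, hp, crng)
            post_beta[c, s] = st.beta
            post_sig[c, s] = st.sigma2
    pooled = post_beta.reshape(-1, dim)
    pooled_sig = post_sig.reshape(-1)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    return PosteriorSamples(
        beta=pooled,
        sigma2=pooled_sig,
        rhat=rhat,
        converged=converged,
        beta_mean=pooled.mean(axis=0),
        beta_ci_low=lo,
        beta_ci_high=hi,
        n_sweeps=t + hp.post_draws,
    )


def infer_all_genes(
    data: PairedDataset,
    hp: HyperParams | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkPosterior:
    """Infer both networks by running the sampler on every gene's
    integrated regression.

    The per-gene subproblems are statistically independent; each gets its
    own spawned RNG stream so results do not depend on execution order.
    Failures are recorded per gene (that column is left NaN) and the
    remaining genes complete.
    """
    if hp is None:
        hp = HyperParams()
    if rng is None:
        rng = np.random.default_rng()
    p = data.p
    gene_rngs = rng.spawn(p)
    B1 = np.full((p, p), np.nan)
    B2 = np.full((p, p), np.nan)
    lo1 = np.full((p, p), np.nan)
    hi1 = np.full((p, p), np.nan)
    lo2 = np.full((p, p), np.nan)
    hi2 = np.full((p, p), np.nan)
    for M in (B1, B2, lo1, hi1, lo2, hi2):
        np.fill_diagonal(M, 0.0)
    per_gene: list[PosteriorSamples | None] = [None] * p
    failures: dict[int, str] = {}
    for i in range(p):
        try:
            design = build_subproblem(data, i)
            samples = gibbs_run(design, hp, gene_rngs[i])
        except Exception as exc:  # noqa: BLE001 - per-gene isolation
            logger.error("gene %d failed: %s", i, exc)
            failures[i] = str(exc)
            continue
        per_gene[i] = samples
        q_i = design.q_i
        for vec, target in (
            (samples.beta_mean, (B1, B2)),
            (samples.beta_ci_low, (lo1, lo2)),
            (samples.beta_ci_high, (hi1, hi2)),
        ):
            b1, b2, _, _ = extract_network_column(vec, i, p, q_i)
            target[0][:, i] = insert_structural_zero(b1, i)
            target[1][:, i] = insert_structural_zero(b2, i)
    return NetworkPosterior(
        B1=B1,
        B2=B2,
        ci_low1=lo1,
        ci_high1=hi1,
        ci_low2=lo2,
        ci_high2=hi2,
        per_gene=per_gene,
        failures=failures,
    )
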