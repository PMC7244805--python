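"""Bayesian isolation-by-environment vs isolation-by-distance model.

Allele frequencies at unlinked loci are modelled as a spatially correlated
Gaussian process across populations: locus l has a latent frequency vector
f_l ~ N(mu_l * 1, mu_l (1 - mu_l) * Omega) truncated to (0,1)^K, and the
observed reference-allele counts are binomial draws x_kl ~ Bin(n_kl, f_kl).
The covariance decays with both geographic and environmental distance,

    Omega_ij = (1/alpha_0) * exp(-(alpha_D D*_ij + alpha_E E*_ij)^alpha_2)
               + delta * 1[i == j],

with D*, E* the distance matrices standardized by their standard
deviations.  The ratio alpha_E / alpha_D — back-transformed to raw distance
units — measures the contribution of environment relative to geography to
genetic differentiation.

Parameters are estimated by blockwise Metropolis–Hastings with step sizes
auto-tuned during an adaptation phase (targeting acceptance rates in the
20–70% band) and frozen afterwards.  The literature-scale schedule is 2 million
iterations thinned every 250; the default here is a desk-scale 100,000.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .datatypes import AlleleCountTable, DistanceMatrices

__all__ = [
    "IBEModel",
    "IBEResults",
    "IBEPriors",
    "build_covariance",
    "model_log_posterior",
    "run_mcmc",
    "summarize_ratio",
]


@dataclass
class IBEPriors:
    """Weakly informative priors for the covariance parameters.

    alpha_0 ~ half-normal(scale), alpha_D and alpha_E ~ Exponential(rate),
    alpha_2 ~ Uniform(0, 1].
    """

    alpha0_scale: float = 10.0
    decay_rate: float = 1.0


def build_covariance(
    params: dict | np.ndarray, dist: DistanceMatrices, delta: float = 1e-6
) -> np.ndarray:
    """Distance-decay covariance Omega; raises if not positive definite.

    ``params`` is (alpha_0, alpha_D, alpha_E, alpha_2) or a dict with those
    keys.  Distances enter standardized (divided by their SDs).
    """
    a0, aD, aE, a2 = _unpack_params(params)
    if a0 <= 0:
        raise ValueError("alpha_0 must be positive")
    if aD < 0 or aE < 0:
        raise ValueError("decay parameters must be non-negative")
    if not (0 < a2 <= 1):
        raise ValueError("alpha_2 must lie in (0, 1]")
    arg = aD * dist.D_std + aE * dist.E_std
    omega = (1.0 / a0) * np.exp(-(arg**a2)) + delta * np.eye(dist.n)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite for (alpha_0={a0}, alpha_D={aD}, "
            f"alpha_E={aE}, alpha_2={a2}, delta={delta})"
        ) from err
    return omega


def _unpack_params(params) -> tuple[float, float, float, float]:
    if isinstance(params, dict):
        return (
            float(params["alpha_0"]),
            float(params["alpha_D"]),
            float(params["alpha_E"]),
            float(params["alpha_2"]),
        )
    a0, aD, aE, a2 = np.asarray(params, dtype=float)
    return float(a0), float(aD), float(aE), float(a2)


def log_prior(params, priors: IBEPriors = IBEPriors()) -> float:
    """Log prior density of the covariance parameters (with constants)."""
    a0, aD, aE, a2 = _unpack_params(params)
    if a0 <= 0 or aD < 0 or aE < 0 or not (0 < a2 <= 1):
        return -np.inf
    lp = stats.halfnorm.logpdf(a0, scale=priors.alpha0_scale)
    lp += stats.expon.logpdf(aD, scale=1.0 / priors.decay_rate)
    lp += stats.expon.logpdf(aE, scale=1.0 / priors.decay_rate)
    return float(lp)  # alpha_2 uniform on (0,1]: density 1


def model_log_posterior(
    params,
    latent_freqs: np.ndarray,
    locus_means: np.ndarray,
    counts: AlleleCountTable,
    dist: DistanceMatrices,
    delta: float = 1e-6,
    priors: IBEPriors = IBEPriors(),
) -> float:
    """Full log posterior density (up to the truncation normalizer).

    Sum over loci of the multivariate-normal log prior of f_l plus the
    binomial log likelihood of the counts, plus the parameter priors.
    Latents outside (0,1) return -inf (bound rejection stands in for formal
    truncation).
    """
    F = np.asarray(latent_freqs, dtype=float)
    mu = np.asarray(locus_means, dtype=float)
    K, L = F.shape
    if (F <= 0).any() or (F >= 1).any() or (mu <= 0).any() or (mu >= 1).any():
        return -np.inf
    lp = log_prior(params, priors)
    if not np.isfinite(lp) or L == 0:
        return float(lp)
    omega = build_covariance(params, dist, delta)
    chol = np.linalg.cholesky(omega)
    logdet = 2 * np.log(np.diag(chol)).sum()
    z = np.linalg.solve(chol, F - mu[None, :])
    q = (z**2).sum(axis=0)
    s = mu * (1 - mu)
    lp += float(np.sum(-0.5 * (K * np.log(2 * np.pi * s) + logdet + q / s)))
    lp += float(stats.binom.logpmf(counts.ref_count, counts.total_alleles, F).sum())
    return lp


# ---------------------------------------------------------------------------
# numba MCMC kernel

_LOG2PI = math.log(2 * math.pi)


@njit(cache=True)
def _cholesky_in_place(A, L):
    """Lower Cholesky of A into L; returns False if not positive definite."""
    K = A.shape[0]
    for i in range(K):
        for j in range(i + 1):
            s = A[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, K):
            L[i, j] = 0.0
    return True


@njit(cache=True)
def _invert_from_cholesky(L, out):
    """out = (L L')^{-1} given lower-triangular L."""
    K = L.shape[0]
    # invert L in place into out (lower triangular inverse)
    for i in range(K):
        for j in range(K):
            out[i, j] = 0.0
    for i in range(K):
        out[i, i] = 1.0 / L[i, i]
        for j in range(i):
            s = 0.0
            for m in range(j, i):
                s -= L[i, m] * out[m, j]
            out[i, j] = s / L[i, i]
    # out <- out' out  (upper-triangular product), done in place column-wise
    for j in range(K):
        for i in range(j, K):
            s = 0.0
            for m in range(i, K):
                s += out[m, i] * out[m, j]
            out[i, j] = s
    for j in range(K):
        for i in range(j):
            out[i, j] = out[j, i]
    return out


@njit(cache=True)
def _build_omega(a0, aD, aE, a2, Dstar, Estar, delta, omega):
    K = Dstar.shape[0]
    for i in range(K):
        for j in range(K):
            arg = aD * Dstar[i, j] + aE * Estar[i, j]
            v = math.exp(-(arg**a2)) / a0
            if i == j:
                v += delta
            omega[i, j] = v


@njit(cache=True)
def _log_prior_kernel(a0, aD, aE, a2, a0_scale, decay_rate):
    if a0 <= 0.0 or aD < 0.0 or aE < 0.0 or a2 <= 0.0 or a2 > 1.0:
        return -np.inf
    return -0.5 * (a0 / a0_scale) ** 2 - decay_rate * (aD + aE)


@njit(cache=True)
def _mvn_caches(Ominv, F, b, c):
    """b_l = 1' Ominv f_l and c_l = f_l' Ominv f_l for every locus."""
    K, L = F.shape
    for l in range(L):
        bl = 0.0
        cl = 0.0
        for i in range(K):
            gi = 0.0
            for j in range(K):
                gi += Ominv[i, j] * F[j, l]
            bl += gi
            cl += gi * F[i, l]
        b[l] = bl
        c[l] = cl


@njit(cache=True)
def _mvn_total(K, L, logdet, a_sum, b, c, mu):
    tot = 0.0
    for l in range(L):
        s = mu[l] * (1.0 - mu[l])
        q = c[l] - 2.0 * mu[l] * b[l] + mu[l] * mu[l] * a_sum
        tot += -0.5 * (K * (_LOG2PI + math.log(s)) + logdet + q / s)
    return tot


@njit(cache=True)
def _run_chain(
    x,
    ntot,
    Dstar,
    Estar,
    delta,
    iterations,
    thin,
    seed,
    adapt_end,
    likelihood_on,
    a0_scale,
    decay_rate,
    init,
    out_params,
    out_logpost,
    out_acc,
    out_steps,
):
    np.random.seed(seed)
    K, L = x.shape
    a0, aD, aE, a2 = init[0], init[1], init[2], init[3]

    # latent initialization at empirical frequencies, pulled off the bounds
    mu = np.empty(L)
    F = np.empty((K, L))
    for l in range(L):
        sx = 0.0
        sn = 0.0
        for k in range(K):
            sx += x[k, l]
            sn += ntot[k, l]
            F[k, l] = (x[k, l] + 1.0) / (ntot[k, l] + 2.0)
        mu[l] = min(max((sx + 1.0) / (sn + 2.0), 0.02), 0.98)

    omega = np.empty((K, K))
    cholL = np.empty((K, K))
    Ominv = np.empty((K, K))
    omega_p = np.empty((K, K))
    cholL_p = np.empty((K, K))
    Ominv_p = np.empty((K, K))
    b = np.empty(L)
    c = np.empty(L)
    b_p = np.empty(L)
    c_p = np.empty(L)
    binom = np.empty(L)
    fprop = np.empty(K)

    logdet = 0.0
    a_sum = 0.0
    mvn_tot = 0.0
    binom_tot = 0.0

    if likelihood_on:
        _build_omega(a0, aD, aE, a2, Dstar, Estar, delta, omega)
        ok = _cholesky_in_place(omega, cholL)
        if not ok:
            out_logpost[0] = np.nan
            return
        logdet = 0.0
        for i in range(K):
            logdet += 2.0 * math.log(cholL[i, i])
        _invert_from_cholesky(cholL, Ominv)
        a_sum = 0.0
        for i in range(K):
            for j in range(K):
                a_sum += Ominv[i, j]
        _mvn_caches(Ominv, F, b, c)
        mvn_tot = _mvn_total(K, L, logdet, a_sum, b, c, mu)
        binom_tot = 0.0
        for l in range(L):
            bl = 0.0
            for k in range(K):
                f = F[k, l]
                bl += x[k, l] * math.log(f) + (ntot[k, l] - x[k, l]) * math.log(1.0 - f)
            binom[l] = bl
            binom_tot += bl

    lprior = _log_prior_kernel(a0, aD, aE, a2, a0_scale, decay_rate)

    # step sizes (log-scale RW for alpha_0/alpha_D/alpha_E, raw for alpha_2)
    step_par = 0.3
    step_mu = 0.05
    step_f = 0.05
    acc_par = 0
    try_par = 0
    acc_mu = 0
    try_mu = 0
    acc_f = 0
    try_f = 0
    win_acc_par = 0
    win_try_par = 0
    win_acc_mu = 0
    win_try_mu = 0
    win_acc_f = 0
    win_try_f = 0

    sample_idx = 0
    for it in range(iterations):
        # --- parameter block (joint log-scale random walk) -----------------
        try_par += 1
        win_try_par += 1
        la0 = math.log(a0) + step_par * np.random.normal()
        laD = math.log(aD) + step_par * np.random.normal()
        laE = math.log(aE) + step_par * np.random.normal()
        a2_p = a2 + 0.5 * step_par * np.random.normal()
        a0_p = math.exp(la0)
        aD_p = math.exp(laD)
        aE_p = math.exp(laE)
        lprior_p = _log_prior_kernel(a0_p, aD_p, aE_p, a2_p, a0_scale, decay_rate)
        if np.isfinite(lprior_p):
            # Jacobian of the log transform for the three positive parameters
            log_ratio = (
                lprior_p
                - lprior
                + (la0 - math.log(a0))
                + (laD - math.log(aD))
                + (laE - math.log(aE))
            )
            ok = True
            mvn_tot_p = 0.0
            logdet_p = 0.0
            a_sum_p = 0.0
            if likelihood_on:
                _build_omega(a0_p, aD_p, aE_p, a2_p, Dstar, Estar, delta, omega_p)
                ok = _cholesky_in_place(omega_p, cholL_p)
                if ok:
                    logdet_p = 0.0
                    for i in range(K):
                        logdet_p += 2.0 * math.log(cholL_p[i, i])
                    _invert_from_cholesky(cholL_p, Ominv_p)
                    a_sum_p = 0.0
                    for i in range(K):
                        for j in range(K):
                            a_sum_p += Ominv_p[i, j]
                    _mvn_caches(Ominv_p, F, b_p, c_p)
                    mvn_tot_p = _mvn_total(K, L, logdet_p, a_sum_p, b_p, c_p, mu)
                    log_ratio += mvn_tot_p - mvn_tot
            if ok and math.log(np.random.random()) < log_ratio:
                a0, aD, aE, a2 = a0_p, aD_p, aE_p, a2_p
                lprior = lprior_p
                acc_par += 1
                win_acc_par += 1
                if likelihood_on:
                    logdet = logdet_p
                    a_sum = a_sum_p
                    mvn_tot = mvn_tot_p
                    for i in range(K):
                        for j in range(K):
                            Ominv[i, j] = Ominv_p[i, j]
                    for l in range(L):
                        b[l] = b_p[l]
                        c[l] = c_p[l]

        if likelihood_on:
            # --- locus-mean block ------------------------------------------
            for l in range(L):
                try_mu += 1
                win_try_mu += 1
                m_old = mu[l]
                m_new = m_old + step_mu * np.random.normal()
                if m_new <= 0.0 or m_new >= 1.0:
                    continue
                s_old = m_old * (1.0 - m_old)
                s_new = m_new * (1.0 - m_new)
                q_old = c[l] - 2.0 * m_old * b[l] + m_old * m_old * a_sum
                q_new = c[l] - 2.0 * m_new * b[l] + m_new * m_new * a_sum
                dlp = -0.5 * (
                    K * (math.log(s_new) - math.log(s_old)) + q_new / s_new - q_old / s_old
                )
                if math.log(np.random.random()) < dlp:
                    mu[l] = m_new
                    mvn_tot += dlp
                    acc_mu += 1
                    win_acc_mu += 1

            # --- latent-frequency block ------------------------------------
            for l in range(L):
                try_f += 1
                win_try_f += 1
                in_bounds = True
                for k in range(K):
                    f = F[k, l] + step_f * np.random.normal()
                    if f <= 0.0 or f >= 1.0:
                        in_bounds = False
                        break
                    fprop[k] = f
                if not in_bounds:
                    continue
                bl_new = 0.0
                cl_new = 0.0
                binom_new = 0.0
                for i in range(K):
                    gi = 0.0
                    for j in range(K):
                        gi += Ominv[i, j] * fprop[j]
                    bl_new += gi
                    cl_new += gi * fprop[i]
                    binom_new += x[i, l] * math.log(fprop[i]) + (
                        ntot[i, l] - x[i, l]
                    ) * math.log(1.0 - fprop[i])
                m = mu[l]
                s = m * (1.0 - m)
                q_old = c[l] - 2.0 * m * b[l] + m * m * a_sum
                q_new = cl_new - 2.0 * m * bl_new + m * m * a_sum
                dlp = -0.5 * (q_new - q_old) / s + binom_new - binom[l]
                if math.log(np.random.random()) < dlp:
                    for k in range(K):
                        F[k, l] = fprop[k]
                    mvn_tot += -0.5 * (q_new - q_old) / s
                    binom_tot += binom_new - binom[l]
                    b[l] = bl_new
                    c[l] = cl_new
                    binom[l] = binom_new
                    acc_f += 1
                    win_acc_f += 1

        # --- adaptation (frozen after adapt_end) ---------------------------
        if it < adapt_end and (it + 1) % 100 == 0:
            if win_try_par > 0:
                r = win_acc_par / win_try_par
                step_par *= math.exp(min(max(r - 0.35, -0.5), 0.5))
                step_par = min(max(step_par, 1e-3), 10.0)
            if win_try_mu > 0:
                r = win_acc_mu / win_try_mu
                step_mu *= math.exp(min(max(r - 0.35, -0.5), 0.5))
                step_mu = min(max(step_mu, 1e-4), 0.5)
            if win_try_f > 0:
                r = win_acc_f / win_try_f
                step_f *= math.exp(min(max(r - 0.35, -0.5), 0.5))
                step_f = min(max(step_f, 1e-4), 0.5)
            win_acc_par = win_try_par = 0
            win_acc_mu = win_try_mu = 0
            win_acc_f = win_try_f = 0

        if (it + 1) % thin == 0 and sample_idx < out_params.shape[0]:
            out_params[sample_idx, 0] = a0
            out_params[sample_idx, 1] = aD
            out_params[sample_idx, 2] = aE
            out_params[sample_idx, 3] = a2
            out_logpost[sample_idx] = lprior + mvn_tot + binom_tot
            sample_idx += 1

    out_acc[0] = acc_par / try_par if try_par > 0 else np.nan
    out_acc[1] = acc_mu / try_mu if try_mu > 0 else np.nan
    out_acc[2] = acc_f / try_f if try_f > 0 else np.nan
    out_steps[0] = step_par
    out_steps[1] = step_mu
    out_steps[2] = step_f


# ---------------------------------------------------------------------------
# public surface


@dataclass
class PosteriorTrace:
    """Thinned MCMC samples with per-block acceptance rates."""

    samples: pd.DataFrame
    acceptance_rates: dict[str, float]
    step_sizes: dict[str, float]
    iterations: int
    thin: int
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def write_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


def run_mcmc(
    counts: AlleleCountTable,
    dist: DistanceMatrices,
    iterations: int = 100_000,
    thin: int = 250,
    seed: int = 0,
    adapt_fraction: float = 0.25,
    delta: float = 1e-6,
    priors: IBEPriors = IBEPriors(),
    likelihood: bool = True,
    init: tuple[float, float, float, float] = (1.0, 0.5, 0.5, 0.5),
) -> PosteriorTrace:
    """Sample the IBE posterior by adaptive blockwise Metropolis–Hastings.

    With ``likelihood=False`` the data terms are dropped and the chain
    samples the parameter priors — a diagnostic mode for validating the
    sampler.
    """
    K = counts.n_populations
    if K < 3 and likelihood:
        raise ValueError("need at least 3 populations")
    if counts.n_loci < 50 and likelihood:
        warnings.warn("fewer than 50 loci: posterior will be diffuse")
    if dist.n != K:
        raise ValueError("distance matrices do not match the count table")
    if not (0 <= adapt_fraction < 1):
        raise ValueError("adapt_fraction must lie in [0, 1)")
    lp0 = log_prior(init, priors)
    if not np.isfinite(lp0):
        raise ValueError(f"initial state {init} has zero prior density")
    n_samples = iterations // thin
    out_params = np.empty((n_samples, 4))
    out_logpost = np.empty(n_samples)
    out_acc = np.empty(3)
    out_steps = np.empty(3)
    _run_chain(
        counts.ref_count.astype(np.float64),
        counts.total_alleles.astype(np.float64),
        np.ascontiguousarray(dist.D_std),
        np.ascontiguousarray(dist.E_std),
        delta,
        iterations,
        thin,
        seed,
        int(adapt_fraction * iterations),
        likelihood,
        priors.alpha0_scale,
        priors.decay_rate,
        np.asarray(init, dtype=float),
        out_params,
        out_logpost,
        out_acc,
        out_steps,
    )
    if np.isnan(out_logpost[0]) and likelihood:
        raise ValueError("initial covariance not positive definite")
    samples = pd.DataFrame(
        out_params, columns=["alpha_0", "alpha_D", "alpha_E", "alpha_2"]
    )
    samples.insert(0, "iteration", (np.arange(n_samples) + 1) * thin)
    samples["log_posterior"] = out_logpost
    return PosteriorTrace(
        samples=samples,
        acceptance_rates={
            "parameters": float(out_acc[0]),
            "locus_means": float(out_acc[1]),
            "frequencies": float(out_acc[2]),
        },
        step_sizes={
            "parameters": float(out_steps[0]),
            "locus_means": float(out_steps[1]),
            "frequencies": float(out_steps[2]),
        },
        iterations=iterations,
        thin=thin,
        seed=seed,
    )


def summarize_ratio(
    trace: PosteriorTrace,
    dist: DistanceMatrices,
    burnin_fraction: float = 0.25,
    ratio_floor: float = 1e-6,
) -> dict:
    """Posterior mean and SD of the back-transformed alpha_E/alpha_D ratio.

    Decay rates are back-transformed to raw distance units (alpha/sd), so
    the per-sample ratio is (alpha_E/alpha_D) * (sd_D/sd_E).  Samples with
    alpha_D below ``ratio_floor`` (on the standardized scale) have the
    denominator floored; their count is reported.
    """
    df = trace.samples
    start = int(burnin_fraction * len(df))
    post = df.iloc[start:]
    if len(post) < 100:
        warnings.warn(f"only {len(post)} post-burn-in samples")
    if len(post) == 0:
        raise ValueError("no post-burn-in samples")
    aD = post["alpha_D"].to_numpy()
    aE = post["alpha_E"].to_numpy()
    floored = aD < ratio_floor
    ratio = (aE / np.maximum(aD, ratio_floor)) * (dist.sd_D / dist.sd_E)
    return {
        "mean": float(ratio.mean()),
        "sd": float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0,
        "q05": float(np.quantile(ratio, 0.05)),
        "q95": float(np.quantile(ratio, 0.95)),
        "n_samples": int(len(ratio)),
        "n_floored": int(floored.sum()),
    }


class IBEModel:
    """Isolation-by-environment model bound to allele counts and distances.

    Parameters
    ----------
    counts : AlleleCountTable
        Reference-allele counts per population x locus (LD-pruned loci).
    distances : DistanceMatrices
        Geographic and environmental distances with standardization
        constants.
    delta : float
        Fixed diagonal nugget keeping the covariance positive definite.
    priors : IBEPriors
        Hyperparameters of the weakly informative priors.
    """

    def __init__(
        self,
        counts: AlleleCountTable,
        distances: DistanceMatrices,
        delta: float = 1e-6,
        priors: IBEPriors | None = None,
    ):
        self.counts = counts
        self.distances = distances
        self.delta = delta
        self.priors = priors or IBEPriors()

    def covariance(self, params) -> np.ndarray:
        return build_covariance(params, self.distances, self.delta)

    def log_posterior(self, params, latent_freqs, locus_means) -> float:
        return model_log_posterior(
            params,
            latent_freqs,
            locus_means,
            self.counts,
            self.distances,
            self.delta,
            self.priors,
        )

    def fit(
        self,
        iterations: int = 100_000,
        thin: int = 250,
        seed: int = 0,
        adapt_fraction: float = 0.25,
        burnin_fraction: float = 0.25,
        likelihood: bool = True,
    ) -> "IBEResults":
        trace = run_mcmc(
            self.counts,
            self.distances,
            iterations=iterations,
            thin=thin,
            seed=seed,
            adapt_fraction=adapt_fraction,
            delta=self.delta,
            priors=self.priors,
            likelihood=likelihood,
        )
        return IBEResults(self, trace, burnin_fraction)


@dataclass
class IBEResults:
    """Posterior trace plus ratio summaries for a fitted IBEModel."""

    model: IBEModel
    trace: PosteriorTrace
    burnin_fraction: float = 0.25
    _ratio: dict = field(default=None, repr=False)

    def ratio_summary(self, ratio_floor: float = 1e-6) -> dict:
        if self._ratio is None:
            self._ratio = summarize_ratio(
                self.trace, self.model.distances, self.burnin_fraction, ratio_floor
            )
        return self._ratio

    @property
    def posterior(self) -> pd.DataFrame:
        start = int(self.burnin_fraction * len(self.trace.samples))
        return self.trace.samples.iloc[start:]

    def summary(self) -> pd.DataFrame:
        post = self.posterior
        rows = []
        for p in ["alpha_0", "alpha_D", "alpha_E", "alpha_2"]:
            v = post[p].to_numpy()
            rows.append(
                {
                    "parameter": p,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "q05": np.quantile(v, 0.05),
                    "q95": np.quantile(v, 0.95),
                }
            )
        r = self.ratio_summary()
        rows.append(
            {
                "parameter": "ratio_E_to_D (raw units)",
                "mean": r["mean"],
                "sd": r["sd"],
                "q05": r["q05"],
                "q95": r["q95"],
            }
        )
        return pd.DataFrame(rows)
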