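"""Coalescent simulation of the SFS and rejection-ABC model choice.

Two single-population demographic models are compared: drift–mutation
equilibrium ("null", constant size) and exponential growth ("growth"),
where looking backward in time the population size shrinks as
N(t) = N0 * exp(-alpha t).  Coalescent waiting times under growth use the
standard time transformation: with k lineages at time t0 and
w ~ Exponential(k(k-1)/2), the next coalescence happens at
t1 = ln(exp(alpha t0) + alpha w) / alpha (reducing to t0 + w as alpha -> 0).
Mutations fall on branches as a Poisson process with rate theta/2 per unit
branch length (infinite sites), and the resulting site frequency spectrum —
folded by default — is aggregated over unlinked loci.

Model choice uses plain rejection ABC on MAD-scaled folded-SFS proportions:
the tolerance fraction of pooled simulations closest to the observed
summaries is accepted, posterior model probabilities are acceptance shares,
and Bayes factors are their ratios (equal numbers of simulations per model
act as a uniform model prior).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import SFS

__all__ = [
    "DemographicModel",
    "DemographicABC",
    "ABCResults",
    "CVResult",
    "simulate_coalescent_sfs",
    "build_reference_table",
    "abc_rejection",
    "abc_model_choice",
    "cv_model_choice",
]

DEFAULT_THETA_RANGE = (0.1, 20.0)  # per-locus, log-uniform
DEFAULT_ALPHA_RANGE = (0.0, 10.0)  # coalescent-time growth rate, uniform


@dataclass
class DemographicModel:
    """A single-population demography: per-locus theta and growth rate."""

    name: str
    theta: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("null", "growth"):
            raise ValueError("model name must be 'null' or 'growth'")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.name == "null" and self.alpha != 0:
            raise ValueError("the null model has alpha = 0")


@njit(cache=True)
def _branch_lengths_by_class(n, alpha, exp_draws, pair_u, out):
    """Accumulate branch length subtending i leaves into out[i-1].

    ``exp_draws`` are unit exponentials (one per coalescence), ``pair_u``
    uniforms choosing the merging pair.  Under growth the waiting time is
    passed through the exponential time transformation.
    """
    sizes = np.empty(n, dtype=np.int64)
    for i in range(n):
        sizes[i] = 1
    for i in range(n - 1):
        out[i] = 0.0
    t = 0.0
    for step in range(n - 1):
        k = n - step
        w = exp_draws[step] / (k * (k - 1) / 2.0)
        if alpha > 0.0:
            t1 = math.log(math.exp(alpha * t) + alpha * w) / alpha
        else:
            t1 = t + w
        dt = t1 - t
        for j in range(k):
            out[sizes[j] - 1] += dt
        i1 = int(pair_u[2 * step] * k)
        if i1 >= k:
            i1 = k - 1
        j1 = int(pair_u[2 * step + 1] * (k - 1))
        if j1 >= k - 1:
            j1 = k - 2
        if j1 >= i1:
            j1 += 1
        sizes[i1] += sizes[j1]
        sizes[j1] = sizes[k - 1]
        t = t1
    return t


@njit(cache=True)
def _many_loci_branch_lengths(n, alpha, exp_draws, pair_u, out):
    for l in range(out.shape[0]):
        _branch_lengths_by_class(n, alpha, exp_draws[l], pair_u[l], out[l])


def simulate_coalescent_sfs(
    model: DemographicModel,
    n_diploids: int,
    n_loci: int = 50,
    seed: int | np.random.Generator = 0,
    folded: bool = True,
) -> SFS:
    """Simulate the SFS of ``n_loci`` unlinked loci for 2*n_diploids
    haploid lineages under the given demography."""
    if n_diploids < 1 or 2 * n_diploids < 2:
        raise ValueError("need at least one diploid (two lineages)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 2 * n_diploids
    lengths = _simulate_branch_lengths(model.alpha, n, n_loci, rng)
    # xi_i ~ Poisson(theta/2 * total class-i branch length), infinite sites
    xi_unfolded = rng.poisson(model.theta / 2.0 * lengths.sum(axis=0))
    return _fold(xi_unfolded, n, n_loci, folded)


def _simulate_branch_lengths(
    alpha: float, n: int, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    exp_draws = rng.exponential(1.0, size=(n_loci, n - 1))
    pair_u = rng.random(size=(n_loci, 2 * (n - 1)))
    out = np.empty((n_loci, n - 1))
    _many_loci_branch_lengths(n, float(alpha), exp_draws, pair_u, out)
    return out


def _fold(xi_unfolded: np.ndarray, n: int, n_loci: int, folded: bool) -> SFS:
    if not folded:
        return SFS(xi=xi_unfolded, n=n, n_loci=n_loci, folded=False)
    half = n // 2
    xi = np.zeros(half, dtype=np.int64)
    for i in range(1, n):
        xi[min(i, n - i) - 1] += xi_unfolded[i - 1]
    return SFS(xi=xi, n=n, n_loci=n_loci, folded=True)


def mean_total_branch_length(n: int) -> float:
    """Expected total tree length under constant size: 2 * sum_{i<n} 1/i."""
    return 2.0 * sum(1.0 / i for i in range(1, n))


def build_reference_table(
    model_name: str,
    n_sims: int = 100_000,
    n_diploids: int = 30,
    n_loci: int = 50,
    theta_range: tuple[float, float] = DEFAULT_THETA_RANGE,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    seed: int = 0,
    folded: bool = True,
) -> pd.DataFrame:
    """Simulate a rejection-ABC reference table.

    theta ~ log-uniform over ``theta_range`` and, for the growth model,
    alpha ~ Uniform over ``alpha_range``.  Summaries are the folded-SFS
    proportions (all-zero for a monomorphic dataset, which is retained to
    preserve the prior).  Columns: theta, alpha, xi1..xiM.
    """
    if model_name not in ("null", "growth"):
        raise ValueError("model_name must be 'null' or 'growth'")
    if theta_range[0] <= 0 or theta_range[1] <= theta_range[0]:
        raise ValueError("theta_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    n = 2 * n_diploids
    thetas = np.exp(rng.uniform(np.log(theta_range[0]), np.log(theta_range[1]), n_sims))
    alphas = (
        rng.uniform(alpha_range[0], alpha_range[1], n_sims)
        if model_name == "growth"
        else np.zeros(n_sims)
    )
    m = n // 2 if folded else n - 1
    summaries = np.empty((n_sims, m))
    n_monomorphic = 0
    for s in range(n_sims):
        lengths = _simulate_branch_lengths(alphas[s], n, n_loci, rng)
        xi_unf = rng.poisson(thetas[s] / 2.0 * lengths.sum(axis=0))
        sfs = _fold(xi_unf, n, n_loci, folded)
        summaries[s] = sfs.proportions()
        if sfs.segregating_sites == 0:
            n_monomorphic += 1
    table = pd.DataFrame(summaries, columns=[f"xi{i+1}" for i in range(m)])
    table.insert(0, "alpha", alphas)
    table.insert(0, "theta", thetas)
    table.attrs.update(
        model=model_name,
        n_diploids=n_diploids,
        n_loci=n_loci,
        folded=folded,
        n_monomorphic=n_monomorphic,
    )
    if n_monomorphic:
        warnings.warn(
            f"{n_monomorphic} simulated datasets were monomorphic (all-zero summaries retained)"
        )
    return table


def _summary_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("xi")]


def _mad_scales(values: np.ndarray) -> np.ndarray:
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0)
    mad[mad == 0] = 1.0
    return mad


def _distances(observed: np.ndarray, table_values: np.ndarray, scales: np.ndarray) -> np.ndarray:
    z = (table_values - observed[None, :]) / scales[None, :]
    return np.sqrt((z**2).sum(axis=1))


@dataclass
class ABCResults:
    """Accepted draws, distances, and (for model choice) Bayes factors."""

    tolerance: float
    accepted: pd.DataFrame
    distances: np.ndarray
    posterior_probabilities: dict[str, float] | None = None
    bayes_factors: dict[tuple[str, str], float] | None = None
    bf_is_bound: bool = False
    observed_summary: np.ndarray | None = None

    def posterior_median(self, parameter: str, model: str | None = None) -> float:
        df = self.accepted
        if model is not None and "model" in df.columns:
            df = df[df["model"] == model]
        return float(df[parameter].median())

    def summary(self) -> pd.DataFrame:
        rows = []
        df = self.accepted
        models = df["model"].unique() if "model" in df.columns else [None]
        for m in models:
            sub = df if m is None else df[df["model"] == m]
            for p in ("theta", "alpha"):
                if len(sub):
                    rows.append(
                        {
                            "model": m or "",
                            "parameter": p,
                            "median": sub[p].median(),
                            "q05": sub[p].quantile(0.05),
                            "q95": sub[p].quantile(0.95),
                            "n_accepted": len(sub),
                        }
                    )
        return pd.DataFrame(rows)


def abc_rejection(observed: SFS, table: pd.DataFrame, tolerance: float = 0.05) -> ABCResults:
    """Rejection ABC: accept the tolerance fraction of simulations whose
    MAD-scaled summaries lie closest (Euclidean) to the observed ones."""
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must lie in (0, 1]")
    cols = _summary_columns(table)
    obs = observed.proportions()
    if len(obs) != len(cols):
        raise ValueError(
            f"observed summary length {len(obs)} does not match table ({len(cols)})"
        )
    values = table[cols].to_numpy()
    n_accept = math.ceil(tolerance * len(table))
    if n_accept < 10:
        warnings.warn(f"only {n_accept} simulations accepted; posterior will be noisy")
    d = _distances(obs, values, _mad_scales(values))
    idx = np.argsort(d, kind="stable")[:n_accept]
    return ABCResults(
        tolerance=tolerance,
        accepted=table.iloc[idx].reset_index(drop=True),
        distances=d[idx],
        observed_summary=obs,
    )


def abc_model_choice(
    observed: SFS, tables: dict[str, pd.DataFrame], tolerance: float = 0.05
) -> ABCResults:
    """Pooled rejection across candidate models' reference tables.

    Posterior model probability = share of accepted simulations;
    BF(A, B) = share_A / share_B, reported for both orientations.  With
    unequal table sizes the shares are weighted to restore an equal-prior
    comparison.
    """
    names = list(tables)
    sizes = {m: len(tables[m]) for m in names}
    pooled = pd.concat(
        [tables[m].assign(model=m) for m in names], ignore_index=True
    )
    cols = _summary_columns(pooled)
    obs = observed.proportions()
    values = pooled[cols].to_numpy()
    d = _distances(obs, values, _mad_scales(values))
    n_accept = math.ceil(tolerance * len(pooled))
    idx = np.argsort(d, kind="stable")[:n_accept]
    accepted = pooled.iloc[idx].reset_index(drop=True)
    # weights undo unequal simulation effort per model
    max_size = max(sizes.values())
    weight = {m: max_size / sizes[m] for m in names}
    wcounts = {
        m: float((accepted["model"] == m).sum() * weight[m]) for m in names
    }
    total = sum(wcounts.values())
    probs = {m: (wcounts[m] / total if total > 0 else np.nan) for m in names}
    bfs: dict[tuple[str, str], float] = {}
    bound = False
    for a in names:
        for b in names:
            if a == b:
                bfs[(a, b)] = 1.0
            elif wcounts[b] > 0:
                bfs[(a, b)] = wcounts[a] / wcounts[b]
            else:
                bfs[(a, b)] = wcounts[a] / weight[b]  # lower bound: <1 sim for b
                bound = True
    if bound:
        warnings.warn("a model had zero acceptances; its Bayes factors are bounds")
    return ABCResults(
        tolerance=tolerance,
        accepted=accepted,
        distances=d[idx],
        posterior_probabilities=probs,
        bayes_factors=bfs,
        bf_is_bound=bound,
        observed_summary=obs,
    )


@dataclass
class CVResult:
    """Leave-one-out cross-validation of ABC model choice."""

    confusion: dict[float, pd.DataFrame]
    n_pseudo: int

    def correct_rate(self, tolerance: float, model: str) -> float:
        cm = self.confusion[tolerance]
        return float(cm.loc[model, model] / cm.loc[model].sum())


def cv_model_choice(
    tables: dict[str, pd.DataFrame],
    tolerances: tuple[float, ...] = (0.01, 0.05),
    n_pseudo: int = 100,
    seed: int = 0,
) -> CVResult:
    """Hold out simulated datasets in turn and ask whether pooled rejection
    recovers the model that generated each."""
    names = list(tables)
    for m in names:
        if n_pseudo > len(tables[m]):
            raise ValueError(f"n_pseudo exceeds table size for model {m!r}")
    rng = np.random.default_rng(seed)
    cols = _summary_columns(tables[names[0]])
    confusion = {
        tol: pd.DataFrame(0, index=names, columns=names, dtype=int) for tol in tolerances
    }
    for true_model in names:
        table = tables[true_model]
        held = rng.choice(len(table), size=n_pseudo, replace=False)
        for row in held:
            obs_summary = table.iloc[row][cols].to_numpy(dtype=float)
            reduced = {
                m: (tables[m].drop(index=row).reset_index(drop=True) if m == true_model else tables[m])
                for m in names
            }
            pooled = pd.concat(
                [reduced[m].assign(model=m) for m in names], ignore_index=True
            )
            values = pooled[cols].to_numpy()
            d = _distances(obs_summary, values, _mad_scales(values))
            sizes = {m: len(reduced[m]) for m in names}
            max_size = max(sizes.values())
            for tol in tolerances:
                n_accept = math.ceil(tol * len(pooled))
                idx = np.argsort(d, kind="stable")[:n_accept]
                acc_models = pooled["model"].to_numpy()[idx]
                wcounts = {
                    m: (acc_models == m).sum() * max_size / sizes[m] for m in names
                }
                chosen = max(names, key=lambda m: wcounts[m])
                confusion[tol].loc[true_model, chosen] += 1
    return CVResult(confusion=confusion, n_pseudo=n_pseudo)


class DemographicABC:
    """ABC analysis bound to an observed site frequency spectrum.

    ``fit`` runs pooled model choice plus per-model parameter rejection
    against reference tables (built here or supplied), returning an
    :class:`ABCResults`.
    """

    def __init__(self, observed: SFS):
        self.observed = observed

    def build_tables(
        self,
        n_sims: int = 100_000,
        n_loci: int = 50,
        theta_range: tuple[float, float] = DEFAULT_THETA_RANGE,
        alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
        seed: int = 0,
    ) -> dict[str, pd.DataFrame]:
        n_diploids = self.observed.n // 2
        return {
            name: build_reference_table(
                name,
                n_sims=n_sims,
                n_diploids=n_diploids,
                n_loci=n_loci,
                theta_range=theta_range,
                alpha_range=alpha_range,
                seed=seed + i,
                folded=self.observed.folded,
            )
            for i, name in enumerate(("null", "growth"))
        }

    def fit(self, tables: dict[str, pd.DataFrame], tolerance: float = 0.05) -> ABCResults:
        result = abc_model_choice(self.observed, tables, tolerance)
        # attach per-model parameter posteriors from single-model rejection
        result.parameter_posteriors = {
            m: abc_rejection(self.observed, tables[m], tolerance) for m in tables
        }
        return result

    def cross_validate(
        self,
        tables: dict[str, pd.DataFrame],
        tolerances: tuple[float, ...] = (0.01, 0.05),
        n_pseudo: int = 100,
        seed: int = 0,
    ) -> CVResult:
        return cv_model_choice(tables, tolerances, n_pseudo, seed)
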