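"""Core population-genetic statistics.

Distances between sampling localities, LD pruning, genotype PCA,
Weir–Cockerham F_ST, the folded site frequency spectrum, and per-locus
diversity (theta) from mean homozygosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    SFS,
    AlleleCountTable,
    GenotypeMatrix,
    LocalityTable,
    upper_triangle,
)

EARTH_RADIUS_KM = 6371.0

ENV_VARIABLES = {
    "elevation": "elevation",
    "MAT": "mean_annual_temperature",
    "MAP": "mean_annual_precipitation",
}


def tally_alleles(g: GenotypeMatrix) -> AlleleCountTable:
    """Collapse a genotype matrix into per-population allele counts.

    x_kl sums reference dosages over non-missing genotypes of population k;
    n_kl is twice the number of non-missing genotypes.
    """
    groups = g.locality_indices()
    pops = g.localities
    if any(len(groups[p]) == 0 for p in pops):
        raise ValueError("empty population")
    x = np.zeros((len(pops), g.n_loci), dtype=np.int64)
    n = np.zeros_like(x)
    for k, pop in enumerate(pops):
        d = g.dosage[groups[pop]]
        observed = d != MISSING
        x[k] = np.where(observed, d, 0).sum(axis=0)
        n[k] = 2 * observed.sum(axis=0)
    return AlleleCountTable(
        ref_count=x, total_alleles=n, population_ids=pops, locus_ids=list(g.locus_ids)
    )


def haversine_distance_matrix(localities: LocalityTable) -> np.ndarray:
    """Great-circle distances (km) between all locality pairs."""
    lat = np.radians(localities.table["latitude"].to_numpy(float))
    lon = np.radians(localities.table["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def environmental_distance_matrix(
    localities: LocalityTable, variables: tuple[str, ...] = ("elevation", "MAT", "MAP")
) -> np.ndarray:
    """Euclidean distance over z-scored environmental variables.

    Each selected variable is standardized across localities (sample SD)
    before the distance is taken, so variables on different scales weigh
    equally.
    """
    if not variables:
        raise ValueError("select at least one environmental variable")
    cols = []
    for v in variables:
        col = ENV_VARIABLES.get(v, v)
        vals = localities.table[col].to_numpy(float)
        sd = np.std(vals, ddof=1)
        if sd == 0:
            raise ValueError(f"environmental variable {v!r} has zero variance")
        cols.append((vals - vals.mean()) / sd)
    z = np.column_stack(cols)
    diff = z[:, None, :] - z[None, :, :]
    e = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(e, 0.0)
    return e


def matrix_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between the off-diagonal upper triangles of two symmetric
    matrices (no permutation test)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    x, y = upper_triangle(a), upper_triangle(b)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("matrix correlation undefined for a constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


def ld_prune(g: GenotypeMatrix, max_r2: float = 0.1, window: int = 50) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning.

    Scanning loci in order, a locus is dropped when its squared Pearson
    correlation of dosages (missing pairwise-deleted) with any *retained*
    locus within the trailing ``window`` loci on the same contig exceeds
    ``max_r2``.  Leftmost-first order makes the output deterministic.
    """
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    keep: list[int] = []
    kept_in_contig: list[int] = []
    current_contig: str | None = None
    for j in range(g.n_loci):
        if g.contigs[j] != current_contig:
            current_contig = g.contigs[j]
            kept_in_contig = []
        ok = True
        for i in reversed(kept_in_contig):
            if j - i > window:
                break
            if _pairwise_r2(d[:, i], d[:, j]) > max_r2:
                ok = False
                break
        if ok:
            keep.append(j)
            kept_in_contig.append(j)
    return g.subset(loci=keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    m = ~(np.isnan(x) | np.isnan(y))
    if m.sum() < 2:
        return 0.0
    xv, yv = x[m], y[m]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


@dataclass
class PCAResult:
    scores: np.ndarray
    variance_fraction: np.ndarray
    individual_ids: list[str]
    outlier_flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.individual_ids,
            columns=[f"PC{i+1}" for i in range(self.scores.shape[1])],
        )
        if self.outlier_flags is not None:
            df["outlier"] = self.outlier_flags
        return df


def genotype_pca(g: GenotypeMatrix, n_components: int = 10, scale: bool = False) -> PCAResult:
    """PCA of the genotype matrix.

    Missing dosages are imputed to the locus mean; columns are centered
    (optionally scaled) and the individual covariance eigendecomposed via
    SVD.  Scores are deterministic up to sign.
    """
    if g.n_individuals < 2 or g.n_loci < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 loci")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} all-missing loci before PCA")
        d = d[:, ~all_missing]
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    d -= mu
    if scale:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        d /= sd
    n_components = min(n_components, min(d.shape) - 1) or 1
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    total_var = (s**2).sum()
    var_frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=scores, variance_fraction=var_frac, individual_ids=list(g.individual_ids)
    )


def flag_outlier_individuals(p: PCAResult, mad_factor: float = 6.0) -> np.ndarray:
    """Flag individuals far from the point cloud on PC1 or PC2.

    An individual is flagged when its PC1 or PC2 score deviates from the
    median by more than ``mad_factor`` times the median absolute deviation —
    a reproducible stand-in for the visual identification of misassigned or
    cryptic-species samples.
    """
    if p.scores.shape[0] < 3:
        raise ValueError("outlier flagging needs at least 3 individuals")
    n_axes = min(2, p.scores.shape[1])
    flags = np.zeros(p.scores.shape[0], dtype=bool)
    for ax in range(n_axes):
        s = p.scores[:, ax]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad == 0:
            warnings.warn(f"MAD of PC{ax+1} is zero; no outliers flagged on this axis")
            continue
        flags |= np.abs(s - med) > mad_factor * mad
    p.outlier_flags = flags
    return flags


def _wc_components(x1, n1, x2, n2):
    """Per-locus between/within variance components of the two-level ANOVA
    on allele indicators (Weir–Cockerham theta for allele-count data)."""
    n_tot = n1 + n2
    valid = (n1 > 0) & (n2 > 0) & (n_tot > 2)  # within-group df must exist
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, x1 / n1, 0.0)
        p2 = np.where(n2 > 0, x2 / n2, 0.0)
        pbar = np.where(n_tot > 0, (x1 + x2) / n_tot, 0.0)
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # df = r - 1 = 1
        ssg = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
        msg = np.where(n_tot > 2, ssg / (n_tot - 2), 0.0)
        nc = np.where(n_tot > 0, (n_tot - (n1**2 + n2**2) / n_tot), 0.0)  # df 1
    a = np.where(nc > 0, (msp - msg) / np.where(nc > 0, nc, 1.0), 0.0)
    return np.where(valid, a, 0.0), np.where(valid, msg, 0.0), valid


def pairwise_fst_wc(a: AlleleCountTable, pop_i: int | str, pop_j: int | str) -> float:
    """Two-population Weir–Cockerham F_ST, ratio-of-sums across loci.

    Computed from allele counts as the two-level (populations /
    alleles-within-populations) variance-component estimator; may be
    negative when within-population diversity exceeds the between-population
    expectation.  Negative values are preserved here.
    """
    i = a.population_ids.index(pop_i) if isinstance(pop_i, str) else pop_i
    j = a.population_ids.index(pop_j) if isinstance(pop_j, str) else pop_j
    comp_a, msg, valid = _wc_components(
        a.ref_count[i].astype(float),
        a.total_alleles[i].astype(float),
        a.ref_count[j].astype(float),
        a.total_alleles[j].astype(float),
    )
    denom = (comp_a + msg)[valid].sum()
    if denom == 0:
        raise ValueError("F_ST undefined: no shared polymorphic loci")
    return float(comp_a[valid].sum() / denom)


def pairwise_fst_matrix(a: AlleleCountTable) -> pd.DataFrame:
    k = a.n_populations
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pairwise_fst_wc(a, i, j)
    return pd.DataFrame(out, index=a.population_ids, columns=a.population_ids)


def global_fst_wc(a: AlleleCountTable) -> float:
    """Multi-population Weir–Cockerham theta (ratio of sums across loci)."""
    x = a.ref_count.astype(float)
    n = a.total_alleles.astype(float)
    valid_pop = n > 0
    r = valid_pop.sum(axis=0)
    keep = r >= 2
    x, n, valid_pop, r = x[:, keep], n[:, keep], valid_pop[:, keep], r[keep]
    n_tot = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, x / n, 0.0)
        pbar = x.sum(axis=0) / n_tot
        msp = (n * (p - pbar) ** 2).sum(axis=0) / (r - 1)
        ssg = (n * p * (1 - p)).sum(axis=0)
        msg = np.where(n_tot > r, ssg / (n_tot - r), 0.0)
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
    num = np.where(nc > 0, (msp - msg) / np.where(nc > 0, nc, 1.0), 0.0)
    denom = num + msg
    if denom.sum() == 0:
        raise ValueError("F_ST undefined: no polymorphic loci")
    return float(num.sum() / denom.sum())


def folded_sfs(
    source: AlleleCountTable | GenotypeMatrix,
    folded: bool = True,
    project_to: int | None = None,
    seed: int = 0,
) -> SFS:
    """Site frequency spectrum pooled over populations.

    Without projection, sites with missing genotypes are dropped so every
    retained site has the same haploid sample size.  With ``project_to``
    set, each site with at least that many sampled alleles is down-sampled
    to exactly ``project_to`` alleles by a seeded hypergeometric draw
    (sites below it are dropped), which rescues sites lost to scattered
    missingness.  Monomorphic sites are excluded.  The folded spectrum bins
    sites by minor-allele count (polarity-free); the unfolded mode bins by
    alternate-allele (non-reference) count.
    """
    if isinstance(source, GenotypeMatrix):
        observed = source.dosage != MISSING
        pooled_x = np.where(observed, source.dosage, 0).sum(axis=0)
        pooled_n = 2 * observed.sum(axis=0)
        full_n = 2 * source.n_individuals
    else:
        pooled_x = source.ref_count.sum(axis=0)
        pooled_n = source.total_alleles.sum(axis=0)
        full_n = int(pooled_n.max()) if pooled_n.size else 0
    if project_to is None:
        n = full_n
        full = pooled_n == n
        x = pooled_x[full]
        n_loci_used = int(full.sum())
    else:
        if project_to < 2 or project_to > full_n:
            raise ValueError("project_to must lie in [2, total alleles]")
        n = int(project_to)
        keep = pooled_n >= n
        rng = np.random.default_rng(seed)
        x = rng.hypergeometric(pooled_x[keep], pooled_n[keep] - pooled_x[keep], n)
        n_loci_used = int(keep.sum())
    if n < 2:
        raise ValueError("need a haploid sample size of at least 2")
    alt = n - x  # alternate-allele counts
    if folded:
        counts = np.minimum(x, alt)
        xi = np.bincount(counts[(counts > 0)], minlength=n // 2 + 1)[1 : n // 2 + 1]
    else:
        xi = np.bincount(alt[(alt > 0) & (alt < n)], minlength=n)[1:n]
    return SFS(xi=xi, n=n, n_loci=n_loci_used, folded=folded)


def theta_from_homozygosity(a: AlleleCountTable, pop: int | str) -> pd.DataFrame:
    """Per-locus theta from mean homozygosity for one population.

    Unbiased expected heterozygosity Ĥ = n/(n-1) · (1 - Σ p̂²) with n the
    sampled allele count; under the infinite-alleles equilibrium the
    expected homozygosity is F = 1/(1+θ), inverted as θ̂ = Ĥ/(1-Ĥ).
    Monomorphic loci give θ̂ = 0.
    """
    k = a.population_ids.index(pop) if isinstance(pop, str) else pop
    n = a.total_alleles[k].astype(float)
    x = a.ref_count[k].astype(float)
    if (n < 2).any():
        raise ValueError("theta needs at least 2 sampled alleles at every locus")
    p = x / n
    h = (n / (n - 1)) * (1 - (p**2 + (1 - p) ** 2))
    if (h >= 1).any():
        raise ValueError("Ĥ = 1: theta undefined")
    theta = h / (1 - h)
    return pd.DataFrame(
        {
            "locus": a.locus_ids,
            "population": a.population_ids[k],
            "H_hat": h,
            "F_hat": 1 - h,
            "theta_hat": theta,
        }
    )


def theta_table(a: AlleleCountTable) -> pd.DataFrame:
    """theta_from_homozygosity stacked over all populations."""
    return pd.concat(
        [theta_from_homozygosity(a, k) for k in range(a.n_populations)],
        ignore_index=True,
    )
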