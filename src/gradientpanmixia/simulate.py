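"""Seeded synthetic data: gradient sampling designs, spatially correlated
allele frequencies, binomial genotypes, and annotated VCF fixtures.

The frequency model mirrors the inference model in :mod:`gradientpanmixia.ibe`
exactly — locus l draws a mean mu_l ~ Uniform(0.05, 0.95) and a K-vector of
locality frequencies from N(mu_l, mu_l (1 - mu_l) Omega), clamped to
[0.001, 0.999] — so parameter recovery closes the loop.  Genotypes are
Binomial(2, f) dosages of the reference allele; sequencing depth is
negative-binomial (overdispersed Poisson) and allele depths split the reads
binomially, which is enough annotation to exercise the full filter cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, DistanceMatrices, GenotypeMatrix, LocalityTable
from .ibe import build_covariance
from .popgen import environmental_distance_matrix, haversine_distance_matrix

KM_PER_DEGREE = 111.19492664455873  # 2*pi*6371/360

# deterministic pseudo-climate: a moist-adiabatic-ish lapse for temperature
# and an orographic increase for precipitation, anchored near the study
# region's lowland values
_MAT_SEA_LEVEL_C = 24.0
_LAPSE_C_PER_M = 0.0055
_MAP_BASE_MM = 2000.0
_MAP_SLOPE_MM_PER_M = 0.8


@dataclass
class SimConfig:
    """Knobs of the synthetic generative model.

    ``alpha_*`` are the covariance parameters of the frequency model (on
    the standardized-distance scale); ``mean_depth`` and
    ``depth_dispersion`` parameterize the negative-binomial read depth
    (dispersion -> inf recovers Poisson); ``base_qual`` anchors site QUAL.
    Defaults emulate near-panmictic RADseq data along a short gradient:
    weak distance decay, no environmental effect, and among-locality
    variance ~ 2% of mu(1-mu).
    """

    seed: int = 0
    n_loci: int = 2000
    alpha_0: float = 50.0
    alpha_D: float = 0.5
    alpha_E: float = 0.0
    alpha_2: float = 1.0
    missing_rate: float = 0.1
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    base_qual: float = 40.0
    delta: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")


def make_gradient_design(
    n_localities: int,
    elev_min: float,
    elev_max: float,
    spacing_km: float = 1.0,
    n_per_locality: int = 10,
    base_lat: float = -0.6,
    base_lon: float = -77.8,
) -> LocalityTable:
    """Evenly spaced localities along a straight-line elevational transect.

    Elevations interpolate linearly from ``elev_min`` to ``elev_max``;
    localities sit ``spacing_km`` apart along a meridian.  Temperature and
    precipitation are deterministic functions of elevation, so the design
    is fully reproducible from its arguments.
    """
    if n_localities < 2:
        raise ValueError("need at least 2 localities")
    if elev_max <= elev_min:
        raise ValueError("elev_max must exceed elev_min")
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")
    if n_per_locality < 1:
        raise ValueError("n_per_locality must be positive")
    elevations = np.linspace(elev_min, elev_max, n_localities)
    lats = base_lat + np.arange(n_localities) * spacing_km / KM_PER_DEGREE
    table = pd.DataFrame(
        {
            "locality_id": [f"L{i+1}" for i in range(n_localities)],
            "latitude": lats,
            "longitude": base_lon,
            "elevation": elevations,
            "mean_annual_temperature": _MAT_SEA_LEVEL_C - _LAPSE_C_PER_M * elevations,
            "mean_annual_precipitation": _MAP_BASE_MM + _MAP_SLOPE_MM_PER_M * elevations,
            "n_individuals": n_per_locality,
        }
    )
    return LocalityTable(table)


def distances_for(localities: LocalityTable, env_variables=("elevation", "MAT", "MAP")) -> DistanceMatrices:
    """Geographic + environmental distance matrices for a locality table."""
    return DistanceMatrices(
        D=haversine_distance_matrix(localities),
        E=environmental_distance_matrix(localities, tuple(env_variables)),
        ids=localities.ids,
    )


def simulate_spatial_frequencies(
    localities: LocalityTable,
    params: SimConfig,
    dist: DistanceMatrices | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-locus locality frequency vectors, shape (n_loci, K).

    Draws mu_l ~ Uniform(0.05, 0.95) and f_l ~ N(mu_l, mu_l(1-mu_l) Omega),
    clamped to [0.001, 0.999].
    """
    dist = distances_for(localities) if dist is None else dist
    rng = np.random.default_rng(params.seed) if rng is None else rng
    omega = build_covariance(
        (params.alpha_0, params.alpha_D, params.alpha_E, params.alpha_2),
        dist,
        params.delta,
    )
    chol = np.linalg.cholesky(omega)
    mu = rng.uniform(0.05, 0.95, size=params.n_loci)
    z = rng.standard_normal((params.n_loci, dist.n))
    f = mu[:, None] + np.sqrt(mu * (1 - mu))[:, None] * (z @ chol.T)
    return np.clip(f, 0.001, 0.999)


def sample_genotypes(
    freqs: np.ndarray,
    localities: LocalityTable,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Binomial(2, f) reference-allele dosages with random missingness."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_loci, n_pop = freqs.shape
    if n_pop != localities.n_localities:
        raise ValueError("frequency columns must match localities")
    counts = localities.table["n_individuals"].to_numpy(int)
    ids, assignment, rows = [], {}, []
    for k, loc in enumerate(localities.ids):
        g = rng.binomial(2, freqs[:, k], size=(counts[k], n_loci)).astype(np.int8)
        rows.append(g)
        for i in range(counts[k]):
            name = f"{loc}_ind{i+1}"
            ids.append(name)
            assignment[name] = loc
    dosage = np.vstack(rows)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING
    return GenotypeMatrix(
        dosage=dosage,
        individual_ids=ids,
        locus_ids=[f"locus_{l+1}" for l in range(n_loci)],
        contigs=[f"contig_{l+1}" for l in range(n_loci)],
        locality_of=assignment,
    )


def write_annotated_vcf(
    genotypes: GenotypeMatrix,
    path: str | Path,
    depth_model: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write a VCF 4.2 fixture with GT:DP:AD genotypes, QUAL and an MQR
    (mapping-quality-ratio) INFO key.

    Depth is negative-binomial around ``mean_depth``; allele depths split
    the reads Binomial(DP, allele balance 1 / 0.5 / 0 by genotype); QUAL
    scales with summed site depth.  Output is byte-identical for a fixed
    seed.
    """
    cfg = depth_model or SimConfig()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    path = Path(path)
    n_ind, n_loci = genotypes.dosage.shape
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
    observed = genotypes.dosage != MISSING
    dp = np.where(
        observed, rng.negative_binomial(cfg.depth_dispersion, p_nb, size=(n_ind, n_loci)), 0
    )
    balance = np.select(
        [genotypes.dosage == 2, genotypes.dosage == 1], [1.0, 0.5], default=0.0
    )
    ref_reads = rng.binomial(dp, balance)
    site_depth = dp.sum(axis=0)
    qual = np.round(site_depth * rng.uniform(1.5, 3.0, size=n_loci) + cfg.base_qual, 2)
    mqr = np.round(rng.uniform(0.92, 1.03, size=n_loci), 4)

    gt_code = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQR,Number=1,Type=Float,Description="Ratio of mean mapping quality of reference over alternate allele">\n')
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        for contig in dict.fromkeys(genotypes.contigs):
            fh.write(f"##contig=<ID={contig},length=1000>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for l in range(n_loci):
            ns = int(observed[:, l].sum())
            cells = []
            for i in range(n_ind):
                g = gt_code[int(genotypes.dosage[i, l])]
                d = int(dp[i, l])
                r = int(ref_reads[i, l])
                cells.append(f"{g}:{d}:{r},{d - r}")
            fh.write(
                f"{genotypes.contigs[l]}\t100\t{genotypes.locus_ids[l]}\tA\tT\t"
                f"{qual[l]:.2f}\t.\tMQR={mqr[l]:.4f};NS={ns}\tGT:DP:AD\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def simulate_dataset(
    localities: LocalityTable, config: SimConfig, vcf_path: str | Path | None = None
):
    """Convenience wrapper: frequencies -> genotypes (-> annotated VCF).

    Returns ``(genotypes, freqs, distances)``; a single generator seeded
    from ``config.seed`` drives every stage, so a fixed config reproduces
    the dataset (and the VCF bytes) exactly.
    """
    rng = np.random.default_rng(config.seed)
    dist = distances_for(localities)
    freqs = simulate_spatial_frequencies(localities, config, dist, rng=rng)
    genotypes = sample_genotypes(freqs, localities, config.missing_rate, seed=rng)
    if vcf_path is not None:
        write_annotated_vcf(genotypes, vcf_path, config, rng=rng)
    return genotypes, freqs, dist
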