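"""One-config orchestration of the full analysis.

Stages run in the standard analysis order: filter -> structure (PCA, F_ST,
distances) -> isolation-by-environment MCMC -> ABC demographic model
choice -> range-limit diagnostics.  Every stage writes tab-separated
outputs under the configured output directory, and the consolidated report
carries the headline numbers (PC1~elevation regression, global and
pairwise F_ST, IBE ratio mean +/- SD, Bayes factors, the theta LRT, and
Wright's neighborhood size).  All randomness flows from the seeds recorded
in the config, so re-running a config reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import popgen
from .datatypes import DistanceMatrices, LocalityTable
from .demography import DemographicABC
from .filtering import FilterConfig, filter_vcf_file
from .ibe import IBEModel, IBEPriors
from .rangelimits import RoussetRegression, ThetaRangeLimitModel

logger = logging.getLogger("gradientpanmixia")


@dataclass
class StructureSettings:
    n_components: int = 10
    mad_factor: float = 6.0
    ld_max_r2: float = 0.1
    ld_window: int = 50
    env_variables: tuple[str, ...] = ("elevation", "MAT", "MAP")


@dataclass
class IBESettings:
    iterations: int = 100_000
    thin: int = 250
    burnin_fraction: float = 0.25
    adapt_fraction: float = 0.25
    seed: int = 0
    delta: float = 1e-6
    alpha0_prior_scale: float = 10.0
    decay_prior_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must lie in [0, 1)")


@dataclass
class ABCSettings:
    n_sims: int = 10_000
    n_loci: int = 50
    tolerance: float = 0.05
    theta_range: tuple[float, float] = (0.1, 20.0)
    alpha_range: tuple[float, float] = (0.0, 10.0)
    seed: int = 0
    run_cv: bool = False
    cv_tolerances: tuple[float, ...] = (0.01, 0.05)
    n_pseudo: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.tolerance <= 1):
            raise ValueError(f"tolerance must lie in (0, 1], got {self.tolerance}")


@dataclass
class StageToggles:
    filter: bool = True
    structure: bool = True
    ibe: bool = True
    abc: bool = True
    rangelimits: bool = True


@dataclass
class PipelineConfig:
    vcf: str
    localities: str
    output_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    structure: StructureSettings = field(default_factory=StructureSettings)
    ibe: IBESettings = field(default_factory=IBESettings)
    abc: ABCSettings = field(default_factory=ABCSettings)
    stages: StageToggles = field(default_factory=StageToggles)

    def validate_paths(self) -> None:
        for name in ("vcf", "localities"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


_SECTION_TYPES = {
    "filter": FilterConfig,
    "structure": StructureSettings,
    "ibe": IBESettings,
    "abc": ABCSettings,
    "stages": StageToggles,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known_top = {"vcf", "localities", "output_dir", *_SECTION_TYPES}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for req in ("vcf", "localities", "output_dir"):
        if req not in raw:
            raise ValueError(f"config is missing required key {req!r}")
    kwargs: dict = {k: raw[k] for k in ("vcf", "localities", "output_dir")}
    for section, cls in _SECTION_TYPES.items():
        sub = raw.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - valid
        if bad:
            raise ValueError(f"unknown keys in config section {section!r}: {sorted(bad)}")
        for key in ("theta_range", "alpha_range", "cv_tolerances", "env_variables"):
            if key in sub and isinstance(sub[key], list):
                sub[key] = tuple(sub[key])
        kwargs[section] = cls(**sub)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the consolidated report."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "pipeline.log")
    localities = LocalityTable.read_tsv(config.localities)
    locality_of = None  # inferred from sample naming by the filter stage
    report: dict = {"seeds": {"ibe": config.ibe.seed, "abc": config.abc.seed}}
    dump_config(config, out / "config_used.yaml")

    logger.info("stage filter: %s", config.vcf)
    genotypes, filt_report = filter_vcf_file(
        config.vcf,
        vcf_out=out / "filtered_primary.vcf",
        report_path=out / "filter_report.tsv",
        config=config.filter,
        locality_of=locality_of,
    )
    report["filter"] = {
        "input_shape": list(filt_report.input_shape),
        "output_shape": list(filt_report.output_shape),
        "steps": dict(filt_report.steps),
    }
    if not config.stages.filter:
        logger.info("filter stage disabled: cascade still runs to load genotypes")

    structure = _stage_structure(config, genotypes, localities, out, report)
    genotypes = structure["genotypes"]  # PCA outliers removed

    if config.stages.ibe:
        _stage_ibe(config, genotypes, structure["distances"], out, report)
    if config.stages.abc:
        _stage_abc(config, localities, out, report)
    if config.stages.rangelimits:
        _stage_rangelimits(config, structure, localities, out, report)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    _write_summary(report, out / "summary.tsv")
    logger.info("pipeline complete: %s", out)
    return report


def _stage_structure(config, genotypes, localities, out, report) -> dict:
    dist = DistanceMatrices(
        D=popgen.haversine_distance_matrix(localities),
        E=popgen.environmental_distance_matrix(localities, config.structure.env_variables),
        ids=localities.ids,
    )
    dist.write_tsv(out / "distance_geo.tsv", out / "distance_env.tsv")
    elev_dist = np.abs(localities.elevation[:, None] - localities.elevation[None, :])
    report["distances"] = {
        "sd_D": dist.sd_D,
        "sd_E": dist.sd_E,
        "pearson_r_elev_geo": popgen.matrix_correlation(elev_dist, dist.D),
    }
    if not config.stages.structure:
        return {"genotypes": genotypes, "distances": dist, "counts": popgen.tally_alleles(genotypes)}

    logger.info("stage structure: PCA on %s x %s", *genotypes.dosage.shape)
    pca = popgen.genotype_pca(genotypes, config.structure.n_components)
    flags = popgen.flag_outlier_individuals(pca, config.structure.mad_factor)
    pca.to_frame().to_csv(out / "pca_scores.tsv", sep="\t")
    if flags.any():
        logger.info("dropping %d PCA outlier individuals", int(flags.sum()))
        genotypes = genotypes.subset(individuals=np.where(~flags)[0])
        pca = popgen.genotype_pca(genotypes, config.structure.n_components)
    elev_of_ind = np.array(
        [
            dict(zip(localities.ids, localities.elevation))[genotypes.locality_of[i]]
            for i in genotypes.individual_ids
        ]
    )
    lr = stats.linregress(elev_of_ind, pca.scores[:, 0])
    counts = popgen.tally_alleles(genotypes)
    fst = popgen.pairwise_fst_matrix(counts)
    fst.to_csv(out / "fst_pairwise.tsv", sep="\t")
    report["structure"] = {
        "n_outliers_dropped": int(flags.sum()),
        "pc1_variance_pct": float(pca.variance_fraction[0] * 100),
        "pc1_elevation_r2": float(lr.rvalue**2),
        "pc1_elevation_p": float(lr.pvalue),
        "global_fst": popgen.global_fst_wc(counts),
        "fst_range": [float(np.min(fst.to_numpy()[np.triu_indices(len(fst), 1)])),
                      float(np.max(fst.to_numpy()[np.triu_indices(len(fst), 1)]))],
    }
    return {"genotypes": genotypes, "distances": dist, "counts": counts, "fst": fst}


def _stage_ibe(config, genotypes, dist, out, report) -> None:
    logger.info("stage ibe: LD pruning at r2 <= %s", config.structure.ld_max_r2)
    pruned = popgen.ld_prune(genotypes, config.structure.ld_max_r2, config.structure.ld_window)
    counts = popgen.tally_alleles(pruned)
    counts.write_tsv(out / "allele_counts.tsv")
    model = IBEModel(
        counts,
        dist,
        delta=config.ibe.delta,
        priors=IBEPriors(config.ibe.alpha0_prior_scale, config.ibe.decay_prior_rate),
    )
    logger.info("stage ibe: MCMC %d iterations", config.ibe.iterations)
    res = model.fit(
        iterations=config.ibe.iterations,
        thin=config.ibe.thin,
        seed=config.ibe.seed,
        adapt_fraction=config.ibe.adapt_fraction,
        burnin_fraction=config.ibe.burnin_fraction,
    )
    res.trace.write_tsv(out / "ibe_trace.tsv")
    res.summary().to_csv(out / "ibe_summary.tsv", sep="\t", index=False)
    ratio = res.ratio_summary()
    report["ibe"] = {
        "n_loci_after_pruning": pruned.n_loci,
        "ratio_mean": ratio["mean"],
        "ratio_sd": ratio["sd"],
        "ratio_q05": ratio["q05"],
        "ratio_q95": ratio["q95"],
        "acceptance_rates": res.trace.acceptance_rates,
    }


def _stage_abc(config, localities, out, report) -> None:
    # the SFS dataset skips MAF/MAC filtering (rare variants carry the
    # growth signal), mirroring the secondary-dataset convention
    secondary_cfg = dataclasses.replace(config.filter, apply_maf=False)
    genotypes, _ = filter_vcf_file(config.vcf, config=secondary_cfg)
    # project down to 80% of the haploid sample size (even) so sites with
    # scattered missing genotypes still inform the spectrum
    target = max(4, 2 * int(0.8 * genotypes.n_individuals))
    sfs = popgen.folded_sfs(genotypes, project_to=target, seed=config.abc.seed)
    sfs.write_tsv(out / "sfs.tsv")
    logger.info("stage abc: observed S=%d over %d complete sites", sfs.segregating_sites, sfs.n_loci)
    abc = DemographicABC(sfs)
    tables = abc.build_tables(
        n_sims=config.abc.n_sims,
        n_loci=config.abc.n_loci,
        theta_range=config.abc.theta_range,
        alpha_range=config.abc.alpha_range,
        seed=config.abc.seed,
    )
    res = abc.fit(tables, tolerance=config.abc.tolerance)
    res.summary().to_csv(out / "abc_posteriors.tsv", sep="\t", index=False)
    report["abc"] = {
        "bayes_factor_null_vs_growth": res.bayes_factors[("null", "growth")],
        "bayes_factor_growth_vs_null": res.bayes_factors[("growth", "null")],
        "posterior_prob": res.posterior_probabilities,
        "bf_is_bound": res.bf_is_bound,
        "posterior_median_theta_null": res.posterior_median("theta", "null"),
    }
    if config.abc.run_cv:
        cv = abc.cross_validate(
            tables,
            tolerances=config.abc.cv_tolerances,
            n_pseudo=config.abc.n_pseudo,
            seed=config.abc.seed,
        )
        report["abc"]["cv_correct_rate"] = {
            str(tol): {m: cv.correct_rate(tol, m) for m in ("null", "growth")}
            for tol in config.abc.cv_tolerances
        }


def _stage_rangelimits(config, structure, localities, out, report) -> None:
    counts = structure["counts"]
    theta = popgen.theta_table(counts)
    theta.to_csv(out / "theta_by_locus.tsv", sep="\t", index=False)
    lrt = ThetaRangeLimitModel(theta, localities).fit()
    fst = structure.get("fst")
    if fst is None:
        fst = popgen.pairwise_fst_matrix(counts)
    order = [list(fst.index).index(p) for p in structure["distances"].ids if p in fst.index]
    fst_m = fst.to_numpy()[np.ix_(order, order)]
    d_m = structure["distances"].D
    nw = RoussetRegression(fst_m, d_m).fit()
    nw.summary().to_csv(out / "neighborhood.tsv", sep="\t", index=False)
    report["rangelimits"] = {
        "lrt_chi2": lrt.chi2,
        "lrt_p": lrt.p_value,
        "theta_slope": lrt.slope,
        "nw": nw.nw,
        "nw_finite": nw.finite,
        "rousset_slope": nw.slope,
    }


def _write_summary(report: dict, path: Path) -> None:
    rows = []
    for section, vals in report.items():
        if not isinstance(vals, dict):
            continue
        for k, v in vals.items():
            if isinstance(v, (int, float, bool, str)):
                rows.append({"section": section, "quantity": k, "value": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and not np.isfinite(o):
        return str(o)
    return str(o)


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
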