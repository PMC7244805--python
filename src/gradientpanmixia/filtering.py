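"""Post-calling SNP filter cascade.

Reproduces a RADseq quality-control cascade in a fixed order: individual
missingness, locus missingness, minor-allele frequency/count, site quality,
genotype depth, allelic balance, strand, mapping-quality ratio,
quality-vs-depth, and a high-depth outlier rule.  Rule order follows the
order the thresholds are usually applied in (and it matters for the
counts).  The "primary" dataset applies the MAF/MAC rule; the "secondary"
dataset (``apply_maf=False``) skips it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GenotypeMatrix


class FilterConfigurationError(ValueError):
    """An enabled rule cannot run, e.g. its annotation is absent."""


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults give the 'primary' dataset.

    ``qual_depth_factor_low`` resolves the ambiguous "quality score >1/4
    below its depth" rule as QUAL < factor * site depth; the alternative
    reading (QUAL < depth - depth/4) corresponds to factor 0.75.
    ``depth_percentile`` replaces a qualitative histogram-asymptote cut for
    high-depth outliers with a reproducible percentile.
    """

    max_ind_missing: float = 0.30
    max_locus_missing: float = 0.25
    min_maf: float = 0.05
    min_mac: int = 3
    min_qual: float = 30.0
    min_genotype_depth: int = 5
    ab_low: float = 0.25
    ab_high: float = 0.75
    mqr_low: float = 0.9
    mqr_high: float = 1.05
    qual_depth_factor_low: float = 0.25
    high_depth_multiplier: float = 3.0
    qual_depth_factor_high: float = 2.0
    depth_percentile: float = 99.5
    apply_maf: bool = True
    strand_rule: bool = False
    mqr_rule: bool = True
    mqr_key: str = "MQR"
    strand_key: str = "SB"
    require_annotations: bool = False

    def __post_init__(self) -> None:
        for name in ("max_ind_missing", "max_locus_missing", "min_maf", "ab_low", "ab_high"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ab_low >= self.ab_high:
            raise ValueError("ab_low must be below ab_high")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterReport:
    """Per-rule drop counts, recorded in application order."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    genotypes_set_missing: int = 0
    skipped_rules: list[str] = field(default_factory=list)
    input_shape: tuple[int, int] = (0, 0)
    output_shape: tuple[int, int] = (0, 0)

    def record(self, rule: str, n_dropped: int) -> None:
        self.steps.append((rule, int(n_dropped)))

    def count(self, rule: str) -> int:
        for name, n in self.steps:
            if name == rule:
                return n
        raise KeyError(rule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_dropped"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.loc[len(df)] = ["genotypes_set_missing", self.genotypes_set_missing]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class VCFData:
    """In-memory image of the annotated biallelic-SNP records of a VCF."""

    dosage: np.ndarray  # individuals x loci, reference dosage, -1 missing
    dp: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    qual: np.ndarray
    mqr: np.ndarray | None
    strand: np.ndarray | None
    contigs: list[str]
    locus_ids: list[str]
    individual_ids: list[str]
    n_non_biallelic: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def site_depth(self) -> np.ndarray:
        """Summed read depth over non-missing genotypes per site."""
        return np.where(self.dosage != MISSING, self.dp, 0).sum(axis=0)

    def mean_genotype_depth(self) -> np.ndarray:
        """Per-site mean depth per non-missing genotype."""
        n_obs = (self.dosage != MISSING).sum(axis=0)
        return self.site_depth() / np.maximum(n_obs, 1)

    def subset(self, individuals=None, loci=None) -> "VCFData":
        ind = np.arange(self.shape[0]) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.shape[1]) if loci is None else np.asarray(loci)
        ix = np.ix_(ind, loc)
        return VCFData(
            dosage=self.dosage[ix],
            dp=self.dp[ix],
            ad_ref=self.ad_ref[ix],
            ad_alt=self.ad_alt[ix],
            qual=self.qual[loc],
            mqr=None if self.mqr is None else self.mqr[loc],
            strand=None if self.strand is None else self.strand[loc],
            contigs=[self.contigs[j] for j in loc],
            locus_ids=[self.locus_ids[j] for j in loc],
            individual_ids=[self.individual_ids[i] for i in ind],
            n_non_biallelic=self.n_non_biallelic,
        )


def read_vcf(path: str | Path, mqr_key: str = "MQR", strand_key: str = "SB") -> VCFData:
    """Load biallelic SNPs (others dropped, counted) with annotations."""
    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    dos_rows, dp_rows, adr_rows, ada_rows = [], [], [], []
    quals, mqrs, strands, contigs, ids = [], [], [], [], []
    n_bad = 0
    for i, v in enumerate(vcf):
        if not v.is_snp or len(v.ALT) != 1:
            n_bad += 1
            continue
        gt = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        dos = np.select([gt == 0, gt == 1, gt == 2], [2, 1, 0], default=MISSING)
        dp = v.format("DP")
        dp = np.zeros(len(gt), dtype=np.int32) if dp is None else np.clip(dp[:, 0], 0, None)
        ad = v.format("AD")
        if ad is None:
            adr = np.zeros(len(gt), dtype=np.int32)
            ada = np.zeros(len(gt), dtype=np.int32)
        else:
            adr = np.clip(ad[:, 0], 0, None)
            ada = np.clip(ad[:, 1], 0, None)
        dos_rows.append(dos.astype(np.int8))
        dp_rows.append(dp.astype(np.int32))
        adr_rows.append(adr.astype(np.int32))
        ada_rows.append(ada.astype(np.int32))
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        mqrs.append(v.INFO.get(mqr_key))
        strands.append(v.INFO.get(strand_key))
        contigs.append(v.CHROM)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    n_loci = len(ids)
    mqr_arr = None
    if any(m is not None for m in mqrs):
        mqr_arr = np.array([np.nan if m is None else float(m) for m in mqrs])
    strand_arr = None
    if any(s is not None for s in strands):
        strand_arr = np.array([np.nan if s is None else float(s) for s in strands])
    return VCFData(
        dosage=np.array(dos_rows, dtype=np.int8).T if n_loci else np.empty((len(individuals), 0), np.int8),
        dp=np.array(dp_rows, dtype=np.int32).T if n_loci else np.empty((len(individuals), 0), np.int32),
        ad_ref=np.array(adr_rows, dtype=np.int32).T if n_loci else np.empty((len(individuals), 0), np.int32),
        ad_alt=np.array(ada_rows, dtype=np.int32).T if n_loci else np.empty((len(individuals), 0), np.int32),
        qual=np.asarray(quals, dtype=float),
        mqr=mqr_arr,
        strand=strand_arr,
        contigs=contigs,
        locus_ids=ids,
        individual_ids=individuals,
        n_non_biallelic=n_bad,
    )


def allele_balance_rule(ref_reads_het: int, total_reads_het: int, low: float = 0.25, high: float = 0.75) -> bool:
    """Keep/drop decision for one site from reads pooled over heterozygotes.

    Returns True (keep) when the pooled reference-read fraction lies in
    [low, high] or no heterozygote reads exist; boundaries keep (the drop
    thresholds are strict: ratio > high or < low drops).
    """
    if total_reads_het <= 0:
        return True
    ratio = ref_reads_het / total_reads_het
    return low <= ratio <= high


def depth_outlier_rule(
    site_depth: np.ndarray,
    qual: np.ndarray,
    multiplier: float = 3.0,
    qual_factor: float = 2.0,
    depth_percentile: float = 99.5,
    total_depth: np.ndarray | None = None,
) -> np.ndarray:
    """Keep-mask for the high-depth outlier rule.

    Sites whose depth exceeds ``multiplier x (mean depth)^2`` are flagged;
    flagged sites survive only with QUAL strictly above ``qual_factor``
    times the (total) depth, and flagged sites beyond the
    ``depth_percentile`` absolute-depth cutoff are dropped regardless.  In
    the cascade ``site_depth`` is the per-genotype mean depth (the scale on
    which a squared-mean threshold is meaningful) while ``total_depth`` is
    the summed site depth that QUAL scales with; by default both clauses
    use the same array.
    """
    site_depth = np.asarray(site_depth, dtype=float)
    qual = np.asarray(qual, dtype=float)
    total = site_depth if total_depth is None else np.asarray(total_depth, dtype=float)
    if len(site_depth) == 0:
        return np.ones(0, dtype=bool)
    threshold = multiplier * site_depth.mean() ** 2
    cutoff = np.percentile(site_depth, depth_percentile)
    flagged = site_depth > threshold
    drop = flagged & ((qual <= qual_factor * total) | (site_depth > cutoff))
    return ~drop


def apply_filter_cascade(
    vcf: str | Path | VCFData,
    config: FilterConfig | None = None,
    locality_of: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full cascade and return the filtered genotypes plus report.

    Rules run in a fixed order: (1) individuals missing more than
    ``max_ind_missing`` of loci; (2) loci missing in more than
    ``max_locus_missing`` of individuals; (3) MAF/MAC (primary dataset
    only); (4) site QUAL; (5) genotype depth (set missing); (6) allelic
    balance; (7) strand; (8) mapping-quality ratio; (9) QUAL vs depth;
    (10) high-depth outliers.
    """
    config = config or FilterConfig()
    data = (
        vcf
        if isinstance(vcf, VCFData)
        else read_vcf(vcf, mqr_key=config.mqr_key, strand_key=config.strand_key)
    )
    report = FilterReport(input_shape=data.shape)
    report.record("non_biallelic_records", data.n_non_biallelic)

    # (1) individual missingness
    missing = data.dosage == MISSING
    if data.shape[1] > 0:
        frac = missing.mean(axis=1)
        keep_ind = np.where(frac <= config.max_ind_missing)[0]
    else:
        keep_ind = np.arange(data.shape[0])
    report.record("individual_missingness", data.shape[0] - len(keep_ind))
    data = data.subset(individuals=keep_ind)

    # (2) locus missingness
    missing = data.dosage == MISSING
    frac = missing.mean(axis=0) if data.shape[0] else np.zeros(data.shape[1])
    keep = np.where(frac <= config.max_locus_missing)[0]
    report.record("locus_missingness", data.shape[1] - len(keep))
    data = data.subset(loci=keep)

    # (3) minor allele frequency / count
    if config.apply_maf:
        obs = data.dosage != MISSING
        x = np.where(obs, data.dosage, 0).sum(axis=0)
        n = 2 * obs.sum(axis=0)
        mac = np.minimum(x, n - x)
        with np.errstate(divide="ignore", invalid="ignore"):
            maf = np.where(n > 0, mac / n, 0.0)
        keep = np.where((maf >= config.min_maf) & (mac >= config.min_mac))[0]
        report.record("maf_mac", data.shape[1] - len(keep))
        data = data.subset(loci=keep)
    else:
        report.record("maf_mac", 0)
        report.skipped_rules.append("maf_mac")

    # (4) site quality
    keep = np.where(~(data.qual < config.min_qual))[0]
    report.record("site_quality", data.shape[1] - len(keep))
    data = data.subset(loci=keep)

    # (5) genotype depth -> missing
    shallow = (data.dosage != MISSING) & (data.dp < config.min_genotype_depth)
    report.genotypes_set_missing = int(shallow.sum())
    data.dosage = np.where(shallow, MISSING, data.dosage).astype(np.int8)
    report.record("genotype_depth", 0)  # masks genotypes, drops no sites

    # (6) allelic balance over heterozygotes
    het = data.dosage == 1
    ref_het = np.where(het, data.ad_ref, 0).sum(axis=0)
    tot_het = np.where(het, data.ad_ref + data.ad_alt, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tot_het > 0, ref_het / np.maximum(tot_het, 1), 0.5)
    keep = np.where((tot_het == 0) | ((ratio >= config.ab_low) & (ratio <= config.ab_high)))[0]
    report.record("allelic_balance", data.shape[1] - len(keep))
    data = data.subset(loci=keep)

    # (7) strand rule (off by default: single-end RAD data carry no
    # strand-balance annotation)
    if config.strand_rule:
        if data.strand is None:
            raise FilterConfigurationError(
                f"strand rule enabled but INFO key {config.strand_key!r} absent"
            )
        keep = np.where(~(data.strand > 0))[0]
        report.record("both_strands", data.shape[1] - len(keep))
        data = data.subset(loci=keep)
    else:
        report.record("both_strands", 0)
        report.skipped_rules.append("both_strands")

    # (8) mapping-quality ratio; without the annotation the rule is skipped
    # with a warning (hard error only when annotations are required)
    if config.mqr_rule and data.mqr is None:
        msg = f"mapping-quality-ratio rule enabled but INFO key {config.mqr_key!r} absent"
        if config.require_annotations:
            raise FilterConfigurationError(msg)
        warnings.warn(msg + "; rule skipped")
        report.record("mapping_quality_ratio", 0)
        report.skipped_rules.append("mapping_quality_ratio")
    elif config.mqr_rule:
        ok = (data.mqr > config.mqr_low) & (data.mqr < config.mqr_high)
        ok |= np.isnan(data.mqr)
        keep = np.where(ok)[0]
        report.record("mapping_quality_ratio", data.shape[1] - len(keep))
        data = data.subset(loci=keep)
    else:
        report.record("mapping_quality_ratio", 0)
        report.skipped_rules.append("mapping_quality_ratio")

    # (9) quality vs depth
    depth = data.site_depth()
    keep = np.where(~(data.qual < config.qual_depth_factor_low * depth))[0]
    report.record("quality_vs_depth", data.shape[1] - len(keep))
    data = data.subset(loci=keep)

    # (10) high-depth outliers
    keep_mask = depth_outlier_rule(
        data.mean_genotype_depth(),
        data.qual,
        config.high_depth_multiplier,
        config.qual_depth_factor_high,
        config.depth_percentile,
        total_depth=data.site_depth(),
    )
    report.record("high_depth_outliers", int((~keep_mask).sum()))
    data = data.subset(loci=np.where(keep_mask)[0])

    report.output_shape = data.shape
    locality = locality_of or _infer_localities(data.individual_ids)
    genotypes = GenotypeMatrix(
        dosage=data.dosage,
        individual_ids=data.individual_ids,
        locus_ids=data.locus_ids,
        contigs=data.contigs,
        locality_of=locality,
    )
    genotypes._vcf_data = data  # filtered annotations, used when re-writing
    return genotypes, report


def _infer_localities(individual_ids: list[str]) -> dict[str, str]:
    """Locality from the 'LOC_indN' naming convention; else one per sample."""
    out = {}
    for ind in individual_ids:
        out[ind] = ind.rsplit("_ind", 1)[0] if "_ind" in ind else ind
    return out


def write_vcf(data: VCFData, path: str | Path) -> Path:
    """Write records (with annotations) back out as VCF 4.2."""
    path = Path(path)
    n_ind, n_loci = data.shape
    gt_code = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQR,Number=1,Type=Float,Description="Ratio of mean mapping quality of reference over alternate allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        for contig in dict.fromkeys(data.contigs):
            fh.write(f"##contig=<ID={contig},length=1000>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.individual_ids)
            + "\n"
        )
        for l in range(n_loci):
            info = []
            if data.mqr is not None and not np.isnan(data.mqr[l]):
                info.append(f"MQR={data.mqr[l]:.4f}")
            cells = [
                f"{gt_code[int(data.dosage[i, l])]}:{int(data.dp[i, l])}:"
                f"{int(data.ad_ref[i, l])},{int(data.ad_alt[i, l])}"
                for i in range(n_ind)
            ]
            fh.write(
                f"{data.contigs[l]}\t100\t{data.locus_ids[l]}\tA\tT\t"
                f"{data.qual[l]:.2f}\t.\t{';'.join(info) or '.'}\tGT:DP:AD\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def filter_vcf_file(
    vcf_in: str | Path,
    vcf_out: str | Path | None = None,
    report_path: str | Path | None = None,
    config: FilterConfig | None = None,
    locality_of: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """File-level wrapper: filter, optionally writing VCF and report."""
    genotypes, report = apply_filter_cascade(vcf_in, config, locality_of)
    if vcf_out is not None:
        write_vcf(genotypes._vcf_data, vcf_out)
    if report_path is not None:
        report.write_tsv(report_path)
    return genotypes, report
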