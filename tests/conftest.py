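"""Shared fixtures: small gradient designs, synthetic datasets, and a
hand-built 200-site VCF whose per-rule filter outcomes are known exactly
by construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import gradientpanmixia as gp


@pytest.fixture(scope="session")
def gradient4() -> gp.LocalityTable:
    return gp.make_gradient_design(4, 730, 1175, 1.0, 10)


@pytest.fixture(scope="session")
def gradient8() -> gp.LocalityTable:
    return gp.make_gradient_design(8, 730, 1950, 1.0, 10)


def decorrelated_design(
    n_localities: int = 10, n_per_locality: int = 10, seed: int = 42
) -> gp.LocalityTable:
    """Gradient design with elevations shuffled along the geographic line.

    The default transect confounds geography with environment exactly
    (correlation 1); shuffling decorrelates them so both decay rates of the
    IBE model are identifiable.
    """
    loc = gp.make_gradient_design(n_localities, 500, 2000, 2.0, n_per_locality)
    rng = np.random.default_rng(seed)
    t = loc.table.copy()
    perm = rng.permutation(n_localities)
    for col in ["elevation", "mean_annual_temperature", "mean_annual_precipitation"]:
        t[col] = t[col].to_numpy()[perm]
    return gp.LocalityTable(t)


@pytest.fixture(scope="session")
def small_dataset(gradient4):
    cfg = gp.SimConfig(seed=11, n_loci=300, missing_rate=0.05)
    genotypes, freqs, dist = gp.simulate_dataset(gradient4, cfg)
    return genotypes, freqs, dist, cfg


# ---------------------------------------------------------------------------
# hand-built filter fixture

N_CLEAN = 136
CATEGORIES = {  # category -> number of sites
    "locmiss": 12,
    "mac": 15,
    "qual": 8,
    "gdepth": 10,
    "ab": 7,
    "mqr": 6,
    "qd": 5,
    "hidepth": 1,
}

EXPECTED_PRIMARY = {
    "non_biallelic_records": 0,
    "individual_missingness": 1,
    "locus_missingness": 12,
    "maf_mac": 15,
    "site_quality": 8,
    "genotype_depth": 0,
    "allelic_balance": 7,
    "both_strands": 0,
    "mapping_quality_ratio": 6,
    "quality_vs_depth": 5,
    "high_depth_outliers": 1,
}
EXPECTED_GENOTYPES_MASKED = 20  # 10 'gdepth' sites x 2 shallow genotypes
EXPECTED_PRIMARY_SHAPE = (11, 136 + 10)  # clean + depth-masked sites survive
EXPECTED_SECONDARY_SHAPE = (11, 136 + 10 + 15)  # MAC singletons retained


@dataclass
class SiteSpec:
    qual: float
    mqr: float
    cells: list[str]  # GT:DP:AD for the 11 scored individuals


def _site(category: str) -> SiteSpec:
    """One VCF record; individuals are P1_ind2..6 then P2_ind1..6."""
    hom = "0/0:10:10,0"
    het = "0/1:10:5,5"
    cells = [hom] * 11
    qual, mqr = 60.0, 1.0
    if category == "clean":
        for i in (0, 1, 5):  # P1_ind2, P1_ind3, P2_ind1: MAC 3, MAF 3/22
            cells[i] = het
    elif category == "locmiss":
        for i in (0, 1, 2, 5):  # 4/11 = 36% missing > 25%
            cells[i] = "./.:0:0,0"
        for i in (6, 7, 8):
            cells[i] = het
    elif category == "mac":  # singleton: MAC 1 < 3, MAF 0.045 < 0.05
        cells[6] = het
    elif category == "qual":  # Phred 25 < 30
        for i in (0, 1, 5):
            cells[i] = het
        qual = 25.0
    elif category == "gdepth":  # two genotypes below 5 reads -> masked
        for i in (0, 1, 5):
            cells[i] = het
        cells[9] = "0/0:3:3,0"
        cells[10] = "0/0:3:3,0"
    elif category == "ab":  # pooled het balance 27/30 = 0.9 > 0.75
        for i in (0, 1, 5):
            cells[i] = "0/1:10:9,1"
    elif category == "mqr":  # ratio outside (0.9, 1.05)
        for i in (0, 1, 5):
            cells[i] = het
        mqr = 1.2
    elif category == "qd":  # QUAL 50 < 0.25 x summed depth 440
        cells = ["0/0:40:40,0"] * 11
        for i in (0, 1, 5):
            cells[i] = "0/1:40:20,20"
        qual = 50.0
    elif category == "hidepth":  # mean genotype depth 2000 >> 3 x mean^2
        cells = ["0/0:2000:2000,0"] * 11
        for i in (0, 1, 5):
            cells[i] = "0/1:2000:1000,1000"
        qual = 6000.0  # survives QUAL >= 0.25 x 22000, fails 10's clauses
    else:
        raise ValueError(category)
    return SiteSpec(qual=qual, mqr=mqr, cells=cells)


def build_filter_fixture(path) -> None:
    """200 biallelic sites over 12 individuals; P1_ind1 is fully missing."""
    individuals = [f"P1_ind{i}" for i in range(1, 7)] + [f"P2_ind{i}" for i in range(1, 7)]
    site_plan = ["clean"] * N_CLEAN
    for cat, n in CATEGORIES.items():
        site_plan += [cat] * n
    assert len(site_plan) == 200
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQR,Number=1,Type=Float,Description="Mapping quality ratio">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for l in range(200):
            fh.write(f"##contig=<ID=ctg{l+1},length=1000>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for l, cat in enumerate(site_plan):
            s = _site(cat)
            cells = ["./.:0:0,0"] + s.cells  # P1_ind1 always missing
            fh.write(
                f"ctg{l+1}\t100\t{cat}_{l+1}\tA\tT\t{s.qual:.2f}\t.\t"
                f"MQR={s.mqr:.4f}\tGT:DP:AD\t" + "\t".join(cells) + "\n"
            )


@pytest.fixture(scope="session")
def filter_fixture_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("filter") / "fixture200.vcf"
    build_filter_fixture(path)
    return path
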