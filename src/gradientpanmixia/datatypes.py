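"""Core in-memory containers shared across the pipeline.

Genotypes are diploid dosages of the *reference* allele (0, 1, 2) with -1
marking a missing call.  Allele counts are reference-allele counts ``x`` out
of ``n`` sampled alleles per population x locus.  All tables round-trip
through tab-separated text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

LOCALITY_COLUMNS = [
    "locality_id",
    "latitude",
    "longitude",
    "elevation",
    "mean_annual_temperature",
    "mean_annual_precipitation",
    "n_individuals",
]


@dataclass
class LocalityTable:
    """Sampling localities along a gradient, one row per locality.

    Environmental variables (elevation in m, mean annual temperature in
    deg C, mean annual precipitation in mm) are consumed as given; no raster
    extraction happens here.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOCALITY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"locality table missing columns: {missing}")
        t = self.table
        if t["locality_id"].duplicated().any():
            raise ValueError("locality_ids must be unique")
        if not ((t["latitude"].between(-90, 90)).all()):
            raise ValueError("latitudes must lie in [-90, 90]")
        if not ((t["longitude"].between(-180, 180)).all()):
            raise ValueError("longitudes must lie in [-180, 180]")
        if (t["n_individuals"] < 1).any():
            raise ValueError("each locality needs n_individuals >= 1")
        if not np.isfinite(t["elevation"].to_numpy(float)).all():
            raise ValueError("elevations must be finite")
        self.table = t.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["locality_id"].astype(str).tolist()

    @property
    def n_localities(self) -> int:
        return len(self.table)

    @property
    def elevation(self) -> np.ndarray:
        return self.table["elevation"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LocalityTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GenotypeMatrix:
    """Individuals x loci reference-allele dosages with locality assignment.

    dosage[i, l] in {0, 1, 2} or MISSING (-1).  ``contigs`` labels the contig
    of each locus so LD pruning can stay within assembly units.
    """

    dosage: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    contigs: list[str]
    locality_of: dict[str, str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_ind, n_loc = self.dosage.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length mismatch")
        if len(self.locus_ids) != n_loc or len(self.contigs) != n_loc:
            raise ValueError("locus metadata length mismatch")
        bad = set(self.individual_ids) - set(self.locality_of)
        if bad:
            raise ValueError(f"individuals with no locality: {sorted(bad)[:5]}")
        vals = np.unique(self.dosage)
        if not np.isin(vals, [MISSING, 0, 1, 2]).all():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def localities(self) -> list[str]:
        """Locality labels in order of first appearance among individuals."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.locality_of[ind], None)
        return list(seen)

    def locality_indices(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individual_ids):
            groups.setdefault(self.locality_of[ind], []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc_idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(ind_idx, loc_idx)],
            individual_ids=[self.individual_ids[i] for i in ind_idx],
            locus_ids=[self.locus_ids[j] for j in loc_idx],
            contigs=[self.contigs[j] for j in loc_idx],
            locality_of=self.locality_of,
        )


@dataclass
class AlleleCountTable:
    """Per population x locus reference-allele counts and sampled totals."""

    ref_count: np.ndarray
    total_alleles: np.ndarray
    population_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.total_alleles = np.asarray(self.total_alleles, dtype=np.int64)
        if self.ref_count.shape != self.total_alleles.shape:
            raise ValueError("ref_count and total_alleles shapes differ")
        if ((self.ref_count < 0) | (self.ref_count > self.total_alleles)).any():
            raise ValueError("need 0 <= x_kl <= n_kl")

    @property
    def n_populations(self) -> int:
        return self.ref_count.shape[0]

    @property
    def n_loci(self) -> int:
        return self.ref_count.shape[1]

    def frequencies(self) -> np.ndarray:
        """Sample reference-allele frequencies; NaN where n_kl == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.total_alleles > 0, self.ref_count / self.total_alleles, np.nan
            )

    def write_tsv(self, path: str | Path) -> None:
        x = pd.DataFrame(self.ref_count, index=self.population_ids, columns=self.locus_ids)
        n = pd.DataFrame(self.total_alleles, index=self.population_ids, columns=self.locus_ids)
        long = pd.concat({"ref_count": x.stack(), "total_alleles": n.stack()}, axis=1)
        long.index.names = ["population", "locus"]
        long.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlleleCountTable":
        long = pd.read_csv(path, sep="\t")
        x = long.pivot(index="population", columns="locus", values="ref_count")
        n = long.pivot(index="population", columns="locus", values="total_alleles")
        n = n.loc[x.index, x.columns]
        return cls(
            ref_count=x.to_numpy(),
            total_alleles=n.to_numpy(),
            population_ids=[str(p) for p in x.index],
            locus_ids=[str(c) for c in x.columns],
        )


@dataclass
class DistanceMatrices:
    """Paired geographic (km) and environmental distances between localities.

    ``sd_D`` and ``sd_E`` hold the standard deviations used to standardize
    each matrix; inference runs on the standardized matrices and the
    constants back-transform posterior decay rates to raw distance units.
    """

    D: np.ndarray
    E: np.ndarray
    ids: list[str]
    sd_D: float = field(default=np.nan)
    sd_E: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        for name, m in (("D", self.D), ("E", self.E)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if (m < 0).any():
                raise ValueError(f"{name} must be non-negative")
            if not np.allclose(np.diag(m), 0.0):
                raise ValueError(f"{name} must have a zero diagonal")
        if self.D.shape != self.E.shape:
            raise ValueError("D and E shapes differ")
        if np.isnan(self.sd_D):
            self.sd_D = _offdiag_sd(self.D)
        if np.isnan(self.sd_E):
            self.sd_E = _offdiag_sd(self.E)

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def D_std(self) -> np.ndarray:
        """Geographic distances divided by their standard deviation."""
        return self.D / self.sd_D if self.sd_D > 0 else self.D.copy()

    @property
    def E_std(self) -> np.ndarray:
        return self.E / self.sd_E if self.sd_E > 0 else self.E.copy()

    def write_tsv(self, path_D: str | Path, path_E: str | Path) -> None:
        for path, m in ((path_D, self.D), (path_E, self.E)):
            pd.DataFrame(m, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path_D: str | Path, path_E: str | Path) -> "DistanceMatrices":
        d = pd.read_csv(path_D, sep="\t", index_col=0)
        e = pd.read_csv(path_E, sep="\t", index_col=0)
        return cls(D=d.to_numpy(), E=e.to_numpy(), ids=[str(i) for i in d.index])


@dataclass
class SFS:
    """Site frequency spectrum aggregated over loci.

    ``xi[i-1]`` counts sites with (minor, if folded) allele count i.  Folded
    spectra run i = 1..floor(n/2); unfolded spectra (relative to the
    reference allele) run i = 1..n-1.  Monomorphic sites are excluded, so
    xi sums to the segregating-site count.
    """

    xi: np.ndarray
    n: int
    n_loci: int = 0
    folded: bool = True

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.int64)
        expected = self.n // 2 if self.folded else self.n - 1
        if len(self.xi) != expected:
            raise ValueError(
                f"xi length {len(self.xi)} != {expected} for n={self.n}, folded={self.folded}"
            )
        if (self.xi < 0).any():
            raise ValueError("xi counts must be non-negative")

    @property
    def segregating_sites(self) -> int:
        return int(self.xi.sum())

    def proportions(self) -> np.ndarray:
        """xi normalized to sum 1; all-zero for a monomorphic spectrum."""
        s = self.xi.sum()
        return self.xi / s if s > 0 else np.zeros_like(self.xi, dtype=float)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"allele_count": np.arange(1, len(self.xi) + 1), "n_sites": self.xi}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, n: int, folded: bool = True) -> "SFS":
        df = pd.read_csv(path, sep="\t")
        return cls(xi=df["n_sites"].to_numpy(), n=n, folded=folded)


def _offdiag_sd(m: np.ndarray) -> float:
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def upper_triangle(m: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle values of a square matrix, row-major."""
    m = np.asarray(m)
    return m[np.triu_indices(m.shape[0], k=1)]
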