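"""Shared in-memory containers for the pool-seq landscape-genomics pipeline.

The raw observable is :class:`PoolCounts` — per-SNP, per-stand read depths for
the reference and alternate allele of a pooled sample.  Everything downstream
(allele frequencies, distance matrices, outlier reports) is derived from it
plus a stand metadata table and per-scenario climate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: The seven climate variables used throughout (temperature / aridity summaries
#: of the study region): Aridity Index Thornthwaite, Climatic Moisture Index,
#: Continentality, growing degree days above 0C and 5C, max temperature of the
#: coldest month, and potential evapotranspiration of the coldest quarter.
CLIMATE_VARIABLES = ("AIT", "CMT", "CONT", "DegD0", "DegD5", "MTC", "PCQ")

STAND_TYPES = ("old", "planted")


@dataclass(frozen=True)
class StandInfo:
    """Metadata for one forest stand (one sequencing pool)."""

    stand_id: str
    stand_type: str  # "old" | "planted"
    locality: int
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.stand_type not in STAND_TYPES:
            raise ValueError(f"stand_type must be one of {STAND_TYPES}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError("longitude out of range [-180, 180]")


def stands_to_frame(stands: Sequence[StandInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stand_id": [s.stand_id for s in stands],
            "stand_type": [s.stand_type for s in stands],
            "locality": [s.locality for s in stands],
            "latitude": [s.latitude for s in stands],
            "longitude": [s.longitude for s in stands],
        }
    )


def stands_from_frame(df: pd.DataFrame) -> list[StandInfo]:
    return [
        StandInfo(
            stand_id=str(r.stand_id),
            stand_type=str(r.stand_type),
            locality=int(r.locality),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class PoolCounts:
    """Reference/alternate read depths per SNP and pooled stand.

    Arrays are SNPs x stands.  ``haploid_size`` is the number of haploid
    genomes in each pool (2 x pooled diploid trees).
    """

    snp_ids: np.ndarray          # (L,) str
    contig: np.ndarray           # (L,) str
    pos: np.ndarray              # (L,) int, 1-based
    ref_allele: np.ndarray       # (L,) str
    alt_allele: np.ndarray       # (L,) str
    ref_depth: np.ndarray        # (L, S) int
    alt_depth: np.ndarray        # (L, S) int
    stand_ids: list[str]
    haploid_size: np.ndarray     # (S,) int

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        self.haploid_size = np.asarray(self.haploid_size, dtype=np.int64)
        L, S = self.ref_depth.shape
        if self.alt_depth.shape != (L, S):
            raise ValueError("ref_depth and alt_depth shapes differ")
        if len(self.stand_ids) != S or self.haploid_size.shape != (S,):
            raise ValueError("stand dimension mismatch")
        if len(self.snp_ids) != L:
            raise ValueError("snp dimension mismatch")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("negative read depths")
        if (self.haploid_size < 2).any():
            raise ValueError("haploid pool size must be >= 2")

    @property
    def n_snps(self) -> int:
        return self.ref_depth.shape[0]

    @property
    def n_stands(self) -> int:
        return self.ref_depth.shape[1]

    @property
    def total_depth(self) -> np.ndarray:
        """(L, S) total read depth."""
        return self.ref_depth + self.alt_depth

    def subset_snps(self, mask_or_ids) -> "PoolCounts":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:
            wanted = set(arr.tolist())
            idx = np.flatnonzero([s in wanted for s in self.snp_ids])
        return replace(
            self,
            snp_ids=self.snp_ids[idx],
            contig=np.asarray(self.contig)[idx],
            pos=np.asarray(self.pos)[idx],
            ref_allele=np.asarray(self.ref_allele)[idx],
            alt_allele=np.asarray(self.alt_allele)[idx],
            ref_depth=self.ref_depth[idx],
            alt_depth=self.alt_depth[idx],
        )

    def subset_stands(self, stand_ids: Sequence[str]) -> "PoolCounts":
        pos = {s: i for i, s in enumerate(self.stand_ids)}
        missing = [s for s in stand_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown stand ids: {missing}")
        idx = np.array([pos[s] for s in stand_ids])
        return replace(
            self,
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            stand_ids=list(stand_ids),
            haploid_size=self.haploid_size[idx],
        )


@dataclass
class FrequencyMatrix:
    """Alternate-allele frequencies, stands x SNPs, all entries in [0, 1]."""

    values: np.ndarray           # (S, L)
    stand_ids: list[str]
    snp_ids: np.ndarray          # (L,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        S, L = self.values.shape
        if len(self.stand_ids) != S or len(self.snp_ids) != L:
            raise ValueError("dimension mismatch")
        if np.isnan(self.values).any():
            raise ValueError("missing frequencies not allowed")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_stands(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.stand_ids, columns=self.snp_ids)

    def subset_stands(self, stand_ids: Sequence[str]) -> "FrequencyMatrix":
        pos = {s: i for i, s in enumerate(self.stand_ids)}
        idx = np.array([pos[s] for s in stand_ids])
        return FrequencyMatrix(self.values[idx], list(stand_ids), self.snp_ids)

    def subset_snps(self, snp_ids) -> "FrequencyMatrix":
        wanted = set(np.asarray(snp_ids).tolist())
        mask = np.array([s in wanted for s in self.snp_ids])
        return FrequencyMatrix(self.values[:, mask], list(self.stand_ids), self.snp_ids[mask])


@dataclass
class ClimateTable:
    """Stands x 7 climate variables for one scenario ("current" or "future")."""

    data: pd.DataFrame           # index: stand_id; columns: CLIMATE_VARIABLES
    scenario: str = "current"

    def __post_init__(self) -> None:
        missing = [v for v in CLIMATE_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValueError(f"climate table missing variables: {missing}")
        self.data = self.data.loc[:, list(CLIMATE_VARIABLES)].astype(float)
        if self.data.isna().any().any():
            raise ValueError("climate table contains missing values")

    @property
    def stand_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> tuple[str, ...]:
        return CLIMATE_VARIABLES

    def subset_stands(self, stand_ids: Sequence[str]) -> "ClimateTable":
        return ClimateTable(self.data.loc[list(stand_ids)], self.scenario)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns.

    FST entries may be slightly negative (estimator noise) and are kept as-is;
    geographic and climate distances are non-negative.
    """

    labels: list[str]
    values: np.ndarray           # (S, S)
    kind: str = "fst"            # fst | geographic_km | climate | fst_background | fst_outlier

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("labels / matrix size mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.labels)}
        idx = np.array([pos[s] for s in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class OutlierReport:
    """Per-SNP x climate-variable association calls for one stand set.

    ``table`` columns: snp_id, variable, statistic (Pearson r for the
    correlation method; recalibrated -log10 scale handled by ``p``), p
    (lfmm only, NaN otherwise), passes (bool).
    """

    table: pd.DataFrame
    method: str                  # "correlation" | "lfmm"
    stand_set: str               # "old" | "planted" | "all"
    threshold: float             # r* for correlation, Bonferroni p* for lfmm

    def __post_init__(self) -> None:
        required = {"snp_id", "variable", "statistic", "passes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"outlier table missing columns: {sorted(missing)}")
        if "p" not in self.table.columns:
            self.table = self.table.assign(p=np.nan)

    def outlier_snps(self, variable: str | None = None) -> np.ndarray:
        """SNP ids passing the threshold, optionally for one variable."""
        t = self.table
        if variable is not None:
            t = t[t["variable"] == variable]
        return t.loc[t["passes"], "snp_id"].unique()


@dataclass
class FilterReport:
    """Per-rule SNP removal counts from the coverage/MAF filter."""

    n_input: int
    removed_min_cov: int
    removed_cov_quantile: int
    removed_maf: int
    n_retained: int
    cov_quantile_bounds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_min_cov": self.removed_min_cov,
            "removed_cov_quantile": self.removed_cov_quantile,
            "removed_maf": self.removed_maf,
            "n_retained": self.n_retained,
        }
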