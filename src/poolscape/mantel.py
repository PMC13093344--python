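"""Isolation by distance / isolation by environment via (partial) Mantel tests.

Distance matrices are vectorised over the strictly lower triangle.  The
simple Mantel statistic is the Pearson correlation of two such vectors; the
partial statistic controls a third matrix through the first-order partial
correlation.  Significance is assessed by simultaneously permuting the rows
and columns of the first matrix and recomputing the (partial) statistic,
one-sided in the upper tail (the vegan convention), with

    p = (#{permuted >= observed} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import (
    CLIMATE_VARIABLES,
    ClimateTable,
    DistanceMatrix,
    OutlierReport,
    PoolCounts,
    StandInfo,
)
from .popgen import geographic_distance, pairwise_fst

__all__ = [
    "climate_distance",
    "split_fst",
    "mantel_test",
    "partial_mantel",
    "MantelResult",
    "ibd_ibe_report",
]


def climate_distance(
    climate: ClimateTable, variables: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance in standardized multi-dimensional climate space.

    Each variable is standardized to zero mean / unit variance across stands
    before computing pairwise Euclidean distances.  With a single variable
    this reduces to the absolute standardized difference (used for the
    per-variable environmental distances).  Zero-variance variables are
    excluded with a warning.
    """
    if len(climate.stand_ids) < 2:
        raise ValueError("need at least 2 stands")
    cols = list(variables) if variables is not None else list(climate.variables)
    z = climate.data[cols].to_numpy()
    sd = z.std(axis=0, ddof=1)
    if (sd == 0.0).any():
        bad = [c for c, s in zip(cols, sd) if s == 0.0]
        warnings.warn(f"zero-variance climate variable(s) excluded: {bad}", stacklevel=2)
        keep = sd > 0.0
        z, sd, cols = z[:, keep], sd[keep], [c for c, k in zip(cols, keep) if k]
    if z.shape[1] == 0:
        raise ValueError("no non-constant climate variables")
    z = (z - z.mean(axis=0)) / sd
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(list(climate.stand_ids), d, kind="climate")


def split_fst(
    pc: PoolCounts, outliers: OutlierReport, outlier_snps=None
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """FST matrices from outlier SNPs and from all remaining (background) SNPs.

    The two SNP sets are disjoint and their union is all SNPs in ``pc``.  By
    default the outlier set is every SNP passing for any climate variable in
    ``outliers``; pass ``outlier_snps`` to restrict it (e.g. to one variable).
    """
    snps = outliers.outlier_snps() if outlier_snps is None else np.asarray(outlier_snps)
    wanted = set(np.asarray(snps).tolist())
    mask = np.array([s in wanted for s in pc.snp_ids])
    if not mask.any():
        raise ValueError("empty outlier set; run a gene-environment analysis first")
    if mask.all():
        raise ValueError("outlier set contains every SNP; background FST undefined")
    fst_out = pairwise_fst(pc.subset_snps(mask))
    fst_bg = pairwise_fst(pc.subset_snps(~mask))
    fst_out.kind = "fst_outlier"
    fst_bg.kind = "fst_background"
    return fst_out, fst_bg


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool
    matrices: tuple[str, ...]


def _aligned_vectors(*mats: DistanceMatrix) -> tuple[list[str], list[np.ndarray]]:
    labels = list(mats[0].labels)
    vecs = []
    for m in mats:
        if list(m.labels) != labels:
            if set(m.labels) != set(labels):
                raise ValueError("distance matrices have different label sets")
            m = m.reorder(labels)
        vecs.append(m.condensed())
    return labels, vecs


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def _permuted_rows(d: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Lower-triangle vectors of ``d`` under ``n_perm`` label permutations."""
    n = d.shape[0]
    i, j = np.tril_indices(n, k=-1)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    return d[perms[:, i], perms[:, j]]


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    return (Xc @ yc) / (np.linalg.norm(Xc, axis=1) * np.linalg.norm(yc))


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Permutes the labels of ``d1``, one-sided upper tail.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, (v1, v2) = _aligned_vectors(d1, d2)
    r_obs = _pearson(v1, v2)
    rng = np.random.default_rng(seed)
    mat1 = d1.reorder(labels).values
    perm_vecs = _permuted_rows(mat1, n_perm, rng)
    r_perm = _pearson_rows(perm_vecs, v2)
    p = (float((r_perm >= r_obs).sum()) + 1.0) / (n_perm + 1.0)
    return MantelResult(r_obs, p, n_perm, False, (d1.kind, d2.kind))


def _partial_r(r12, r13, r23):
    denom = np.sqrt((1.0 - r13**2) * (1.0 - r23**2))
    return (r12 - r13 * r23) / denom


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d3: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel correlation of ``d1`` and ``d2`` controlling for ``d3``.

    The first-order partial correlation is recomputed for every permutation
    of ``d1``'s labels; one-sided upper tail.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, (v1, v2, v3) = _aligned_vectors(d1, d2, d3)
    r12 = _pearson(v1, v2)
    r13 = _pearson(v1, v3)
    r23 = _pearson(v2, v3)
    if abs(r13) >= 1.0 - 1e-12 or abs(r23) >= 1.0 - 1e-12:
        raise ValueError("control matrix perfectly correlated; partial r undefined")
    r_obs = float(_partial_r(r12, r13, r23))
    rng = np.random.default_rng(seed)
    mat1 = d1.reorder(labels).values
    perm_vecs = _permuted_rows(mat1, n_perm, rng)
    r12p = _pearson_rows(perm_vecs, v2)
    r13p = _pearson_rows(perm_vecs, v3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = _partial_r(r12p, r13p, r23)
    p = (float((r_perm >= r_obs).sum()) + 1.0) / (n_perm + 1.0)
    return MantelResult(r_obs, p, n_perm, True, (d1.kind, d2.kind, d3.kind))


def ibd_ibe_report(
    stands: list[StandInfo],
    pc: PoolCounts,
    outlier_reports: dict[str, OutlierReport],
    climate_current: ClimateTable,
    climate_future: ClimateTable,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable partial-Mantel IBE table plus the IBD/geo-climate summary.

    ``outlier_reports`` maps "{method}:{stand_set}" (e.g. "correlation:old")
    to the outlier report computed on that stand subset.  For every report,
    climate variable and scenario, the outlier-SNP FST matrix (SNPs passing
    for that variable) is tested against the single-variable standardized
    climate distance, controlling for background FST (all SNPs outside the
    report's full outlier set).  Variables with no outliers yield NaN rows.

    The second returned table holds, per stand set, plain Mantel IBD
    (geographic vs all-SNP FST) and the geographic-vs-climate correlation.
    """
    rng_seq = np.random.SeedSequence(seed)
    stand_sets = {
        "old": [s.stand_id for s in stands if s.stand_type == "old"],
        "planted": [s.stand_id for s in stands if s.stand_type == "planted"],
    }
    ibe_rows = []
    for key, report in outlier_reports.items():
        method, stand_set = key.split(":")
        ids = stand_sets[stand_set]
        sub = pc.subset_stands(ids)
        union_snps = report.outlier_snps()
        union = set(union_snps.tolist())
        fst_bg = None
        if 0 < len(union) < pc.n_snps:
            mask_bg = np.array([s not in union for s in pc.snp_ids])
            fst_bg = pairwise_fst(sub.subset_snps(mask_bg))
            fst_bg.kind = "fst_background"
        for variable in CLIMATE_VARIABLES:
            var_snps = report.outlier_snps(variable)
            fst_out = None
            if fst_bg is not None and len(var_snps) >= 2:
                wanted = set(var_snps.tolist())
                mask_out = np.array([s in wanted for s in pc.snp_ids])
                fst_out = pairwise_fst(sub.subset_snps(mask_out))
                fst_out.kind = "fst_outlier"
            for scenario, climate in (("current", climate_current), ("future", climate_future)):
                sub_seed = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                if fst_out is None:
                    ibe_rows.append(
                        {
                            "method": method,
                            "stand_set": stand_set,
                            "variable": variable,
                            "scenario": scenario,
                            "n_outlier_snps": len(var_snps),
                            "partial_r": np.nan,
                            "p": np.nan,
                        }
                    )
                    continue
                dclim = climate_distance(
                    climate.subset_stands(ids), variables=[variable]
                )
                res = partial_mantel(fst_out, dclim, fst_bg, n_perm=n_perm, seed=sub_seed)
                ibe_rows.append(
                    {
                        "method": method,
                        "stand_set": stand_set,
                        "variable": variable,
                        "scenario": scenario,
                        "n_outlier_snps": len(var_snps),
                        "partial_r": res.r,
                        "p": res.p,
                    }
                )
    ibe = pd.DataFrame(ibe_rows)

    ibd_rows = []
    stands_by_id = {s.stand_id: s for s in stands}
    for stand_set, ids in stand_sets.items():
        sub_stands = [stands_by_id[i] for i in ids]
        geo = geographic_distance(sub_stands)
        fst_all = pairwise_fst(pc.subset_stands(ids))
        dclim = climate_distance(climate_current.subset_stands(ids))
        s1 = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        s2 = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        ibd = mantel_test(fst_all, geo, n_perm=n_perm, seed=s1)
        geo_clim = mantel_test(dclim, geo, n_perm=n_perm, seed=s2)
        ibd_rows.append(
            {
                "stand_set": stand_set,
                "ibd_r": ibd.r,
                "ibd_p": ibd.p,
                "geo_climate_r": geo_clim.r,
                "geo_climate_p": geo_clim.p,
            }
        )
    return ibe, pd.DataFrame(ibd_rows)
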