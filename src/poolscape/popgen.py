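"""Neutral-variation statistics from pooled read counts.

Pairwise FST uses an ANOVA / method-of-moments estimator for Pool-Seq data
in the Hivert et al. (2018) family.  Reads are treated as the observations;
because the ``c`` reads of a pool resample only ``n`` haploid genomes with
replacement, the within-pool mean square must be rescaled before it
estimates within-deme diversity.  Writing a = 1 - Q1 (expected heterozygosity
within demes) and b = 1 - Q2 (between demes), FST = (b - a)/b, and with
per-pool depths c_i and haploid sizes n_i the read-level sums of squares have

    E[SSI] = (a/2) * S_a,            S_a = sum_i (c_i - 1)(1 - 1/n_i)
    E[SSP] = (a/2)(T_a - S_a) + (b/2) U,
                                     T_a = sum_i c_i (c_i - 1)(1 - 1/n_i)/C1
                                     U   = C1 - C2/C1

with C1 = sum_i c_i, C2 = sum_i c_i^2.  Solving gives per-locus unbiased
components a_hat, b_hat; the multilocus estimate is the ratio of sums
sum_l (b_hat - a_hat) / sum_l b_hat, which reduces to the classical
Weir-Cockerham ANOVA ratio (with read depth playing the sample-size role)
when pools are effectively infinite.  Negative estimates are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, PoolCounts, StandInfo

__all__ = [
    "pairwise_fst",
    "fst_pair",
    "outgroup_f3",
    "f3_locality_scan",
    "F3Result",
    "diversity_stats",
    "haversine_km",
    "geographic_distance",
]

EARTH_RADIUS_KM = 6371.0088


def _fst_components(
    y: np.ndarray, c: np.ndarray, n_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (a_hat, b_hat) for a set of pools.

    ``y``: alt read counts (L, P); ``c``: depths (L, P); ``n_h``: haploid pool
    sizes (P,).  Loci where any pool has depth < 2 yield NaN components.
    """
    c = c.astype(float)
    usable = (c >= 2).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = y / c
        C1 = c.sum(axis=1)
        C2 = (c**2).sum(axis=1)
        w = 1.0 - 1.0 / n_h[None, :]
        S_a = ((c - 1.0) * w).sum(axis=1)
        T_a = (c * (c - 1.0) * w).sum(axis=1) / C1
        U = C1 - C2 / C1
        pbar = y.sum(axis=1) / C1
        SSI = (c * phat * (1.0 - phat)).sum(axis=1)
        SSP = (c * (phat - pbar[:, None]) ** 2).sum(axis=1)
        a_hat = 2.0 * SSI / S_a
        b_hat = (2.0 * SSP + a_hat * (S_a - T_a)) / U
    a_hat[~usable] = np.nan
    b_hat[~usable] = np.nan
    return a_hat, b_hat


def fst_pair(
    y1: np.ndarray, c1: np.ndarray, n1: int, y2: np.ndarray, c2: np.ndarray, n2: int
) -> float:
    """Multilocus pool-seq FST between two pools (ratio of sums over loci)."""
    y = np.stack([y1, y2], axis=1)
    c = np.stack([c1, c2], axis=1)
    a_hat, b_hat = _fst_components(y, c, np.array([n1, n2]))
    ok = np.isfinite(a_hat) & np.isfinite(b_hat)
    if not ok.any():
        raise ValueError("no usable loci for FST (need depth >= 2 in both pools)")
    num = (b_hat[ok] - a_hat[ok]).sum()
    den = b_hat[ok].sum()
    if den == 0.0:
        raise ValueError("zero FST denominator (no variation at usable loci)")
    return float(num / den)


def pairwise_fst(pc: PoolCounts) -> DistanceMatrix:
    """All pairwise multilocus FST values between stands."""
    if pc.n_stands < 2:
        raise ValueError("need at least 2 stands")
    if pc.n_snps < 1:
        raise ValueError("need at least 1 SNP")
    S = pc.n_stands
    out = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            f = fst_pair(
                pc.alt_depth[:, i], pc.total_depth[:, i], int(pc.haploid_size[i]),
                pc.alt_depth[:, j], pc.total_depth[:, j], int(pc.haploid_size[j]),
            )
            out[i, j] = out[j, i] = f
    return DistanceMatrix(list(pc.stand_ids), out, kind="fst")


@dataclass(frozen=True)
class F3Result:
    """Outgroup f3 = E[(p_out - p_1)(p_out - p_2)] with block-jackknife SE.

    Larger values mean the two source stands share more genetic drift
    relative to the outgroup, i.e. are more similar to each other.
    """

    outgroup: str
    source1: str
    source2: str
    f3: float
    jackknife_se: float
    z: float
    n_loci: int
    n_blocks: int


def _pool_freq_and_var(pc: PoolCounts, idx: int):
    """Per-locus frequency estimate and an unbiased sampling-variance estimate.

    The estimate p_hat = alt/c has sampling variance p(1-p)(1/n + 1/c - 1/(nc))
    from haplotype sampling into the pool plus read resampling; p(1-p) is
    estimated without bias by p_hat(1-p_hat) * c/((c-1)(1-1/n)).
    """
    c = pc.total_depth[:, idx].astype(float)
    n = float(pc.haploid_size[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = pc.alt_depth[:, idx] / c
        h = p * (1.0 - p) * c / ((c - 1.0) * (1.0 - 1.0 / n))
        v = h * (1.0 / n + 1.0 / c - 1.0 / (n * c))
    return p, v, c


def outgroup_f3(
    pc: PoolCounts,
    source1: str,
    source2: str,
    outgroup: str,
    block_size: int = 500,
) -> F3Result:
    """Outgroup f3 with the outgroup's squared-term bias correction.

    The naive locus average of (p_out - p_1)(p_out - p_2) is biased upward by
    the sampling variance of the outgroup's frequency estimate (its square
    appears in the product); that variance is estimated from pool size and
    read depth and subtracted per locus.  The standard error comes from a
    delete-one block jackknife over contiguous SNP blocks.
    """
    trio = (source1, source2, outgroup)
    if len(set(trio)) != 3:
        raise ValueError("source1, source2 and outgroup must be distinct stands")
    pos = {s: i for i, s in enumerate(pc.stand_ids)}
    missing = [s for s in trio if s not in pos]
    if missing:
        raise KeyError(f"unknown stands: {missing}")
    p1, _, c1 = _pool_freq_and_var(pc, pos[source1])
    p2, _, c2 = _pool_freq_and_var(pc, pos[source2])
    po, vo, co = _pool_freq_and_var(pc, pos[outgroup])
    ok = (c1 >= 2) & (c2 >= 2) & (co >= 2)
    f3_l = ((po - p1) * (po - p2) - vo)[ok]
    L = len(f3_l)
    n_blocks = L // block_size + (1 if L % block_size else 0)
    if n_blocks < 2:
        raise ValueError(
            f"need at least 2 jackknife blocks ({L} loci, block_size {block_size})"
        )
    f3 = float(f3_l.mean())
    blocks = np.array_split(f3_l, n_blocks)
    total = f3_l.sum()
    theta = np.array([(total - b.sum()) / (L - len(b)) for b in blocks])
    B = n_blocks
    se = float(np.sqrt((B - 1) / B * ((theta - theta.mean()) ** 2).sum()))
    z = f3 / se if se > 0 else np.inf * np.sign(f3)
    return F3Result(outgroup, source1, source2, f3, se, float(z), L, n_blocks)


def f3_locality_scan(
    pc: PoolCounts, stands: list[StandInfo], block_size: int = 500
) -> pd.DataFrame:
    """All within-locality outgroup-f3 tests, cycling the outgroup role.

    For each complete locality (one old + two planted stands) the outgroup is
    assigned to each stand in turn.  When the old stand is the outgroup the
    sources are the two planted stands (comparison class "P vs. P"); when a
    planted stand is the outgroup the sources are old + planted ("O vs. P").
    Incomplete localities are skipped with a warning.
    """
    by_loc: dict[int, dict[str, list[StandInfo]]] = {}
    present = set(pc.stand_ids)
    for s in stands:
        if s.stand_id not in present:
            continue
        by_loc.setdefault(s.locality, {"old": [], "planted": []})[s.stand_type].append(s)
    rows = []
    for loc in sorted(by_loc):
        grp = by_loc[loc]
        if len(grp["old"]) != 1 or len(grp["planted"]) != 2:
            warnings.warn(f"locality {loc}: incomplete (needs 1 old + 2 planted); skipped",
                          stacklevel=2)
            continue
        old = grp["old"][0].stand_id
        p1, p2 = (s.stand_id for s in grp["planted"])
        configs = [
            (old, p1, p2, "P vs. P"),
            (p1, old, p2, "O vs. P"),
            (p2, old, p1, "O vs. P"),
        ]
        for outgroup, s1, s2, cls in configs:
            r = outgroup_f3(pc, s1, s2, outgroup, block_size=block_size)
            rows.append(
                {
                    "locality": loc,
                    "outgroup": outgroup,
                    "source1": s1,
                    "source2": s2,
                    "f3": r.f3,
                    "se": r.jackknife_se,
                    "z": r.z,
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)


def diversity_stats(
    pc: PoolCounts, rare_threshold: float = 0.05, bias_corrected: bool = True
) -> pd.DataFrame:
    """Per-stand diversity summaries from read proportions.

    * ``n_invariant``: SNPs whose within-stand frequency is exactly 0 or 1;
    * ``prop_rare``: fraction of stand-polymorphic SNPs with minor-allele
      frequency below ``rare_threshold``;
    * ``heterozygosity``: mean over SNPs of 2p(1-p), by default with the
      n/(n-1) small-sample correction using the haploid pool size.

    Run this on counts *before* MAF filtering so invariant sites are countable.
    """
    depth = pc.total_depth
    if (depth == 0).any():
        raise ValueError("zero-depth entries; apply coverage filtering first")
    p = (pc.alt_depth / depth).T  # stands x snps
    invariant = (p == 0.0) | (p == 1.0)
    maf = np.minimum(p, 1.0 - p)
    poly = ~invariant
    with np.errstate(invalid="ignore"):
        prop_rare = np.where(
            poly.sum(axis=1) > 0,
            ((maf < rare_threshold) & poly).sum(axis=1) / np.maximum(poly.sum(axis=1), 1),
            0.0,
        )
    het = 2.0 * p * (1.0 - p)
    if bias_corrected:
        n_h = pc.haploid_size.astype(float)[:, None]
        het = het * n_h / (n_h - 1.0)
    return pd.DataFrame(
        {
            "stand_id": pc.stand_ids,
            "n_invariant": invariant.sum(axis=1),
            "prop_rare": prop_rare,
            "heterozygosity": het.mean(axis=1),
        }
    ).set_index("stand_id")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points given in degrees."""
    la1, lo1, la2, lo2 = map(np.deg2rad, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(stands: list[StandInfo]) -> DistanceMatrix:
    """Pairwise great-circle distances between stands, in km."""
    n = len(stands)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(
                stands[i].latitude, stands[i].longitude,
                stands[j].latitude, stands[j].longitude,
            )
            out[i, j] = out[j, i] = d
    return DistanceMatrix([s.stand_id for s in stands], out, kind="geographic_km")
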