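"""Risk of non-adaptedness (RONA).

For each stand and climate variable, RONA is the average allele-frequency
change at climate-associated SNPs needed to track the projected future
climate, with each SNP weighted by the R^2 of its frequency-environment
regression:

    shift_{l,s} = |b_l| * |e_future,s - e_current,s|
    RONA_s      = sum_l R2_l * shift_{l,s} / sum_l R2_l

where b_l is the OLS slope of stand frequency on the raw (unstandardized)
climate variable.  The default uses the difference of fitted values
("theoretical" shift); the variant measuring |fitted future - observed
current| is available via ``shift="observed"``.  RONA is a proxy for
adaptive mismatch, not a fitness measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CLIMATE_VARIABLES, ClimateTable, FrequencyMatrix, OutlierReport

__all__ = [
    "snp_env_regression",
    "rona_per_stand",
    "rona_table",
    "rona_contrast",
]


def snp_env_regression(freqs: FrequencyMatrix, env: np.ndarray) -> pd.DataFrame:
    """Per-SNP OLS of stand frequency on a raw climate variable.

    Returns a DataFrame indexed by snp_id with columns intercept, slope and
    r_squared.  SNPs constant across stands get slope 0 and r^2 0.
    """
    env = np.asarray(env, dtype=float)
    n = freqs.n_stands
    if n < 3:
        raise ValueError("need at least 3 stands")
    if env.shape != (n,):
        raise ValueError("env length must match number of stands")
    if env.std() == 0.0:
        raise ValueError("climate variable is constant across stands")
    Y = freqs.values  # n x L
    ec = env - env.mean()
    see = ec @ ec
    Yc = Y - Y.mean(axis=0)
    slope = (ec @ Yc) / see
    intercept = Y.mean(axis=0) - slope * env.mean()
    ssy = (Yc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ssy > 0, slope**2 * see / ssy, 0.0)
    slope = np.where(ssy > 0, slope, 0.0)
    return pd.DataFrame(
        {"intercept": intercept, "slope": slope, "r_squared": r2},
        index=pd.Index(freqs.snp_ids, name="snp_id"),
    )


def _rona_from_model(
    sub: FrequencyMatrix,
    env_current: np.ndarray,
    env_future: np.ndarray,
    reg: pd.DataFrame,
    shift: str,
) -> np.ndarray:
    """R^2-weighted per-stand RONA given fitted per-SNP regressions."""
    w = reg["r_squared"].to_numpy()
    if w.sum() == 0.0:
        raise ValueError("all regression weights are zero")
    b = reg["slope"].to_numpy()
    a = reg["intercept"].to_numpy()
    delta = env_future - env_current  # per stand
    if shift == "theoretical":
        shifts = np.abs(b)[None, :] * np.abs(delta)[:, None]  # stands x snps
    elif shift == "observed":
        fitted_future = a[None, :] + b[None, :] * env_future[:, None]
        shifts = np.abs(np.clip(fitted_future, 0.0, 1.0) - sub.values)
    else:
        raise ValueError("shift must be 'theoretical' or 'observed'")
    return (shifts * w[None, :]).sum(axis=1) / w.sum()


def rona_per_stand(
    freqs: FrequencyMatrix,
    env_current: np.ndarray,
    env_future: np.ndarray,
    assoc_snps: OutlierReport,
    variable: str,
    shift: str = "theoretical",
) -> pd.DataFrame:
    """R^2-weighted expected allele-frequency shift per stand for one variable.

    ``assoc_snps`` must contain SNPs passing for ``variable``; regressions are
    fitted on the supplied stand set (the same set being scored).
    """
    env_current = np.asarray(env_current, dtype=float)
    env_future = np.asarray(env_future, dtype=float)
    snps = assoc_snps.outlier_snps(variable)
    if len(snps) == 0:
        raise ValueError(
            f"no SNPs associated with {variable} in this report; run the GEA step"
        )
    sub = freqs.subset_snps(snps)
    reg = snp_env_regression(sub, env_current)
    rona = _rona_from_model(sub, env_current, env_future, reg, shift)
    return pd.DataFrame(
        {
            "stand_id": freqs.stand_ids,
            "stand_set": assoc_snps.stand_set,
            "variable": variable,
            "method": assoc_snps.method,
            "rona": rona,
            "n_snps_used": len(snps),
        }
    )


def rona_table(
    freqs_by_set: dict[str, FrequencyMatrix],
    climate_current: ClimateTable,
    climate_future: ClimateTable,
    reports: dict[str, OutlierReport],
    shift: str = "observed",
    reference: str = "old",
) -> pd.DataFrame:
    """All stand x variable x method RONA values for the study protocol.

    For each method and climate variable, the associated SNP set is the
    *union* of outliers across stand sets (the planted set alone often has
    none).  With ``reference="old"`` (default) the per-SNP
    frequency-environment regressions are fitted on the old-growth stands —
    the natural populations that express the local-adaptation cline — and
    define the expected adaptive frequency at any climate; each stand's RONA
    is then the R^2-weighted mean |expected frequency under its future
    climate - observed current frequency| (``shift="observed"``).  Planted
    stands therefore pay both for the projected climate shift and for any
    standing mismatch between their current frequencies and the adaptive
    cline, which is exactly what makes recently planted, non-local material
    riskier.  ``reference="own"`` fits each stand set on itself and
    ``shift="theoretical"`` uses |slope * delta_e| instead (no standing
    mismatch; old and planted then differ only through their fitted slopes).

    ``freqs_by_set`` maps stand-set name to the frequency matrix of that
    subset; ``reports`` maps "{method}:{stand_set}" to its outlier report.
    Variables without associated SNPs in any stand set are skipped.
    """
    if reference not in ("old", "own"):
        raise ValueError("reference must be 'old' or 'own'")
    by_method: dict[str, list[OutlierReport]] = {}
    for key, report in reports.items():
        by_method.setdefault(key.split(":")[0], []).append(report)
    rows = []
    for method, reps in by_method.items():
        for variable in CLIMATE_VARIABLES:
            union: list = []
            seen = set()
            for r in reps:
                for s in r.outlier_snps(variable):
                    if s not in seen:
                        seen.add(s)
                        union.append(s)
            if not union:
                continue
            ref_reg = None
            if reference == "old":
                ref_freqs = freqs_by_set["old"].subset_snps(union)
                ref_env = (
                    climate_current.subset_stands(ref_freqs.stand_ids)
                    .data[variable]
                    .to_numpy()
                )
                ref_reg = snp_env_regression(ref_freqs, ref_env)
            for stand_set, freqs in freqs_by_set.items():
                sub = freqs.subset_snps(union)
                cur = climate_current.subset_stands(sub.stand_ids).data[variable].to_numpy()
                fut = climate_future.subset_stands(sub.stand_ids).data[variable].to_numpy()
                reg = ref_reg if ref_reg is not None else snp_env_regression(sub, cur)
                rona_vals = _rona_from_model(sub, cur, fut, reg, shift)
                rows.append(
                    pd.DataFrame(
                        {
                            "stand_id": sub.stand_ids,
                            "stand_set": stand_set,
                            "variable": variable,
                            "method": method,
                            "rona": rona_vals,
                            "n_snps_used": len(union),
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["stand_id", "stand_set", "variable", "method", "rona", "n_snps_used"]
        )
    return pd.concat(rows, ignore_index=True)


def rona_contrast(results: pd.DataFrame) -> pd.DataFrame:
    """Old-vs-planted RONA comparison per variable and method.

    Reports the mean RONA in each stand set, their difference
    (planted - old) and a two-sided Wilcoxon rank-sum p-value.  Variables
    present in only one stand set yield NaN difference and p.
    """
    rows = []
    for (method, variable), grp in results.groupby(["method", "variable"], sort=True):
        old = grp.loc[grp["stand_set"] == "old", "rona"].to_numpy()
        planted = grp.loc[grp["stand_set"] == "planted", "rona"].to_numpy()
        if len(old) and len(planted):
            if np.array_equal(np.sort(old), np.sort(planted)):
                diff, p = 0.0, 1.0
            else:
                stat = stats.ranksums(planted, old)
                diff, p = float(planted.mean() - old.mean()), float(stat.pvalue)
        else:
            diff, p = np.nan, np.nan
        rows.append(
            {
                "method": method,
                "variable": variable,
                "mean_rona_old": old.mean() if len(old) else np.nan,
                "mean_rona_planted": planted.mean() if len(planted) else np.nan,
                "difference": diff,
                "p_ranksum": p,
            }
        )
    return pd.DataFrame(rows)
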