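"""Synthetic pooled-sequencing landscapes with known ground truth.

Emulates the study design the rest of the package analyses: 15 localities
spread along a west-east gradient in northern Sweden, each with one
old-growth stand and two nearby planted stands, pools of 30 diploid trees
(60 haplotypes), deep but variable GBS coverage, and tens of thousands of
SNPs of which a small fraction carry climate-driven clines.  Clines are
strong in old stands; in planted stands they are attenuated by regressing
the expected frequency toward the species-wide ancestral mean, emulating
replanting from non-local seed sources.

The generating model is deliberately minimal:

* neutral drift is Balding-Nichols — stand frequencies are Beta-distributed
  around an ancestral frequency pi with variance pi(1-pi)*fst_background;
* adaptive SNPs place the *mean* stand frequency on a logistic cline in the
  standardized driver variable, then apply the same Beta drift noise;
* pooled reads resample haplotypes with replacement at negative-binomial
  depth with a symmetric per-read error.

There is no linkage, no coalescent history and no GBS fragment model; SNPs
are exchangeable and independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CLIMATE_VARIABLES,
    ClimateTable,
    FrequencyMatrix,
    PoolCounts,
    StandInfo,
)

__all__ = [
    "make_stands",
    "stand_axis",
    "simulate_climate",
    "simulate_frequencies",
    "simulate_pool_reads",
    "simulate_dataset",
    "SimulatedDataset",
]

# West-east extent of the sampled region (approx. Scandinavian mountains to
# the Baltic coast in northern Sweden).
_LON_WEST, _LON_EAST = 13.0, 21.0
_LAT_WEST, _LAT_EAST = 64.6, 63.4

# Climate variable profiles: value at the western end, value at the eastern
# end of the axis.  Signs/ranges are loosely modelled on ENVIREM values for
# northern Sweden; the east (coast) is warmer and less continental than the
# west (mountains).
_CLIMATE_PROFILE = {
    "AIT": (62.0, 38.0),      # wetter (higher aridity index) in the mountains
    "CMT": (0.95, 0.55),      # climatic moisture index
    "CONT": (27.0, 21.0),     # continentality, degC
    "DegD0": (110.0, 175.0),  # growing degree days > 0C (10*degC units)
    "DegD5": (65.0, 125.0),   # growing degree days > 5C (10*degC units)
    "MTC": (-13.0, -5.0),     # max temperature of the coldest month (10*degC)
    "PCQ": (4.0, 13.0),       # PET of the coldest quarter
}

#: Default future-scenario shift, one entry per climate variable, expressed in
#: each variable's own units.  Magnitudes correspond to roughly one across-stand
#: standard deviation of warming/drying by 2070 under a mid-range
#: concentration pathway (warmer: DegD0/DegD5/MTC/PCQ up, CONT down; drier:
#: AIT/CMT down).
DEFAULT_SCENARIO_SHIFT = np.array([-6.0, -0.10, -1.5, 18.0, 16.0, 2.2, 2.5])


def make_stands(n_localities: int = 15, seed: int = 0, jitter_km: float = 2.0) -> list[StandInfo]:
    """Place ``n_localities`` localities along a west-east axis, each with one
    old-growth stand and two planted stands within ``jitter_km`` of it.
    """
    if n_localities < 2:
        raise ValueError("n_localities must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_localities)
    t = np.clip(t + rng.normal(0.0, 0.25 / n_localities, n_localities), 0.0, 1.0)
    lon0 = _LON_WEST + t * (_LON_EAST - _LON_WEST)
    lat0 = _LAT_WEST + t * (_LAT_EAST - _LAT_WEST) + rng.normal(0.0, 0.15, n_localities)

    # ~111 km per degree latitude; scale longitude jitter by cos(lat).
    jit_lat = jitter_km / 111.0
    stands: list[StandInfo] = []
    for k in range(n_localities):
        loc = k + 1
        jit_lon = jitter_km / (111.0 * np.cos(np.deg2rad(lat0[k])))
        stands.append(
            StandInfo(f"L{loc:02d}_O", "old", loc, float(lat0[k]), float(lon0[k]))
        )
        for p in (1, 2):
            stands.append(
                StandInfo(
                    f"L{loc:02d}_P{p}",
                    "planted",
                    loc,
                    float(lat0[k] + rng.uniform(-jit_lat, jit_lat)),
                    float(lon0[k] + rng.uniform(-jit_lon, jit_lon)),
                )
            )
    return stands


def stand_axis(stands: list[StandInfo]) -> np.ndarray:
    """Position of each stand on the west-east axis, rescaled to [0, 1]."""
    lon = np.array([s.longitude for s in stands])
    span = lon.max() - lon.min()
    if span == 0.0:
        return np.zeros_like(lon)
    return (lon - lon.min()) / span


def simulate_climate(
    stands: list[StandInfo],
    scenario_shift: np.ndarray | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    scenario: str | None = None,
) -> ClimateTable:
    """Climate tables as monotone functions of the west-east axis plus noise.

    Each of the seven variables is a linear function of the shared axis with
    independent Gaussian noise of standard deviation ``noise_sd`` times the
    variable's west-east range, which makes the variables strongly mutually
    correlated (as real temperature/aridity summaries are).  ``scenario_shift``
    — one value per variable in the variable's units, or a stands x variables
    matrix for a spatially varying projection — is added after the noise, so
    with the same seed a zero shift reproduces the current table exactly.
    """
    if not stands:
        raise ValueError("stands must be non-empty")
    rng = np.random.default_rng(seed)
    t = stand_axis(stands)
    if scenario_shift is None:
        shift = np.zeros(len(CLIMATE_VARIABLES))
        default_name = "current"
    else:
        shift = np.asarray(scenario_shift, dtype=float)
        if shift.shape not in ((len(CLIMATE_VARIABLES),), (len(stands), len(CLIMATE_VARIABLES))):
            raise ValueError(
                "scenario_shift must have one entry per climate variable, or be "
                "a stands x variables matrix"
            )
        default_name = "current" if np.all(shift == 0.0) else "future"
    cols = {}
    for v, (west, east) in _CLIMATE_PROFILE.items():
        base = west + t * (east - west)
        noise = rng.normal(0.0, noise_sd * abs(east - west), len(stands))
        cols[v] = base + noise
    data = pd.DataFrame(cols, index=[s.stand_id for s in stands])
    data += shift
    return ClimateTable(data, scenario or default_name)


def _beta_drift(rng: np.random.Generator, mean: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols draw: Beta with given mean and variance mean(1-mean)*fst."""
    mean = np.clip(mean, 1e-6, 1.0 - 1e-6)
    a = mean * (1.0 - fst) / fst
    b = (1.0 - mean) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_frequencies(
    stands: list[StandInfo],
    climate: ClimateTable,
    n_neutral: int = 20_000,
    n_adaptive: int = 100,
    fst_background: float = 0.05,
    slope_logit: float = 1.0,
    source_decoupling: float = 0.8,
    seed: int = 0,
) -> tuple[FrequencyMatrix, pd.DataFrame]:
    """Simulate per-stand allele frequencies and the ground-truth table.

    ``n_adaptive`` is the number of adaptive SNPs *per climate variable*
    (drivers cycle through the seven variables).  Neutral SNPs follow pure
    Balding-Nichols drift around an ancestral frequency ~ Uniform(0.05, 0.95).
    Adaptive SNPs place the old-stand mean on logistic(logit(pi) +
    slope_logit * z) where z is the standardized driver at the stand; planted
    stands mix that cline with the ancestral mean pi in proportion
    ``source_decoupling`` before the same drift noise is applied.

    Returns the stands x SNPs frequency matrix and a truth table with columns
    snp_id, is_adaptive, driver_variable, slope_logit, source_decoupling.
    """
    if not 0.0 < fst_background < 1.0:
        raise ValueError("fst_background must lie in (0, 1)")
    if not 0.0 <= source_decoupling <= 1.0:
        raise ValueError("source_decoupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    stand_ids = [s.stand_id for s in stands]
    if list(climate.data.index) != stand_ids:
        climate = climate.subset_stands(stand_ids)
    is_planted = np.array([s.stand_type == "planted" for s in stands])
    S = len(stands)

    # standardized drivers, stands x variables
    z = climate.data.to_numpy()
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    n_adaptive_total = n_adaptive * len(CLIMATE_VARIABLES)
    L = n_neutral + n_adaptive_total

    pi = np.empty(L)
    pi[:n_neutral] = rng.uniform(0.05, 0.95, n_neutral)
    pi[n_neutral:] = rng.uniform(0.2, 0.8, n_adaptive_total)

    mean = np.broadcast_to(pi, (S, L)).copy()  # stands x snps
    drivers = np.array(
        [CLIMATE_VARIABLES[j % len(CLIMATE_VARIABLES)] for j in range(n_adaptive_total)],
        dtype=object,
    )
    if n_adaptive_total:
        alpha = np.log(pi[n_neutral:] / (1.0 - pi[n_neutral:]))
        zcols = np.array([list(CLIMATE_VARIABLES).index(v) for v in drivers])
        logit = alpha[None, :] + slope_logit * z[:, zcols]
        cline = 1.0 / (1.0 + np.exp(-logit))
        adaptive_mean = cline.copy()
        mixed = (1.0 - source_decoupling) * cline + source_decoupling * pi[None, n_neutral:]
        adaptive_mean[is_planted] = mixed[is_planted]
        mean[:, n_neutral:] = adaptive_mean

    values = _beta_drift(rng, mean, fst_background)

    width = max(6, len(str(L)))
    snp_ids = np.array([f"snp_{j:0{width}d}" for j in range(L)], dtype=object)
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "is_adaptive": np.r_[np.zeros(n_neutral, bool), np.ones(n_adaptive_total, bool)],
            "driver_variable": np.r_[np.full(n_neutral, None, dtype=object), drivers],
            "slope_logit": np.r_[np.zeros(n_neutral), np.full(n_adaptive_total, slope_logit)],
            "source_decoupling": np.r_[
                np.zeros(n_neutral), np.full(n_adaptive_total, source_decoupling)
            ],
        }
    )
    return FrequencyMatrix(values, stand_ids, snp_ids), truth


_NUCS = np.array(list("ACGT"))


def simulate_pool_reads(
    freqs: FrequencyMatrix,
    haploids_per_pool: int = 60,
    mean_depth: float = 1850.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 1e-3,
    seed: int = 0,
) -> PoolCounts:
    """Pooled read counts from per-stand allele frequencies.

    Per SNP and stand: the pool's alternate-haplotype count k is
    Binomial(haploids_per_pool, freq); read depth d is negative-binomial with
    the given mean and dispersion (shape) parameter; alternate reads are
    Binomial(d, q) where q = (k/n)(1-e) + (1-k/n)e incorporates a symmetric
    per-read error e.  Reads therefore resample haplotypes with replacement,
    which is the appropriate pool-seq observation model.
    """
    if haploids_per_pool < 2:
        raise ValueError("haploids_per_pool must be >= 2")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    S, L = freqs.values.shape
    k = rng.binomial(haploids_per_pool, freqs.values)          # (S, L)
    p_nb = depth_dispersion / (depth_dispersion + mean_depth)
    depth = rng.negative_binomial(depth_dispersion, p_nb, size=(S, L))
    f = k / haploids_per_pool
    q = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    alt = rng.binomial(depth, q)
    ref = depth - alt

    ref_allele = rng.choice(_NUCS, size=L)
    offsets = rng.integers(1, 4, size=L)
    alt_allele = _NUCS[(np.searchsorted(_NUCS, ref_allele) + offsets) % 4]

    return PoolCounts(
        snp_ids=freqs.snp_ids.copy(),
        contig=np.full(L, "chr1", dtype=object),
        pos=np.arange(1, L + 1) * 100,
        ref_allele=ref_allele.astype(object),
        alt_allele=alt_allele.astype(object),
        ref_depth=ref.T,
        alt_depth=alt.T,
        stand_ids=list(freqs.stand_ids),
        haploid_size=np.full(S, haploids_per_pool),
    )


@dataclass
class SimulatedDataset:
    """One complete synthetic study: stands, climate, truth, frequencies, reads."""

    stands: list[StandInfo]
    climate_current: ClimateTable
    climate_future: ClimateTable
    freqs: FrequencyMatrix
    truth: pd.DataFrame
    counts: PoolCounts

    @property
    def old_ids(self) -> list[str]:
        return [s.stand_id for s in self.stands if s.stand_type == "old"]

    @property
    def planted_ids(self) -> list[str]:
        return [s.stand_id for s in self.stands if s.stand_type == "planted"]


def simulate_dataset(
    n_localities: int = 15,
    n_neutral: int = 20_000,
    n_adaptive: int = 100,
    fst_background: float = 0.05,
    slope_logit: float = 1.0,
    source_decoupling: float = 0.8,
    haploids_per_pool: int = 60,
    mean_depth: float = 1850.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 1e-3,
    climate_noise_sd: float = 0.05,
    scenario_shift: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Convenience wrapper generating the default study conditions end to end.

    Per-stage seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_stand, s_clim, s_freq, s_reads = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    stands = make_stands(n_localities, seed=s_stand)
    if scenario_shift is None:
        # projected change is not spatially uniform: modulate the mean shift
        # along the west-east axis (stronger change toward the coast)
        t = stand_axis(stands)
        shift = DEFAULT_SCENARIO_SHIFT[None, :] * (1.0 + 0.3 * (t[:, None] - 0.5))
    else:
        shift = np.asarray(scenario_shift)
    climate_current = simulate_climate(stands, None, climate_noise_sd, seed=s_clim)
    climate_future = simulate_climate(stands, shift, climate_noise_sd, seed=s_clim, scenario="future")
    freqs, truth = simulate_frequencies(
        stands,
        climate_current,
        n_neutral=n_neutral,
        n_adaptive=n_adaptive,
        fst_background=fst_background,
        slope_logit=slope_logit,
        source_decoupling=source_decoupling,
        seed=s_freq,
    )
    counts = simulate_pool_reads(
        freqs,
        haploids_per_pool=haploids_per_pool,
        mean_depth=mean_depth,
        depth_dispersion=depth_dispersion,
        error_rate=error_rate,
        seed=s_reads,
    )
    return SimulatedDataset(stands, climate_current, climate_future, freqs, truth, counts)
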