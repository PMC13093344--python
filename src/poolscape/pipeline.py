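"""End-to-end pipeline: simulate/ingest -> filter -> frequencies -> neutral
statistics -> gene-environment outliers -> IBD/IBE Mantel suite -> RONA.

The run is driven by a :class:`RunConfig` (constructed directly or loaded
from a flat YAML mapping) with a mandatory master seed; per-stage seeds are
spawned deterministically from it, so a config reproduces every output file
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gea, landscape, mantel, pool_io, popgen, rona
from .containers import (
    CLIMATE_VARIABLES,
    ClimateTable,
    stands_from_frame,
    stands_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_inputs", "run_pipeline", "OUTPUT_FILES"]

#: Files every successful run writes into the output directory.
OUTPUT_FILES = (
    "stands.tsv",
    "frequencies.tsv",
    "fst_all.tsv",
    "f3.tsv",
    "diversity.tsv",
    "gea_associations.tsv",
    "association_counts.tsv",
    "ibe_report.tsv",
    "rona.tsv",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` (generator parameters, possibly empty for the
    defaults) or the input paths (``counts_path`` + ``stands_path`` +
    ``climate_current_path`` + ``climate_future_path``) must be provided.
    """

    seed: int
    outdir: str = "poolscape_out"
    simulate: dict | None = None
    counts_path: str | None = None
    counts_format: str = "vcf"           # vcf | sync
    stands_path: str | None = None
    climate_current_path: str | None = None
    climate_future_path: str | None = None
    haploid_sizes: list[int] | None = None
    # filter thresholds (defaults: 60 reads, 0.1-99.9 coverage quantiles, MAF 0.008)
    min_cov: int = 60
    cov_quantile_lo: float = 0.001
    cov_quantile_hi: float = 0.999
    maf_min: float = 0.008
    # gene-environment settings
    gea_methods: tuple[str, ...] = ("correlation", "lfmm")
    n_draws: int = 1_000_000
    null_quantile: float = 0.999
    null_n: str = "old"                  # "old": one threshold from the old-stand count
    k_latent: int = 4
    alpha: float = 0.05
    # Mantel settings
    n_perm: int = 9999
    f3_block_size: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        has_paths = self.counts_path is not None
        if (self.simulate is not None) == has_paths:
            raise ValueError(
                "exactly one of a simulation block or input paths must be given"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gea_methods" in raw:
            raw["gea_methods"] = tuple(raw["gea_methods"])
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = landscape.simulate_dataset(seed=config.seed, **config.simulate)
        return sim.stands, sim.counts, sim.climate_current, sim.climate_future, sim.truth
    stands = stands_from_frame(pd.read_csv(config.stands_path, sep="\t"))
    if config.counts_format == "vcf":
        pc = pool_io.read_pool_vcf(config.counts_path, haploid_sizes=config.haploid_sizes)
    elif config.counts_format == "sync":
        if config.haploid_sizes is None:
            raise ValueError("sync input requires haploid_sizes")
        pc = pool_io.read_sync(
            config.counts_path, config.haploid_sizes,
            stand_ids=[s.stand_id for s in stands],
        )
    else:
        raise ValueError("counts_format must be 'vcf' or 'sync'")
    cur = ClimateTable(
        pd.read_csv(config.climate_current_path, sep="\t", index_col=0), "current"
    )
    fut = ClimateTable(
        pd.read_csv(config.climate_future_path, sep="\t", index_col=0), "future"
    )
    return stands, pc, cur, fut, None


def validate_inputs(config: RunConfig) -> list[str]:
    """Cross-check stand ids and climate columns; returns findings (no raising)."""
    findings: list[str] = []
    try:
        stands, pc, cur, fut, _ = _load_inputs(config)
    except Exception as exc:  # malformed inputs are themselves the finding
        return [f"failed to load inputs: {exc}"]
    stand_ids = [s.stand_id for s in stands]
    raw_cols = {}
    for name, path in (
        ("climate:current", config.climate_current_path),
        ("climate:future", config.climate_future_path),
    ):
        if path is not None:
            raw_cols[name] = list(pd.read_csv(path, sep="\t", index_col=0, nrows=0).columns)
    for name, table in (("climate:current", cur), ("climate:future", fut)):
        for s in stand_ids:
            if s not in table.data.index:
                findings.append(f"stand {s} absent from {name}")
        extra = [c for c in raw_cols.get(name, []) if c not in CLIMATE_VARIABLES]
        if extra:
            findings.append(f"{name}: extra columns ignored: {extra}")
    for s in stand_ids:
        if s not in pc.stand_ids:
            findings.append(f"stand {s} absent from counts")
    by_loc: dict[int, list[str]] = {}
    for s in stands:
        by_loc.setdefault(s.locality, []).append(s.stand_type)
    for loc, types in sorted(by_loc.items()):
        if sorted(types) != ["old", "planted", "planted"]:
            findings.append(
                f"locality {loc} lacks the 1-old + 2-planted structure ({types})"
            )
    return findings


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV/JSON outputs plus a log.

    Returns the JSON-able summary dictionary.  Any stage failure is re-raised
    annotated with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("poolscape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seeds = _stage_seeds(config.seed, ["simulate", "null", "mantel"])
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}
    stage = "load"
    try:
        stands, pc_raw, climate_current, climate_future, truth = _load_inputs(config)
        stands_to_frame(stands).to_csv(outdir / "stands.tsv", sep="\t", index=False)
        climate_current.data.to_csv(outdir / "climate_current.tsv", sep="\t")
        climate_future.data.to_csv(outdir / "climate_future.tsv", sep="\t")
        if truth is not None:
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        logger.info("loaded %d SNPs x %d stands", pc_raw.n_snps, pc_raw.n_stands)

        stage = "filter"
        pc_cov, _ = pool_io.filter_snps(
            pc_raw, config.min_cov, config.cov_quantile_lo, config.cov_quantile_hi,
            maf_min=0.0,
        )
        pc, report = pool_io.filter_snps(
            pc_raw, config.min_cov, config.cov_quantile_lo, config.cov_quantile_hi,
            config.maf_min,
        )
        (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        summary["filter"] = report.to_dict()

        stage = "frequencies"
        freqs = pool_io.estimate_frequencies(pc)
        freqs.to_frame().to_csv(outdir / "frequencies.tsv", sep="\t")

        stage = "popgen"
        fst_all = popgen.pairwise_fst(pc)
        fst_all.to_frame().to_csv(outdir / "fst_all.tsv", sep="\t")
        f3 = popgen.f3_locality_scan(pc, stands, block_size=config.f3_block_size)
        f3.to_csv(outdir / "f3.tsv", sep="\t", index=False)
        # diversity on coverage-filtered counts, before the MAF filter, so
        # invariant sites remain countable
        diversity = popgen.diversity_stats(pc_cov)
        diversity.to_csv(outdir / "diversity.tsv", sep="\t")
        summary["n_snps_retained"] = pc.n_snps
        if len(f3):
            summary["f3_median_by_class"] = (
                f3.groupby("class")["f3"].median().to_dict()
            )

        stage = "pca"
        scores, var_explained = gea.pca_structure(freqs)
        pd.DataFrame(
            scores,
            index=freqs.stand_ids,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ).to_csv(outdir / "pca_scores.tsv", sep="\t")
        summary["pca_variance_explained"] = var_explained[: config.k_latent].tolist()

        stage = "gea"
        set_ids = {
            "old": [s.stand_id for s in stands if s.stand_type == "old"],
            "planted": [s.stand_id for s in stands if s.stand_type == "planted"],
        }
        n_null = len(set_ids["old"])
        r_star = gea.corr_null_threshold(
            n_null,
            climate_current.subset_stands(set_ids["old"]),
            n_draws=config.n_draws,
            quantile=config.null_quantile,
            seed=seeds["null"],
        )
        summary["corr_null_threshold"] = r_star
        summary["bonferroni_threshold"] = gea.bonferroni_threshold(config.alpha, pc.n_snps)
        reports: dict[str, gea.OutlierReport] = {}
        for stand_set, ids in set_ids.items():
            fsub = freqs.subset_stands(ids)
            csub = climate_current.subset_stands(ids)
            if "correlation" in config.gea_methods:
                reports[f"correlation:{stand_set}"] = gea.corr_outliers(
                    fsub, csub, r_star, stand_set=stand_set
                )
            if "lfmm" in config.gea_methods:
                reports[f"lfmm:{stand_set}"] = gea.lfmm_associations(
                    fsub, csub, k_latent=config.k_latent, alpha=config.alpha,
                    stand_set=stand_set,
                )
        assoc = pd.concat(
            [
                r.table.assign(method=r.method, stand_set=r.stand_set)
                for r in reports.values()
            ],
            ignore_index=True,
        )
        assoc.to_csv(outdir / "gea_associations.tsv", sep="\t", index=False)
        counts_tbl = pd.concat(
            [gea.count_associations(r) for r in reports.values()], ignore_index=True
        )
        counts_tbl.to_csv(outdir / "association_counts.tsv", sep="\t", index=False)
        summary["association_counts"] = {
            f"{row.method}:{row.stand_set}:{row.variable}": int(row.n_significant)
            for row in counts_tbl.itertuples(index=False)
        }

        stage = "ibe"
        ibe, ibd = mantel.ibd_ibe_report(
            stands, pc, reports, climate_current, climate_future,
            n_perm=config.n_perm, seed=seeds["mantel"],
        )
        ibe.to_csv(outdir / "ibe_report.tsv", sep="\t", index=False)
        ibd.to_csv(outdir / "ibd_summary.tsv", sep="\t", index=False)
        summary["ibd"] = ibd.to_dict(orient="records")
        summary["mean_partial_r"] = {
            f"{m}:{s}:{sc}": float(
                ibe.query("method == @m and stand_set == @s and scenario == @sc")[
                    "partial_r"
                ].mean()
            )
            for m in {k.split(":")[0] for k in reports}
            for s in ("old", "planted")
            for sc in ("current", "future")
        }

        stage = "rona"
        freqs_by_set = {k: freqs.subset_stands(v) for k, v in set_ids.items()}
        rona_tbl = rona.rona_table(freqs_by_set, climate_current, climate_future, reports)
        rona_tbl.to_csv(outdir / "rona.tsv", sep="\t", index=False)
        contrast = rona.rona_contrast(rona_tbl)
        contrast.to_csv(outdir / "rona_contrast.tsv", sep="\t", index=False)
        summary["rona_contrast"] = contrast.to_dict(orient="records")

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        logger.info("pipeline complete: %s", outdir)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
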