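"""Shared fixtures: a session-scoped run of the full pipeline under the
default study conditions, plus small synthetic datasets for module tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolscape import landscape
from poolscape.containers import FrequencyMatrix
from poolscape.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic landscape (the study design:
    15 localities x 3 stands, 20k neutral + 100/variable adaptive SNPs,
    decoupling 0.8).  Returns (outdir, summary)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(seed=20_260_922, outdir=str(outdir), simulate={})
    summary = run_pipeline(cfg)
    return outdir, summary


@pytest.fixture(scope="session")
def default_tables(default_run):
    """Key output tables of the default run, parsed."""
    outdir, summary = default_run
    return {
        "summary": summary,
        "truth": pd.read_csv(outdir / "truth.tsv", sep="\t"),
        "stands": pd.read_csv(outdir / "stands.tsv", sep="\t"),
        "assoc": pd.read_csv(outdir / "gea_associations.tsv", sep="\t"),
        "counts": pd.read_csv(outdir / "association_counts.tsv", sep="\t"),
        "ibe": pd.read_csv(outdir / "ibe_report.tsv", sep="\t"),
        "rona": pd.read_csv(outdir / "rona.tsv", sep="\t"),
        "rona_contrast": pd.read_csv(outdir / "rona_contrast.tsv", sep="\t"),
        "diversity": pd.read_csv(outdir / "diversity.tsv", sep="\t"),
        "f3": pd.read_csv(outdir / "f3.tsv", sep="\t"),
    }


@pytest.fixture(scope="session")
def small_sim():
    """A light synthetic dataset for IO / statistics tests."""
    return landscape.simulate_dataset(
        n_localities=4,
        n_neutral=600,
        n_adaptive=10,
        mean_depth=300.0,
        seed=11,
    )


def balding_nichols_freqs(
    rng: np.random.Generator, n_stands: int, n_snps: int, fst: float
) -> FrequencyMatrix:
    """Pure Balding-Nichols stand frequencies (no clines), shared helper."""
    pi = rng.uniform(0.05, 0.95, n_snps)
    a = pi * (1 - fst) / fst
    b = (1 - pi) * (1 - fst) / fst
    vals = rng.beta(np.tile(a, (n_stands, 1)), np.tile(b, (n_stands, 1)))
    return FrequencyMatrix(
        vals, [f"s{i}" for i in range(n_stands)], [f"snp{j}" for j in range(n_snps)]
    )
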