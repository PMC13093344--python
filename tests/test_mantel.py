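"""Climate distances, FST partitioning and (partial) Mantel tests, including
a cross-check against scikit-bio's Mantel implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from poolscape import gea, landscape, mantel, pool_io
from poolscape.containers import ClimateTable, DistanceMatrix


def _random_distance(rng, n, kind="fst"):
    x = rng.normal(size=(n, 4))
    return DistanceMatrix([f"s{i}" for i in range(n)],
                          squareform(pdist(x)), kind=kind)


class TestClimateDistance:
    def test_identical_rows_have_zero_distance(self):
        stands = landscape.make_stands(3, seed=1)
        clim = landscape.simulate_climate(stands, seed=2)
        data = clim.data.copy()
        data.iloc[1] = data.iloc[0]
        d = mantel.climate_distance(ClimateTable(data, "current"))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_three_stand_hand_worked_oracle(self):
        """Single variable with values (1, 2, 4): after standardization the
        pairwise distances are the absolute z-score differences."""
        import pandas as pd

        vals = np.array([1.0, 2.0, 4.0])
        data = pd.DataFrame(
            {v: vals for v in ("AIT", "CMT", "CONT", "DegD0", "DegD5", "MTC", "PCQ")},
            index=["a", "b", "c"],
        )
        d = mantel.climate_distance(ClimateTable(data, "current"), variables=["AIT"])
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert d.values[0, 1] == pytest.approx(abs(z[0] - z[1]))
        assert d.values[0, 2] == pytest.approx(abs(z[0] - z[2]))
        # all seven identical variables: each contributes the same squared term
        d7 = mantel.climate_distance(ClimateTable(data, "current"))
        assert d7.values[0, 1] == pytest.approx(np.sqrt(7) * abs(z[0] - z[1]))

    def test_triangle_inequality(self):
        stands = landscape.make_stands(8, seed=3)
        clim = landscape.simulate_climate(stands, seed=4)
        d = mantel.climate_distance(clim).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_zero_variance_variable_excluded(self):
        import pandas as pd

        data = pd.DataFrame(
            {v: [1.0, 2.0, 3.0] for v in ("AIT", "CMT", "CONT", "DegD0", "DegD5", "MTC", "PCQ")},
            index=["a", "b", "c"],
        )
        data["PCQ"] = 7.0
        with pytest.warns(UserWarning, match="PCQ"):
            d = mantel.climate_distance(ClimateTable(data, "current"))
        assert np.isfinite(d.values).all()


class TestSplitFst:
    def test_partition_is_disjoint_and_exhaustive(self, small_sim):
        pc, _ = pool_io.filter_snps(small_sim.counts, min_cov=30, maf_min=0.0)
        snps = pc.snp_ids[:40]
        rep = gea.OutlierReport(
            table=pd.DataFrame(
                {"snp_id": snps, "variable": "AIT", "statistic": 0.9, "passes": True}
            ),
            method="correlation", stand_set="old", threshold=0.73,
        )
        fst_out, fst_bg = mantel.split_fst(pc, rep)
        assert fst_out.kind == "fst_outlier" and fst_bg.kind == "fst_background"

    def test_degenerate_outlier_sets_raise(self, small_sim):
        pc, _ = pool_io.filter_snps(small_sim.counts, min_cov=30, maf_min=0.0)
        empty = gea.OutlierReport(
            pd.DataFrame(columns=["snp_id", "variable", "statistic", "passes"]),
            method="correlation", stand_set="old", threshold=0.73,
        )
        with pytest.raises(ValueError, match="empty outlier set"):
            mantel.split_fst(pc, empty)
        everything = gea.OutlierReport(
            pd.DataFrame({"snp_id": pc.snp_ids, "variable": "AIT",
                          "statistic": 0.9, "passes": True}),
            method="correlation", stand_set="old", threshold=0.73,
        )
        with pytest.raises(ValueError, match="every SNP"):
            mantel.split_fst(pc, everything)

    def test_outlier_fst_exceeds_background_under_selection(self):
        """Diversifying clinal selection inflates differentiation at outlier
        loci relative to the neutral background (old stands)."""
        from poolscape.containers import OutlierReport

        ds = landscape.simulate_dataset(
            n_localities=8, n_neutral=1200, n_adaptive=30,
            mean_depth=400.0, seed=77,
        )
        pc, _ = pool_io.filter_snps(ds.counts, min_cov=30, maf_min=0.0)
        adaptive = set(ds.truth.loc[ds.truth.is_adaptive, "snp_id"])
        rep2 = OutlierReport(
            pd.DataFrame(
                {
                    "snp_id": pc.snp_ids,
                    "variable": "AIT",
                    "statistic": 0.9,
                    "passes": [s in adaptive for s in pc.snp_ids],
                }
            ),
            "correlation", "old", 0.73,
        )
        old_ids = [s.stand_id for s in ds.stands if s.stand_type == "old"]
        fst_out, fst_bg = mantel.split_fst(pc.subset_stands(old_ids), rep2)
        assert fst_out.condensed().mean() > fst_bg.condensed().mean()


class TestMantel:
    def test_perfect_self_correlation(self):
        rng = np.random.default_rng(1)
        d = _random_distance(rng, 10)
        res = mantel.mantel_test(d, d, n_perm=99, seed=2)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(2)
        d1 = _random_distance(rng, 9)
        d2 = _random_distance(rng, 9)
        shifted = DistanceMatrix(
            d2.labels, d2.values + 3.0 - 3.0 * np.eye(d2.n), d2.kind
        )
        r1 = mantel.mantel_test(d1, d2, n_perm=99, seed=3).r
        r2 = mantel.mantel_test(d1, shifted, n_perm=99, seed=3).r
        assert r1 == pytest.approx(r2)

    def test_agrees_with_scikit_bio(self):
        """Independent oracle: scikit-bio's Mantel r on the same matrices."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        d1 = _random_distance(rng, 12)
        d2 = _random_distance(rng, 12)
        ours = mantel.mantel_test(d1, d2, n_perm=999, seed=4)
        r_ref, p_ref, _ = skbio_mantel(
            SkbioDM(d1.values, ids=d1.labels), SkbioDM(d2.values, ids=d2.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(ours.p - p_ref) < 0.05

    def test_permutation_p_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        d1 = _random_distance(rng, 10)
        d2 = _random_distance(rng, 10)
        a = mantel.mantel_test(d1, d2, n_perm=499, seed=11)
        b = mantel.mantel_test(d1, d2, n_perm=499, seed=11)
        assert a.p == b.p and a.r == b.r

    def test_label_alignment(self):
        rng = np.random.default_rng(6)
        d1 = _random_distance(rng, 8)
        order = list(reversed(d1.labels))
        d2 = _random_distance(rng, 8).reorder(order)
        res = mantel.mantel_test(d1, d2, n_perm=99, seed=7)
        res_aligned = mantel.mantel_test(d1, d2.reorder(d1.labels), n_perm=99, seed=7)
        assert res.r == pytest.approx(res_aligned.r)


class TestPartialMantel:
    def test_control_without_effect_keeps_full_correlation(self):
        rng = np.random.default_rng(8)
        d1 = _random_distance(rng, 12)
        d3 = _random_distance(rng, 12)
        res = mantel.partial_mantel(d1, d1, d3, n_perm=99, seed=9)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_identical_control_removes_correlation(self):
        rng = np.random.default_rng(10)
        d1 = _random_distance(rng, 12)
        d2 = _random_distance(rng, 12)
        noise = np.triu(rng.normal(0, 0.05, (12, 12)), 1)
        d3 = mantel.DistanceMatrix(d1.labels, d1.values + noise + noise.T, "climate")
        res = mantel.partial_mantel(d1, d2, d3, n_perm=99, seed=11)
        assert abs(res.r) < 0.2

    def test_reduces_to_simple_mantel_with_uninformative_control(self):
        rng = np.random.default_rng(12)
        d1 = _random_distance(rng, 14)
        d2 = _random_distance(rng, 14)
        noise = rng.normal(0, 1e-4, (14, 14))
        noise = np.triu(noise, 1)
        flat = DistanceMatrix(d1.labels, 5.0 - 5.0 * np.eye(14) + noise + noise.T, "climate")
        r_partial = mantel.partial_mantel(d1, d2, flat, n_perm=99, seed=13).r
        r_simple = mantel.mantel_test(d1, d2, n_perm=99, seed=13).r
        assert abs(r_partial - r_simple) < 0.02

    def test_perfectly_correlated_control_is_an_error(self):
        rng = np.random.default_rng(14)
        d1 = _random_distance(rng, 8)
        with pytest.raises(ValueError, match="perfectly correlated"):
            mantel.partial_mantel(d1, d1, d1, n_perm=99, seed=15)

    def test_decoupling_contrast_on_scaled_landscapes(self):
        """Old stands show strong, significant IBE at outlier loci while
        planted stands do not, across replicate scaled-down landscapes."""
        from poolscape.pool_io import estimate_frequencies
        from poolscape.popgen import pairwise_fst

        r_star = gea.corr_null_threshold_analytic(15)
        conform = 0
        reps = 4
        for rep in range(reps):
            ds = landscape.simulate_dataset(
                n_localities=15, n_neutral=2000, n_adaptive=25,
                mean_depth=400.0, seed=900 + rep,
            )
            pc, _ = pool_io.filter_snps(ds.counts, min_cov=30, maf_min=0.0)
            freqs = estimate_frequencies(pc)
            ok = True
            for stand_type, expect_sig in (("old", True), ("planted", False)):
                ids = [s.stand_id for s in ds.stands if s.stand_type == stand_type]
                clim = ds.climate_current.subset_stands(ids)
                rep_out = gea.corr_outliers(
                    freqs.subset_stands(ids), clim, r_star, stand_set=stand_type
                )
                var_snps = set(rep_out.outlier_snps("AIT").tolist())
                if len(var_snps) < 2:
                    # nothing detected: trivially not significant
                    ok &= not expect_sig
                    continue
                sub = pc.subset_stands(ids)
                mask_out = np.array([s in var_snps for s in pc.snp_ids])
                union = set(rep_out.outlier_snps().tolist())
                mask_bg = np.array([s not in union for s in pc.snp_ids])
                fst_out = pairwise_fst(sub.subset_snps(mask_out))
                fst_bg = pairwise_fst(sub.subset_snps(mask_bg))
                fst_bg.kind = "fst_background"
                dclim = mantel.climate_distance(clim, variables=["AIT"])
                res = mantel.partial_mantel(fst_out, dclim, fst_bg,
                                            n_perm=1999, seed=30 + rep)
                if expect_sig:
                    ok &= res.r > 0.5 and res.p < 0.001
                else:
                    ok &= res.p >= 0.001
            conform += ok
        assert conform >= reps - 1


class TestIbdIbeReport:
    def test_report_shape_and_scenarios(self, default_tables):
        ibe = default_tables["ibe"]
        # 7 variables x 2 stand sets x 2 scenarios per method
        for m in ("correlation", "lfmm"):
            assert len(ibe.query("method == @m")) == 28
        assert set(ibe["scenario"]) == {"current", "future"}

    def test_geography_and_climate_are_coupled(self, default_tables):
        for row in default_tables["summary"]["ibd"]:
            assert row["geo_climate_r"] > 0.8
            assert row["geo_climate_p"] < 0.01
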