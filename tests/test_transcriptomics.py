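"""Expression preprocessing, PLS, spin nulls, bootstrap gene screening."""
import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import dalff
from dalff import transcriptomics as tx
from dalff._stats import bh_qvalues


def _toy_table(seed=0, n_samples=30):
    rng = np.random.default_rng(seed)
    probes = ["A_p0", "A_p1", "B_p0", "C_p0", "C_p1", "C_p2"]
    genes = pd.Series(["A", "A", "B", "C", "C", "C"], index=probes)
    expr = pd.DataFrame(rng.normal(size=(6, n_samples)), index=probes)
    ref = pd.DataFrame(rng.normal(size=(3, n_samples)), index=["A", "B", "C"])
    bg = pd.DataFrame(rng.random((6, n_samples)) < 0.9, index=probes)
    coords = rng.normal(size=(n_samples, 3))
    return tx.DonorSampleTable(
        donor_id="d0", coords_mm=coords, expression=expr,
        probe_gene=genes, above_background=bg, reference=ref,
    )


class TestProbeFiltering:
    def test_fraction_boundary_half(self):
        t = _toy_table()
        n = t.above_background.shape[1]
        t.above_background.iloc[0] = [True] * (n // 2) + [False] * (n - n // 2)
        t.above_background.iloc[1] = [True] * (n // 2 - 1) + [False] * (
            n - n // 2 + 1
        )
        kept = tx.filter_probes_by_background(t, 0.5)
        assert "A_p0" in kept and "A_p1" not in kept

    def test_matches_counting_oracle(self):
        t = _toy_table(seed=3)
        kept = tx.filter_probes_by_background(t, 0.5)
        oracle = [
            p
            for p in t.expression.index
            if t.above_background.loc[p].sum() / t.above_background.shape[1] >= 0.5
        ]
        assert kept == oracle

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tx.filter_probes_by_background(_toy_table(), 0.0)


class TestProbeSelection:
    def test_single_probe_gene_kept(self):
        t = _toy_table()
        chosen = tx.select_probe_per_gene(t.expression, t.probe_gene, t.reference)
        assert chosen["B"] == "B_p0"

    def test_probe_equal_to_reference_wins(self):
        t = _toy_table(seed=1)
        t.expression.loc["A_p1"] = t.reference.loc["A"]
        chosen = tx.select_probe_per_gene(t.expression, t.probe_gene, t.reference)
        assert chosen["A"] == "A_p1"

    def test_matches_exhaustive_max_correlation_search(self):
        t = _toy_table(seed=2)
        chosen = tx.select_probe_per_gene(t.expression, t.probe_gene, t.reference)
        for gene in ["A", "B", "C"]:
            probes = t.probe_gene.index[t.probe_gene == gene]
            rs = {
                p: np.corrcoef(t.expression.loc[p], t.reference.loc[gene])[0, 1]
                for p in probes
            }
            assert chosen[gene] == max(rs, key=rs.get)

    def test_constant_probe_skipped_with_fallback(self):
        t = _toy_table(seed=4)
        t.expression.loc["A_p0"] = 1.0  # zero variance
        chosen = tx.select_probe_per_gene(t.expression, t.probe_gene, t.reference)
        assert chosen["A"] == "A_p1"


class TestSampleAssignment:
    def test_sample_at_labeled_voxel_and_far_sample(self, atlas90):
        cent = atlas90.centroids_mm[:1]
        far = np.array([[500.0, 0.0, 0.0]])
        labels = tx.assign_samples_to_regions(
            np.vstack([cent, far]), atlas90, max_distance_mm=2.0
        )
        assert labels[0] == 1
        assert labels[1] == 0

    def test_matches_brute_force_nearest_voxel(self, atlas90):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-25, 25, size=(40, 3))
        got = tx.assign_samples_to_regions(coords, atlas90, max_distance_mm=4.0)
        vox = np.argwhere(atlas90.labels > 0)
        world = vox @ atlas90.affine[:3, :3].T + atlas90.affine[:3, 3]
        for i, c in enumerate(coords):
            d = np.linalg.norm(world - c, axis=1)
            j = d.argmin()
            ijk = np.round(
                np.linalg.inv(atlas90.affine)[:3, :3] @ c
                + np.linalg.inv(atlas90.affine)[:3, 3]
            ).astype(int)
            inside = np.all((ijk >= 0) & (ijk < atlas90.labels.shape))
            if inside:
                assert got[i] == atlas90.labels[tuple(ijk)]
            elif d[j] <= 4.0:
                assert got[i] == atlas90.labels[tuple(vox[j])]
            else:
                assert got[i] == 0


class TestScaledRobustSigmoid:
    def test_formula_on_one_to_five(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = tx.scaled_robust_sigmoid(x)
        raw = 1.0 / (1.0 + np.exp(-(x - 3.0) / (2.0 / 1.35)))
        oracle = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(out, oracle)
        assert out[0] == 0.0 and out[-1] == 1.0

    def test_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            tx.scaled_robust_sigmoid(x),
            tx.scaled_robust_sigmoid(3.0 * x + 7.0),
            atol=1e-12,
        )

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError):
            tx.scaled_robust_sigmoid(np.ones(10))


class TestDifferentialStability:
    def test_identical_and_negated_profiles(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(
            rng.normal(size=(6, 2)), columns=["g1", "g2"],
            index=[1, 2, 3, 4, 5, 6],
        )
        ds = tx.differential_stability({"a": prof, "b": prof.copy()})
        np.testing.assert_allclose(ds.to_numpy(), 1.0)
        ds2 = tx.differential_stability({"a": prof, "b": -prof})
        np.testing.assert_allclose(ds2.to_numpy(), -1.0)

    def test_three_donor_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        mats = {
            d: pd.DataFrame(rng.normal(size=(8, 1)), columns=["g"],
                            index=range(8))
            for d in "abc"
        }
        ds = tx.differential_stability(mats)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        oracle = np.mean(
            [mats[i]["g"].corr(mats[j]["g"]) for i, j in pairs]
        )
        assert ds["g"] == pytest.approx(oracle)


class TestPlsFit:
    def test_response_equal_to_one_gene_column(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"g{i}" for i in range(5)])
        y = x["g2"].copy()
        fit = tx.pls_fit(x, y, 1)
        assert np.argmax(np.abs(fit.weights[:, 0])) == 2
        assert fit.explained_variance[0] > 0.95

    def test_first_component_weight_proportional_to_xty(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(6, 4)))
        y = pd.Series(rng.normal(size=6))
        fit = tx.pls_fit(x, y, 1)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        c = xs.to_numpy().T @ ys.to_numpy()
        cosine = abs(
            c @ fit.weights[:, 0] / np.linalg.norm(c)
            / np.linalg.norm(fit.weights[:, 0])
        )
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_invariant_to_gene_rotation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 6))
        y = pd.Series(x[:, 0] + 0.3 * rng.normal(size=30))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = tx.pls_fit(pd.DataFrame(x), y, 2, standardize=False)
        b = tx.pls_fit(pd.DataFrame(x @ q), y, 2, standardize=False)
        np.testing.assert_allclose(
            a.explained_variance, b.explained_variance, rtol=1e-8
        )

    def test_matches_sklearn_pls_regression(self):
        # independent implementation cross-check (scores up to sign)
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(25, 8)))
        y = pd.Series(rng.normal(size=25) + x[0].to_numpy())
        mine = tx.pls_fit(x, y, 2)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ref = PLSRegression(n_components=2, scale=False).fit(
            xs.to_numpy(), ys.to_numpy()
        )
        for k in range(2):
            cos = np.corrcoef(mine.scores[:, k], ref.x_scores_[:, k])[0, 1]
            assert abs(cos) == pytest.approx(1.0, abs=1e-8)

    def test_region_order_invariance(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(15, 4)), index=range(15))
        y = pd.Series(rng.normal(size=15), index=range(15))
        perm = rng.permutation(15)
        a = tx.pls_fit(x, y, 2)
        b = tx.pls_fit(x.iloc[perm], y.iloc[perm], 2)
        np.testing.assert_allclose(
            a.explained_variance, b.explained_variance, rtol=1e-9
        )
        np.testing.assert_allclose(a.weights, b.weights, rtol=1e-8, atol=1e-10)

    def test_undefined_entries_rejected(self):
        x = pd.DataFrame(np.ones((6, 2)) * np.nan)
        with pytest.raises(ValueError):
            tx.pls_fit(x, pd.Series(np.zeros(6)), 1)

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(size=(8, 2)))
        y = pd.Series(rng.normal(size=8))
        with pytest.warns(UserWarning, match="truncated"):
            fit = tx.pls_fit(x, y, 5)
        assert fit.scores.shape[1] <= 2


class TestSpinNull:
    def test_permutation_mode_rows_are_permutations(self, atlas90):
        null = tx.build_spin_null(
            atlas90.sphere_coords, 20, seed=0, mode="permutation",
            hemispheres=atlas90.regions["hemisphere"].to_numpy(),
        )
        for row in null.permutations:
            assert sorted(row) == list(range(90))

    def test_hemispheres_stay_separate(self, atlas90):
        null = tx.build_spin_null(
            atlas90.sphere_coords, 10, seed=1, mode="nearest",
            hemispheres=atlas90.regions["hemisphere"].to_numpy(),
        )
        left = np.arange(45)
        assert np.all(null.permutations[:, left] < 45)
        assert np.all(null.permutations[:, 45:] >= 45)

    def test_spin_null_wider_than_iid_permutation_null(self, atlas90):
        # smooth maps: rotations preserve autocorrelation, shuffles destroy it
        rng = np.random.default_rng(2)
        from dalff.synth import _spatial_smoother

        sm = _spatial_smoother(atlas90.centroids_mm, 10.0)
        a = sm @ rng.normal(size=90)
        b = sm @ rng.normal(size=90)
        null = tx.build_spin_null(
            atlas90.sphere_coords, 500, seed=3,
            hemispheres=atlas90.regions["hemisphere"].to_numpy(),
        )
        spin_rs = [
            np.corrcoef(a[p], b)[0, 1] for p in null.permutations
        ]
        iid_rs = [
            np.corrcoef(rng.permutation(a), b)[0, 1] for _ in range(500)
        ]
        assert np.std(spin_rs) > np.std(iid_rs)

    def test_spin_p_self_correlation_minimum(self, atlas90):
        rng = np.random.default_rng(4)
        null = tx.build_spin_null(atlas90.sphere_coords, 99, seed=5)
        a = rng.normal(size=90)
        assert tx.spin_p(a, a, null) == pytest.approx(1 / 100)

    def test_spin_p_bounds_and_one_spin_edge(self, atlas90):
        rng = np.random.default_rng(6)
        null = tx.build_spin_null(atlas90.sphere_coords, 1, seed=7)
        for _ in range(5):
            p = tx.spin_p(rng.normal(size=90), rng.normal(size=90), null)
            assert p in (0.5, 1.0)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            tx.build_spin_null(np.eye(3)[:2], 10)


@pytest.fixture(scope="module")
def planted(atlas90):
    rng = np.random.default_rng(0)
    g = rng.normal(size=90)
    target = pd.Series(g, index=atlas90.regions.index)
    _, mat, truth = dalff.generate_expression(
        60, 2, target, atlas90.centroids_mm,
        planted_fraction=0.2, noise_sd=0.3, seed=1,
    )
    y = pd.Series(g + 0.4 * rng.normal(size=90), index=target.index)
    return mat, y, truth


class TestBootstrapGeneZ:
    def test_planted_genes_significant_with_correct_signs(self, planted):
        mat, y, truth = planted
        table = tx.bootstrap_gene_z(mat, y, 1, n_boot=500, seed=0,
                                    n_components=1)
        for gene in truth.index[truth.planted]:
            expected = "PLS+" if truth.loc[gene, "sign"] > 0 else "PLS-"
            assert table.loc[gene, "class"] == expected

    def test_flipping_response_sign_swaps_classes(self, planted):
        mat, y, _ = planted
        a = tx.bootstrap_gene_z(mat, y, 1, n_boot=200, seed=1, n_components=1)
        b = tx.bootstrap_gene_z(mat, -y, 1, n_boot=200, seed=1, n_components=1)
        swap = {"PLS+": "PLS-", "PLS-": "PLS+", "ns": "ns"}
        assert list(b["class"]) == [swap[c] for c in a["class"]]
        np.testing.assert_allclose(b["z"], -a["z"], rtol=1e-9)

    def test_duplicate_gene_columns_get_matching_z(self, planted):
        mat, y, _ = planted
        dup = mat.copy()
        dup["dup_of_first"] = dup[dup.columns[0]]
        table = tx.bootstrap_gene_z(dup, y, 1, n_boot=2000, seed=2,
                                    n_components=1)
        z1 = table.loc[dup.columns[0], "z"]
        z2 = table.loc["dup_of_first", "z"]
        assert z2 == pytest.approx(z1, rel=0.05)

    def test_small_bootstrap_count_rejected(self, planted):
        mat, y, _ = planted
        with pytest.raises(ValueError):
            tx.bootstrap_gene_z(mat, y, 1, n_boot=10)


class TestExportGeneLists:
    def test_infinite_cut_gives_empty_z_lists(self, tmp_path):
        table = pd.DataFrame(
            {"z": [3.0, -4.0], "q": [0.001, 0.002],
             "class": ["PLS+", "PLS-"]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        paths = tx.export_gene_lists(table, np.inf, tmp_path)
        assert tx.read_gene_list(paths["z_above_cut"]) == []
        assert tx.read_gene_list(paths["z_below_cut"]) == []

    def test_lists_consistent_with_classes_and_round_trip(self, tmp_path):
        table = pd.DataFrame(
            {"z": [6.0, -7.0, 0.5], "q": [0.001, 0.002, 0.9],
             "class": ["PLS+", "PLS-", "ns"]},
            index=pd.Index(["g1", "g2", "g3"], name="gene"),
        )
        paths = tx.export_gene_lists(table, 5.0, tmp_path)
        assert tx.read_gene_list(paths["pls_pos_fdr"]) == ["g1"]
        assert tx.read_gene_list(paths["pls_neg_fdr"]) == ["g2"]
        assert tx.read_gene_list(paths["z_above_cut"]) == ["g1"]
        assert tx.read_gene_list(paths["z_below_cut"]) == ["g2"]


class TestBuildExpressionMatrix:
    def test_pipeline_recovers_planted_gradient(self, atlas90):
        rng = np.random.default_rng(1)
        left = atlas90.hemisphere_labels("L")
        g = rng.normal(size=len(left))
        target = pd.Series(g, index=left)
        cent = atlas90.regions.loc[left, ["cx_mm", "cy_mm", "cz_mm"]].to_numpy()
        tables, _, truth = dalff.generate_expression(
            30, 3, target, cent, planted_fraction=0.2, noise_sd=0.2, seed=2
        )
        mat = tx.build_expression_matrix(tables, atlas90,
                                         hemisphere_filter="left")
        assert list(mat.index) == sorted(left)
        assert (mat.to_numpy() >= 0).all() and (mat.to_numpy() <= 1).all()
        planted = [
            gene for gene in truth.index[truth.planted] if gene in mat.columns
        ]
        assert len(planted) >= 4
        rs = [abs(mat[gene].corr(target)) for gene in planted]
        assert np.mean(rs) > 0.8


class TestBenjaminiHochberg:
    def test_known_step_up_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.3])), [0.3])

    def test_all_ones_give_no_rejections(self):
        q = bh_qvalues(np.ones(5))
        np.testing.assert_allclose(q, 1.0)
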