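"""Distance matrix, clustering, prototype mapping, frequency statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score

import reachtrace as rt
from conftest import dataset_from_blocks

TABLE1 = pd.DataFrame(
    [[506, 116, 54, 52, 16], [165, 38, 37, 56, 24]],
    index=["Typical", "Atypical"],
    columns=["straight", "curved", "cCoM", "dCoM", "dCoM2"],
)


class TestDistanceMatrix:
    def test_identical_trajectories_have_zero_distance(self):
        block = np.column_stack([np.arange(5.0), np.linspace(0, -4, 5),
                                 np.linspace(0, 6, 5)])
        dm = rt.distance_matrix(dataset_from_blocks([block, block.copy()]),
                                rt.RAW)
        assert dm.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_offsets_sum_to_two(self):
        a = np.array([[0.0, 0, 0], [1.0, 1, 0]])
        b = np.array([[0.0, 0, 1], [1.0, 1, 1]])
        dm = rt.distance_matrix(dataset_from_blocks([a, b]), rt.RAW)
        assert dm.iloc[0, 1] == pytest.approx(2.0)
        assert dm.iloc[1, 0] == pytest.approx(2.0)
        assert dm.iloc[0, 0] == 0.0

    def test_joint_translation_leaves_distance_unchanged(self):
        rng = np.random.default_rng(1)
        a = np.column_stack([np.arange(8.0), rng.normal(size=8), rng.normal(size=8)])
        b = np.column_stack([np.arange(8.0), rng.normal(size=8), rng.normal(size=8)])
        d0 = rt.distance_matrix(dataset_from_blocks([a, b]), rt.RAW).iloc[0, 1]
        a2, b2 = a.copy(), b.copy()
        a2[:, 1:] += (31.0, -17.0)
        b2[:, 1:] += (31.0, -17.0)
        d1 = rt.distance_matrix(dataset_from_blocks([a2, b2]), rt.RAW).iloc[0, 1]
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_unequal_point_counts_direct_to_resampling(self, synth_small):
        ds, _ = synth_small
        with pytest.raises(ValueError, match="resample"):
            rt.distance_matrix(ds, rt.RAW)


class TestClustering:
    def test_two_well_separated_shapes_split_perfectly(self):
        t = np.arange(10.0)
        line = np.column_stack([t, -60 * t, 90 * t])
        hook = np.column_stack([t, 60 * t, 90 * t])
        blocks = [line + np.array([0, 1, 1]) * i for i in range(3)]
        blocks += [hook + np.array([0, 1, 1]) * i for i in range(3)]
        ds = dataset_from_blocks(blocks)
        out = rt.cluster_hierarchical(ds, rt.RAW, n_clusters=2)
        labels = out.table.set_index("trial_id")["label"]
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_five_type_low_noise_mixture_recovered(self, balanced_lownoise):
        ds, truth = balanced_lownoise
        out = rt.cluster_hierarchical(ds, n_clusters=5)
        tt = truth.set_index("trial_id").loc[out.table.trial_id, "true_type"]
        assert adjusted_rand_score(tt, out.table["label"]) >= 0.9

    def test_partition_is_invariant_to_trial_order(self, balanced_lownoise):
        ds, _ = balanced_lownoise
        ids = ds.trial_ids[:60]
        sub = rt.subset(ds, ids)
        perm = rt.subset(ds, ids[::-1])
        a = rt.cluster_hierarchical(sub, n_clusters=4).table
        b = rt.cluster_hierarchical(perm, n_clusters=4).table
        part_a = {frozenset(g.trial_id) for _, g in a.groupby("label")}
        part_b = {frozenset(g.trial_id) for _, g in b.groupby("label")}
        assert part_a == part_b

    def test_labels_ordered_by_descending_size(self, balanced_lownoise):
        ds, _ = balanced_lownoise
        counts = rt.cluster_hierarchical(ds, n_clusters=5).counts()
        sizes = [counts[str(i)] for i in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_clusters_is_an_error(self, balanced_lownoise):
        ds, _ = balanced_lownoise
        with pytest.raises(ValueError, match="n_clusters"):
            rt.cluster_hierarchical(ds, n_clusters=1)


class TestPrototypeMapping:
    def test_exact_dcom_trace_maps_with_zero_distance(self):
        # dense sampling leg by leg so the corner vertex itself is a sample
        poly = np.array([(0.0, 0.0), (665.0, 974.0), (-665.0, 974.0)])
        leg1 = np.linspace(poly[0], poly[1], 40)
        leg2 = np.linspace(poly[1], poly[2], 41)[1:]
        pts = np.vstack([leg1, leg2])
        block = np.column_stack([np.linspace(0, 2000, len(pts)), pts])
        out = rt.map_to_prototypes(dataset_from_blocks([block]), rt.RAW)
        assert out.table["label"].iloc[0] == "dCoM"
        assert out.table["distance"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_straight_trace_maps_to_straight(self):
        block = np.column_stack([np.linspace(0, 1000, 40),
                                 np.linspace(0, -665, 40),
                                 np.linspace(0, 974, 40)])
        out = rt.map_to_prototypes(dataset_from_blocks([block]), rt.RAW)
        assert out.table["label"].iloc[0] == "straight"
        assert out.table["distance"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_low_noise_mixture_recovery_above_95_percent(self, balanced_lownoise):
        ds, truth = balanced_lownoise
        out = rt.map_to_prototypes(ds)
        tt = truth.set_index("trial_id").loc[out.table.trial_id, "true_type"]
        assert (out.table["label"].to_numpy() == tt.to_numpy()).mean() >= 0.95

    def test_rigid_rescaling_of_the_world_keeps_labels(self, balanced_lownoise):
        ds, _ = balanced_lownoise
        ids = ds.trial_ids[:40]
        sub = rt.subset(ds, ids)
        before = rt.map_to_prototypes(sub).table["label"]
        arr = sub.get(rt.LENGTH_NORMALIZED).copy()
        xi = arr.feature_index(rt.XPOS)
        yi = arr.feature_index(rt.YPOS)
        arr.values[:, :, xi] = arr.values[:, :, xi] * 0.4 + 120.0
        arr.values[:, :, yi] = arr.values[:, :, yi] * 0.4 - 55.0
        moved = sub.with_representation(rt.LENGTH_NORMALIZED, arr, "scale")
        after = rt.map_to_prototypes(moved).table["label"]
        assert (before.to_numpy() == after.to_numpy()).all()

    def test_coincident_endpoints_stay_unassigned(self):
        loop = np.column_stack([np.linspace(0, 500, 30),
                                100 * np.sin(np.linspace(0, 2 * np.pi, 30)),
                                100 - 100 * np.cos(np.linspace(0, 2 * np.pi, 30))])
        loop[-1, 1:] = loop[0, 1:]
        straight = np.column_stack([np.linspace(0, 500, 30),
                                    np.linspace(0, -600, 30),
                                    np.linspace(0, 900, 30)])
        out = rt.map_to_prototypes(dataset_from_blocks([loop, straight]), rt.RAW)
        assert out.table["label"].isna().iloc[0]
        assert out.table["label"].iloc[1] == "straight"

    def test_cluster_means_map_to_the_dominant_top_down_labels(self, balanced_lownoise):
        ds, truth = balanced_lownoise
        clus = rt.cluster_hierarchical(ds, n_clusters=5)
        mapped = rt.map_to_prototypes(ds)
        joined = clus.table.merge(mapped.table, on="trial_id",
                                  suffixes=("_cluster", "_proto"))
        for _, grp in joined.groupby("label_cluster"):
            dominant = grp["label_proto"].mode().iloc[0]
            assert (grp["label_proto"] == dominant).mean() > 0.9


class TestFrequencyStatistics:
    def test_printed_contingency_table_chi2(self):
        res = rt.chi_square_independence(TABLE1)
        assert res.chi2 == pytest.approx(57.97, abs=0.005)
        assert res.df == 4
        assert res.p < 0.001

    def test_printed_residuals_to_two_decimals(self):
        res = rt.chi_square_independence(TABLE1)
        r = res.pearson_residuals
        expected = {
            ("Typical", "straight"): 1.70, ("Typical", "curved"): 0.80,
            ("Typical", "cCoM"): -1.21, ("Typical", "dCoM"): -2.71,
            ("Typical", "dCoM2"): -2.26, ("Atypical", "straight"): -2.59,
            ("Atypical", "curved"): -1.22, ("Atypical", "cCoM"): 1.84,
            ("Atypical", "dCoM"): 4.13, ("Atypical", "dCoM2"): 3.45,
        }
        for (row, col), val in expected.items():
            assert r.loc[row, col] == pytest.approx(val, abs=0.005)

    def test_residual_squares_sum_to_chi2(self):
        res = rt.chi_square_independence(TABLE1)
        assert (res.pearson_residuals**2).to_numpy().sum() == pytest.approx(
            res.chi2, abs=1e-9)

    def test_uniform_table_has_zero_statistic(self):
        O = pd.DataFrame([[10, 10], [10, 10]])
        res = rt.chi_square_independence(O)
        assert res.chi2 == 0.0
        np.testing.assert_array_equal(res.pearson_residuals.to_numpy(), 0.0)

    def test_agrees_with_scipy_uncorrected(self):
        rng = np.random.default_rng(5)
        O = pd.DataFrame(rng.integers(5, 80, (3, 4)))
        res = rt.chi_square_independence(O)
        chi2, p, dof, _ = chi2_contingency(O.to_numpy(), correction=False)
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df == dof

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="zero row or column"):
            rt.chi_square_independence(pd.DataFrame([[0, 0], [3, 4]]))

    def test_frequency_table_from_assignment(self, synth_prepped):
        ds, truth = synth_prepped
        mapped = rt.map_to_prototypes(ds)
        table = rt.type_frequency_table(mapped, ds.trial_table, "Condition",
                                        labels=rt.TYPE_ORDER)
        assert table.to_numpy().sum() == mapped.table["label"].notna().sum()
        assert list(table.index) == ["atypical", "typical"]

    def test_dcom_residual_grows_with_dcom_proportion(self):
        """Shifting mixture mass into dCoM raises that cell's residual."""
        residuals = []
        for extra in (0.0, 0.12, 0.24):
            mix_a = {"straight": 0.6 - extra, "curved": 0.2, "cCoM": 0.1,
                     "dCoM": 0.1 + extra, "dCoM2": 0.0}
            mix_t = {"straight": 0.6, "curved": 0.2, "cCoM": 0.1,
                     "dCoM": 0.1, "dCoM2": 0.0}
            spec = rt.SynthSpec(seed=505, n_subjects=60, type_mixture={
                "typical": mix_t, "atypical": mix_a})
            ds, truth = rt.generate(spec)
            merged = ds.trial_table.merge(truth[["trial_id", "true_type"]],
                                          on="trial_id")
            table = pd.crosstab(merged["Condition"], merged["true_type"])
            res = rt.chi_square_independence(table)
            residuals.append(res.pearson_residuals.loc["atypical", "dCoM"])
        assert residuals[0] < residuals[1] < residuals[2]


class TestOrdinalExport:
    def test_competition_ranks_for_three_labels(self):
        table = pd.DataFrame({"trial_id": ["a", "b", "c"],
                              "label": ["straight", "cCoM", "dCoM2"],
                              "distance": [1.0, 2.0, 3.0]})
        out = rt.ordinal_export(rt.TypeAssignment(table))
        assert out["rank"].tolist() == [1, 3, 5]

    def test_rank_column_respects_the_documented_order(self):
        table = pd.DataFrame({"trial_id": list("abcde"),
                              "label": rt.TYPE_ORDER,
                              "distance": np.ones(5)})
        out = rt.ordinal_export(rt.TypeAssignment(table))
        assert out.sort_values("rank")["label"].tolist() == rt.TYPE_ORDER

    def test_row_count_equals_assigned_trials(self, synth_prepped):
        ds, _ = synth_prepped
        mapped = rt.map_to_prototypes(ds)
        out = rt.ordinal_export(mapped, trial_table=ds.trial_table)
        assert len(out) == mapped.table["label"].notna().sum()
        assert {"Condition", "rank"} <= set(out.columns)
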