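"""Trial-level indices: frozen oracles, invariances, aggregation contracts."""

import numpy as np
import pandas as pd
import pytest

import reachtrace as rt
from conftest import dataset_from_blocks, random_trajectory


def _measures_of(points, **kwargs):
    t = np.arange(len(points), dtype=float) * 100.0
    block = np.column_stack([t, np.asarray(points, dtype=float)])
    return rt.compute_measures(dataset_from_blocks([block]), **kwargs).iloc[0]


class TestCurvature:
    def test_three_point_frozen_example(self):
        """Point-line distance and shoelace oracles for a bent trajectory."""
        row = _measures_of([(0, 0), (30, 40), (-100, 100)])
        assert row["MAD"] == pytest.approx(70 / np.sqrt(2), abs=1e-9)
        assert row["MD_above"] == pytest.approx(70 / np.sqrt(2), abs=1e-9)
        assert row["AD"] == pytest.approx(70 / np.sqrt(2) / 3, abs=1e-9)
        assert row["AUC"] == pytest.approx(3500.0, abs=1e-9)
        assert row["MAD_time"] == 100.0

    def test_straight_trajectory_has_zero_curvature(self):
        row = _measures_of([(0, 0), (-25, 50), (-50, 100)])
        for col in ("MAD", "MD_above", "AD", "AUC"):
            assert row[col] == pytest.approx(0.0, abs=1e-9)
        assert row["x_flips"] == 0

    def test_deviation_away_from_nonchosen_side_is_negative(self):
        # left-ending trajectory bulging left (away from the nonchosen side)
        row = _measures_of([(0, 0), (-80, 40), (-100, 100)])
        assert row["MAD"] < 0
        assert row["MD_above"] == 0.0
        assert row["AUC"] < 0

    def test_mirrored_trajectory_flips_signs(self):
        pts = [(0, 0), (30, 40), (-100, 100)]
        mirrored = [(-x, y) for x, y in pts]
        a, b = _measures_of(pts), _measures_of(mirrored)
        assert a["MAD"] == pytest.approx(b["MAD"], abs=1e-9)
        assert a["AUC"] == pytest.approx(b["AUC"], abs=1e-9)

    def test_auc_equals_rotated_trapezoid_integration(self):
        """Shoelace AUC against integration in chord-aligned coordinates."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            block = random_trajectory(rng, n_min=4, n_max=30)
            pts = block[:, 1:]
            if np.allclose(pts[0], pts[-1]):
                continue
            row = rt.compute_measures(dataset_from_blocks([block])).iloc[0]
            d = pts[-1] - pts[0]
            L = np.hypot(*d)
            # rotate so the chord lies along +y; the signed x is the deviation
            c, s = d[1] / L, d[0] / L
            rel = pts - pts[0]
            u = c * rel[:, 0] - s * rel[:, 1]   # chord-perpendicular
            v = s * rel[:, 0] + c * rel[:, 1]   # chord-parallel
            area = np.sum(0.5 * (u[1:] + u[:-1]) * np.diff(v))
            factor = 1.0 if d[0] > 0 else -1.0
            assert row["AUC"] == pytest.approx(-factor * area, rel=1e-9, abs=1e-9)

    def test_coincident_endpoints_leave_curvature_missing(self):
        row = _measures_of([(0, 0), (50, 50), (0, 0)])
        assert np.isnan(row["MAD"]) and np.isnan(row["AUC"])
        assert row["x_flips"] == 1  # complexity still defined


class TestComplexity:
    def test_flip_counting_example(self):
        row = _measures_of([(0, 0), (-20, 10), (-10, 20), (-40, 30), (-35, 40)])
        assert row["x_flips"] == 3

    def test_reversal_counting_example(self):
        row = _measures_of([(0, 0), (15, 10), (-5, 20), (-60, 30)])
        assert row["x_reversals"] == 1

    def test_touching_the_midline_is_not_a_reversal(self):
        row = _measures_of([(0, 0), (10, 10), (0, 20), (15, 30)])
        assert row["x_reversals"] == 0

    def test_flip_threshold_suppresses_small_deltas(self):
        pts = [(0, 0), (-20, 10), (-19, 20), (-40, 30)]
        assert _measures_of(pts)["x_flips"] == 2
        assert _measures_of(pts, flip_threshold=2.0)["x_flips"] == 0

    def test_flips_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(22)
        block = random_trajectory(rng)
        fast = block.copy()
        fast[:, 0] *= 0.25
        a = rt.compute_measures(dataset_from_blocks([block])).iloc[0]
        b = rt.compute_measures(dataset_from_blocks([fast])).iloc[0]
        assert a["x_flips"] == b["x_flips"]
        assert a["x_reversals"] == b["x_reversals"]


class TestTemporal:
    def test_idle_then_movement_decomposition(self):
        # movement only in the last two of three 100-ms intervals
        row = _measures_of([(0, 0), (0, 0), (5, 5), (10, 10)])
        assert row["RT"] == 300.0
        assert row["movement_time"] == 200.0
        assert row["idle_time"] == 100.0
        assert row["initiation_time"] == 100.0
        assert row["motor_pauses"] == 0.0

    def test_immediate_movement_has_zero_initiation(self):
        row = _measures_of([(0, 0), (5, 5), (10, 10)])
        assert row["initiation_time"] == 0.0

    def test_mid_trial_pause_counts_as_motor_pause(self):
        row = _measures_of([(0, 0), (5, 5), (5, 5), (10, 10)])
        assert row["idle_time"] == 100.0
        assert row["initiation_time"] == 0.0
        assert row["motor_pauses"] == 100.0

    def test_rt_identity_and_ordering_invariants(self, synth_prepped):
        ds, _ = synth_prepped
        mt = rt.compute_measures(ds)
        np.testing.assert_allclose(
            mt["RT"], mt["idle_time"] + mt["movement_time"], atol=1e-9)
        assert (mt["initiation_time"] <= mt["idle_time"] + 1e-9).all()
        assert (mt["idle_time"] <= mt["RT"] + 1e-9).all()

    def test_vel_and_acc_maxima_present_after_derivatives(self, synth_small):
        ds, _ = synth_small
        mt = rt.compute_measures(rt.derivatives(ds))
        assert (mt["vel_max"] > 0).all()
        assert mt["acc_max"].notna().all()


class TestDeviationBounds:
    def test_md_above_and_ad_bounded_by_max_deviation(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            block = random_trajectory(rng, n_min=4, n_max=25)
            pts = block[:, 1:]
            if np.allclose(pts[0], pts[-1]):
                continue
            from reachtrace.measures import signed_deviations
            dev, _ = signed_deviations(pts)
            row = rt.compute_measures(dataset_from_blocks([block])).iloc[0]
            peak = np.abs(dev).max()
            assert row["MD_above"] <= peak + 1e-9
            assert abs(row["AD"]) <= peak + 1e-9
            assert abs(row["MAD"]) == pytest.approx(peak, abs=1e-9)


class TestSampleEntropy:
    def test_constant_series_has_zero_entropy(self):
        assert rt.sample_entropy(np.full(50, 3.0)) == 0.0

    def test_periodic_series_has_zero_entropy(self):
        series = np.tile([0.0, 1.0], 25)
        assert rt.sample_entropy(series, rt.SampleEntropyParams(r=0.1)) == 0.0

    def test_iid_noise_has_positive_entropy(self):
        # series long enough that template matches exist at both lengths
        positive = 0
        for seed in range(500):
            x = np.random.default_rng(seed).normal(size=300)
            if rt.sample_entropy(x) > 0:
                positive += 1
        assert positive >= 495  # 99% of seeded replicates

    def test_short_series_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            rt.sample_entropy(np.arange(4.0), rt.SampleEntropyParams(m=3))

    def test_template_counting_against_naive_oracle(self):
        """Direct O(n^2 m) pair counting reproduces -ln(A/B)."""
        rng = np.random.default_rng(24)
        for _ in range(20):
            x = rng.normal(size=40)
            m, r = 3, 0.3
            nt = len(x) - m
            A = B = 0
            for i in range(nt):
                for j in range(nt):
                    if i == j:
                        continue
                    if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                        B += 1
                    if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                        A += 1
            expected = -np.log(A / B) if A and B else np.nan
            got = rt.sample_entropy(x, rt.SampleEntropyParams(m=m, r=r))
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestStandardizeAggregate:
    def test_three_values_standardize_to_unit_steps(self):
        table = pd.DataFrame({"g": ["a"] * 3, "v": [1.0, 2.0, 3.0]})
        out = rt.standardize(table, ["v"], within="g")
        np.testing.assert_allclose(out["v_z"], [-1, 0, 1])

    def test_groups_standardized_independently(self):
        table = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4,
                              "v": [1, 2, 3, 4, 10, 20, 30, 40.0]})
        out = rt.standardize(table, ["v"], within="g")
        for _, grp in out.groupby("g"):
            assert grp["v_z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["v_z"].std(ddof=1) == pytest.approx(1.0)

    def test_standardize_is_idempotent(self):
        table = pd.DataFrame({"v": np.random.default_rng(0).normal(2, 5, 30)})
        once = rt.standardize(table, ["v"])
        twice = rt.standardize(once.rename(columns={"v_z": "w"}), ["w"])
        np.testing.assert_allclose(twice["w_z"], once["v_z"], atol=1e-12)

    def test_aggregate_means_per_cell(self):
        table = pd.DataFrame({
            "subject_id": ["s1", "s1", "s2", "s2"],
            "cond": ["a", "b", "a", "b"],
            "v": [1.0, 2.0, 3.0, 4.0],
        })
        out = rt.aggregate(table, ["v"], ["cond", "subject_id"])
        assert len(out) == 4 and set(out["v"]) == {1.0, 2.0, 3.0, 4.0}

    def test_subject_first_aggregation_is_unweighted(self):
        # s1 contributes 3 trials, s2 one: subject means get equal weight
        table = pd.DataFrame({
            "subject_id": ["s1"] * 3 + ["s2"],
            "cond": ["a"] * 4,
            "v": [0.0, 0.0, 0.0, 8.0],
        })
        out = rt.aggregate(table, ["v"], ["cond"], subject_id="subject_id")
        assert out["v"].iloc[0] == pytest.approx(4.0)  # not the pooled 2.0

    def test_constant_column_aggregates_to_itself(self):
        table = pd.DataFrame({"cond": ["a", "a", "b"], "v": [7.0] * 3})
        out = rt.aggregate(table, ["v"], ["cond"])
        assert (out["v"] == 7.0).all()


class TestCorrelationReport:
    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(25)
        mt = pd.DataFrame({"MAD": rng.normal(size=30)})
        mt["AD"] = mt["MAD"]
        out = rt.index_correlation_report(mt, ["MAD", "AD"])
        assert out.loc["MAD", "AD"] == pytest.approx(1.0)

    def test_antimonotone_pair_has_spearman_minus_one(self):
        v = np.random.default_rng(26).normal(size=30)
        mt = pd.DataFrame({"MAD": v, "AD": -np.exp(v)})
        out = rt.index_correlation_report(mt, ["MAD", "AD"], method="spearman")
        assert out.loc["MAD", "AD"] == pytest.approx(-1.0)

    def test_eleven_standard_indices_on_synthetic_data(self, synth_prepped):
        ds, _ = synth_prepped
        mt = rt.add_sample_entropy(ds, rt.compute_measures(ds))
        out = rt.index_correlation_report(mt)
        assert out.shape == (11, 11)
        np.testing.assert_allclose(out.to_numpy(), out.to_numpy().T, atol=1e-12)
        assert out.loc["MAD", "MD_above"] > 0.8  # near-duplicate indices

    def test_too_few_rows_is_an_error(self):
        with pytest.raises(ValueError, match="3 complete rows"):
            rt.index_correlation_report(
                pd.DataFrame({"MAD": [1.0, 2.0], "AD": [1.0, 2.0]}), ["MAD", "AD"])


class TestConflictSensitivity:
    def test_com_heavy_mixture_raises_every_index_family(self):
        """More change-of-mind types -> larger curvature, complexity, entropy."""
        calm = {"straight": 0.8, "curved": 0.2, "cCoM": 0.0, "dCoM": 0.0,
                "dCoM2": 0.0}
        conflicted = {"straight": 0.2, "curved": 0.2, "cCoM": 0.2, "dCoM": 0.2,
                      "dCoM2": 0.2}
        spec = rt.SynthSpec(seed=303, n_subjects=10, type_mixture={
            "typical": calm, "atypical": conflicted})
        ds, _ = rt.generate(spec)
        ds = rt.remap_symmetric(ds)
        ds = rt.align_start(ds)
        ds = rt.time_normalize(ds)
        mt = rt.add_sample_entropy(ds, rt.compute_measures(ds))
        g = ds.trial_table.merge(mt, on="trial_id").groupby("Condition")[
            ["MAD", "AD", "AUC", "x_flips", "sample_entropy"]].mean()
        assert (g.loc["atypical"] > g.loc["typical"]).all()
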