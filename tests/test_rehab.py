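import numpy as np
import pytest

import palsymetry as pm
from palsymetry.errors import (
    DimensionMismatchError,
    RegionConfigError,
    UndefinedAsymmetryError,
)


def mesh(vertices):
    return pm.FaceMesh(vertices=np.asarray(vertices, dtype=float))


def eval_from_means(means, n=10):
    return pm.Evaluation(
        session_id="s", stats={
            k: pm.RegionStats(e_sum=v * n, e_mean=v, n_vertices=n)
            for k, v in means.items()
        },
    )


class TestMotionMagnitude:
    def test_zero_motion_gives_zero_everywhere(self, bundle):
        s0 = pm.construct_shape(bundle.model, bundle.model.zero_coefficients())
        ev = pm.motion_magnitude(s0, s0, bundle.regions)
        assert all(st.e_sum == 0.0 and st.e_mean == 0.0 for st in ev.stats.values())

    def test_three_four_five_displacement(self):
        s0 = mesh(np.zeros((3, 4)))
        v1 = np.zeros((3, 4))
        v1[:, 2] = [3.0, 4.0, 0.0]
        region = pm.RegionIndex(name="spot", indices=[2])
        ev = pm.motion_magnitude(s0, mesh(v1), [region])
        assert ev.stats["spot"].e_sum == 25.0
        assert ev.stats["spot"].e_mean == 25.0

    def test_matches_brute_force_loop(self, bundle):
        rng = np.random.default_rng(3)
        m = bundle.model.vertex_count
        s0 = mesh(rng.standard_normal((3, m)))
        s1 = mesh(rng.standard_normal((3, m)))
        ev = pm.motion_magnitude(s0, s1, bundle.regions)
        for region in bundle.regions:
            acc = 0.0
            for v in region.indices:
                d = s1.vertices[:, v] - s0.vertices[:, v]
                acc += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            assert abs(ev.stats[region.name].e_sum - acc) < 1e-12 * max(1, acc)

    def test_additive_over_disjoint_regions(self, bundle):
        rng = np.random.default_rng(4)
        m = bundle.model.vertex_count
        s0 = mesh(rng.standard_normal((3, m)))
        s1 = mesh(rng.standard_normal((3, m)))
        d1 = pm.RegionIndex(name="a", indices=np.arange(0, 40))
        d2 = pm.RegionIndex(name="b", indices=np.arange(40, 100))
        union = pm.RegionIndex(name="ab", indices=np.arange(0, 100))
        ev = pm.motion_magnitude(s0, s1, [d1, d2, union])
        lhs = ev.stats["ab"].e_sum
        rhs = ev.stats["a"].e_sum + ev.stats["b"].e_sum
        assert abs(lhs - rhs) <= 1e-12 * max(1.0, lhs)

    def test_global_translation_inflates_all_regions_equally(self, bundle):
        """Rigid motion between captures contaminates E identically in every
        region -- the documented reason meshes must be pose-normalized."""
        s0 = pm.construct_shape(bundle.model, bundle.model.zero_coefficients())
        shift = np.array([[2.0], [1.0], [-2.0]])
        s1 = mesh(s0.vertices + shift)
        ev = pm.motion_magnitude(s0, s1, bundle.regions)
        expected = float(np.sum(shift**2))
        for st in ev.stats.values():
            assert abs(st.e_mean - expected) < 1e-12

    def test_vertex_count_mismatch_raises(self):
        with pytest.raises(DimensionMismatchError):
            pm.motion_magnitude(mesh(np.zeros((3, 5))), mesh(np.zeros((3, 6))),
                                [pm.RegionIndex(name="r", indices=[0])])

    def test_out_of_range_region_raises(self):
        with pytest.raises(IndexError):
            pm.motion_magnitude(mesh(np.zeros((3, 5))), mesh(np.zeros((3, 5))),
                                [pm.RegionIndex(name="r", indices=[9])])


class TestRehabProgress:
    def test_identical_sessions_give_zero_progress(self):
        base = eval_from_means({"left": 2.0, "right": 3.0})
        follow = pm.Evaluation(session_id="t", stats=dict(base.stats))
        table = pm.rehab_progress(pm.RehabSeries([base, follow]))
        assert np.allclose(table.progress, 0.0)

    def test_signed_difference(self):
        base = eval_from_means({"left": 4.0})
        follow = pm.Evaluation(
            session_id="t",
            stats={"left": pm.RegionStats(e_sum=90.0, e_mean=9.0, n_vertices=10)},
        )
        table = pm.rehab_progress(pm.RehabSeries([base, follow]))
        assert table.iloc[0].progress == 5.0

    def test_monotone_for_growing_amplitude(self, bundle):
        """With movement amplitude growing linearly across sessions, E grows
        as amplitude^2 and progress is monotone in every region."""
        coeffs = pm.sample_face(bundle.model, 5)
        evals = []
        for i, amp in enumerate([0.5, 0.8, 1.1, 1.4, 1.7]):
            s0, s1 = pm.simulate_movement(bundle, coeffs, amp, "left", 0.6)
            evals.append(
                pm.motion_magnitude(s0, s1, bundle.regions, session_id=str(i + 1))
            )
        table = pm.rehab_progress(pm.RehabSeries(evals))
        for region, grp in table.groupby("region"):
            ordered = grp.sort_values("session").progress.to_numpy()
            assert np.all(np.diff(ordered) > 0)

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            pm.rehab_progress(pm.RehabSeries([eval_from_means({"left": 1.0})]))

    def test_region_mismatch_rejected(self):
        base = eval_from_means({"left": 1.0})
        follow = pm.Evaluation(
            session_id="t",
            stats={"right": pm.RegionStats(e_sum=1.0, e_mean=0.1, n_vertices=10)},
        )
        with pytest.raises(RegionConfigError):
            pm.rehab_progress(pm.RehabSeries([base, follow]))


class TestAsymmetry:
    def test_symmetric_motion_gives_zero(self):
        assert pm.asymmetry_index(eval_from_means({"left": 2.0, "right": 2.0})) == 0.0

    def test_fully_lateralized_is_plus_one(self):
        ev = eval_from_means({"left": 0.0, "right": 3.0})
        assert pm.asymmetry_index(ev) == 1.0

    def test_no_motion_is_undefined(self):
        with pytest.raises(UndefinedAsymmetryError):
            pm.asymmetry_index(eval_from_means({"left": 0.0, "right": 0.0}))

    @pytest.mark.parametrize("rho", [0.25, 0.5, 0.75])
    def test_attenuation_recovery(self, bundle, rho):
        """Simulated one-sided attenuation rho shows up as index
        (1 - rho^2)/(1 + rho^2) and inverts back to rho."""
        expected = (1 - rho**2) / (1 + rho**2)
        for rep in range(20):
            coeffs = pm.sample_face(bundle.model, 100 + rep)
            s0, s1 = pm.simulate_movement(bundle, coeffs, 1.0, "left", rho)
            ev = pm.motion_magnitude(s0, s1, bundle.regions)
            idx = pm.asymmetry_index(ev)
            assert abs(idx - expected) < 0.05
            assert abs(pm.attenuation_from_asymmetry(idx) - rho) < 0.05


class TestLoadRegions:
    def test_quadrants_partition_off_midline_vertices(self, bundle, tmp_path):
        config = tmp_path / "regions.yaml"
        config.write_text(
            "regions:\n"
            "  upper_left:  {rule: \"x < 0 and y > 0\"}\n"
            "  upper_right: {rule: \"x > 0 and y > 0\"}\n"
            "  lower_left:  {rule: \"x < 0 and y < 0\"}\n"
            "  lower_right: {rule: \"x > 0 and y < 0\"}\n"
        )
        regions = pm.load_regions(config, bundle.model)
        rel = bundle.model.mean_shape - bundle.model.mean_shape.mean(axis=1, keepdims=True)
        off_axis = np.flatnonzero((np.abs(rel[0]) > 1e-9) & (np.abs(rel[1]) > 1e-9))
        combined = np.concatenate([r.indices for r in regions])
        assert np.unique(combined).size == combined.size  # disjoint
        np.testing.assert_array_equal(np.sort(combined), off_axis)

    def test_explicit_index_list(self, bundle, tmp_path):
        config = tmp_path / "regions.yaml"
        config.write_text("regions:\n  tiny: {indices: [0, 1, 2]}\n")
        (region,) = pm.load_regions(config, bundle.model)
        assert len(region) == 3

    def test_left_right_sizes_equal_on_symmetric_model(self, bundle, tmp_path):
        config = tmp_path / "regions.yaml"
        config.write_text(
            "regions:\n  left: {rule: \"x < 0\"}\n  right: {rule: \"x > 0\"}\n"
        )
        left, right = pm.load_regions(config, bundle.model)
        assert len(left) == len(right)

    def test_empty_region_rejected(self, bundle, tmp_path):
        config = tmp_path / "regions.yaml"
        config.write_text("regions:\n  nowhere: {rule: \"z > 100000\"}\n")
        with pytest.raises(RegionConfigError, match="no vertices"):
            pm.load_regions(config, bundle.model)
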