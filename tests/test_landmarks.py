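import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import palsymetry as pm
from palsymetry.errors import PtsFormatError, SchemeMismatchError


def toy_scheme():
    return pm.LandmarkScheme(
        name="toy5", size=5,
        subsets={"mouth": [3, 4], "left_eye": [0], "right_eye": [1]},
    )


def random_set(scheme, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    return pm.LandmarkSet(scheme=scheme, points=scale * rng.random((scheme.size, 2)))


class TestMergeHybrid:
    def test_definition_on_toy_scheme(self):
        scheme = toy_scheme()
        primary = pm.LandmarkSet(scheme=scheme, points=np.zeros((5, 2)))
        secondary = pm.LandmarkSet(scheme=scheme, points=np.full((5, 2), 9.0))
        merged = pm.merge_hybrid(primary, secondary)
        expected = np.array([[0, 0], [0, 0], [0, 0], [9, 9], [9, 9.0]])
        np.testing.assert_array_equal(merged.points, expected)

    def test_idempotent_when_sources_agree(self, scheme):
        a = random_set(scheme, 1)
        merged = pm.merge_hybrid(a, pm.LandmarkSet(scheme=scheme, points=a.points.copy()))
        np.testing.assert_array_equal(merged.points, a.points)

    def test_exactly_mouth_subset_replaced_on_68(self, scheme):
        primary, secondary = random_set(scheme, 2), random_set(scheme, 3)
        merged = pm.merge_hybrid(primary, secondary)
        differs = np.any(merged.points != primary.points, axis=1)
        mouth = scheme.subset("mouth")
        assert differs.sum() == mouth.size  # brute-force count
        assert set(np.flatnonzero(differs)) == set(mouth.tolist())
        # non-subset points are bit-identical to primary
        keep = np.setdiff1d(np.arange(68), mouth)
        assert np.array_equal(merged.points[keep], primary.points[keep])

    def test_scheme_mismatch_raises(self, scheme):
        with pytest.raises(SchemeMismatchError):
            pm.merge_hybrid(random_set(scheme, 4), random_set(toy_scheme(), 5))

    def test_unknown_subset_raises_key_error(self, scheme):
        with pytest.raises(KeyError):
            pm.merge_hybrid(random_set(scheme, 6), random_set(scheme, 7), "chin")


class TestPtsIO:
    def test_round_trip(self, scheme, tmp_path):
        original = random_set(scheme, 8)
        path = tmp_path / "face.pts"
        pm.write_pts(original, path)
        back = pm.read_pts(path)
        np.testing.assert_allclose(back.points, original.points, atol=1e-6)

    def test_crlf_parses_identically(self, scheme, tmp_path):
        original = random_set(scheme, 9)
        lf, crlf = tmp_path / "lf.pts", tmp_path / "crlf.pts"
        pm.write_pts(original, lf)
        crlf.write_bytes(lf.read_text().replace("\n", "\r\n").encode())
        np.testing.assert_array_equal(pm.read_pts(crlf).points, pm.read_pts(lf).points)

    def test_count_mismatch_raises(self, scheme, tmp_path):
        path = tmp_path / "short.pts"
        pm.write_pts(random_set(scheme, 10), path)
        lines = path.read_text().splitlines()
        del lines[5]  # drop one coordinate line
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PtsFormatError, match="n_points"):
            pm.read_pts(path)

    def test_missing_header_raises(self, tmp_path):
        path = tmp_path / "bad.pts"
        path.write_text("{\n1.0 2.0\n}\n")
        with pytest.raises(PtsFormatError, match="n_points"):
            pm.read_pts(path)


class TestInterocular:
    def test_centroid_distance(self):
        scheme = toy_scheme()
        pts = np.array([[0.0, 0], [100, 0], [1, 1], [2, 2], [3, 3]])
        assert pm.interocular_distance(pm.LandmarkSet(scheme=scheme, points=pts)) == 100.0

    def test_rigid_rotation_invariance_and_scale_homogeneity(self, scheme):
        lm = random_set(scheme, 11)
        base = pm.interocular_distance(lm)
        theta = 0.9
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = pm.LandmarkSet(scheme=scheme, points=lm.points @ rot.T + 40.0)
        assert abs(pm.interocular_distance(rotated) - base) < 1e-9
        scaled = pm.LandmarkSet(scheme=scheme, points=2.5 * lm.points)
        assert abs(pm.interocular_distance(scaled) - 2.5 * base) < 1e-12


class TestOcularRmse:
    def test_zero_for_identical_sets(self, scheme):
        lm = random_set(scheme, 12)
        assert pm.ocular_rmse(lm, lm) == 0.0

    def test_constant_offset_closed_form(self, scheme):
        truth = random_set(scheme, 13)
        iod = pm.interocular_distance(truth)
        direction = np.array([0.6, 0.8])  # unit vector
        pred = pm.LandmarkSet(scheme=scheme, points=truth.points + 0.1 * iod * direction)
        assert abs(pm.ocular_rmse(pred, truth) - 10.0) < 1e-9

    def test_matches_naive_loop_oracle(self, scheme):
        truth, pred = random_set(scheme, 14), random_set(scheme, 15)
        iod = pm.interocular_distance(truth)
        acc = 0.0
        for i in range(68):
            du = pred.points[i, 0] - truth.points[i, 0]
            dv = pred.points[i, 1] - truth.points[i, 1]
            acc += (np.sqrt(du**2 + dv**2) / iod * 100.0) ** 2
        oracle = np.sqrt(acc / 68)
        assert abs(pm.ocular_rmse(pred, truth) - oracle) < 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(theta=st.floats(-3.1, 3.1), s=st.floats(0.2, 5.0),
           tx=st.floats(-100, 100), ty=st.floats(-100, 100))
    def test_similarity_invariance(self, theta, s, tx, ty):
        scheme = pm.ibug_68()
        truth, pred = random_set(scheme, 16), random_set(scheme, 17)
        base = pm.ocular_rmse(pred, truth)
        rot = s * np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
        shift = np.array([tx, ty])
        t2 = pm.LandmarkSet(scheme=scheme, points=truth.points @ rot.T + shift)
        p2 = pm.LandmarkSet(scheme=scheme, points=pred.points @ rot.T + shift)
        assert abs(pm.ocular_rmse(p2, t2) - base) < 1e-9

    def test_quadratic_mean_identity_with_per_landmark(self, scheme):
        truth, pred = random_set(scheme, 18), random_set(scheme, 19)
        per = pm.per_landmark_error(pred, truth)
        assert per.shape == (68,)
        assert abs(np.sqrt(np.mean(per**2)) - pm.ocular_rmse(pred, truth)) < 1e-12

    def test_per_landmark_locality(self, scheme):
        truth = random_set(scheme, 20)
        moved = truth.points.copy()
        moved[30] += 5.0
        per = pm.per_landmark_error(
            pm.LandmarkSet(scheme=scheme, points=moved), truth
        )
        assert np.count_nonzero(per) == 1 and per[30] > 0


class TestPerSubjectReport:
    def test_single_subject_total_equals_subject(self, scheme):
        pred, truth = random_set(scheme, 21), random_set(scheme, 22)
        report = pm.per_subject_report([(pred, truth)])
        assert abs(report.iloc[0].ocular_rmse - report.iloc[-1].ocular_rmse) < 1e-12

    def test_equal_subjects_pool_to_same_value(self, scheme):
        truth = random_set(scheme, 23)
        pred = pm.LandmarkSet(scheme=scheme, points=truth.points + np.array([3.0, 4.0]))
        report = pm.per_subject_report([(pred, truth), (pred, truth)])
        r = report.iloc[0].ocular_rmse
        assert abs(report.iloc[1].ocular_rmse - r) < 1e-12
        assert abs(report[report.subject == "total"].iloc[0].ocular_rmse - r) < 1e-12

    def test_total_matches_pooled_oracle(self, scheme):
        pairs = [(random_set(scheme, 30 + i), random_set(scheme, 40 + i)) for i in range(3)]
        report = pm.per_subject_report(pairs)
        pooled = np.concatenate(
            [pm.per_landmark_error(p, t) ** 2 for p, t in pairs]
        )
        oracle = float(np.sqrt(np.mean(pooled)))
        total = report[report.subject == "total"].iloc[0]
        assert abs(total.ocular_rmse - oracle) < 1e-12
        assert total.n_landmarks == 3 * 68

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pm.per_subject_report([])
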