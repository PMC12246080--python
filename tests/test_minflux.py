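"""MINFLUX localization processing: alignment, event combination, precision
statistics and filtering, DBSCAN, cross-dataset distances, sphere export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofish import (DbscanParams, align_datasets, combine_events,
                      cross_dataset_min_distances, dbscan_filter,
                      dbscan_labels, export_sphere_model, filter_by_precision,
                      precision_summary, read_sphere_model)
from mitofish.synthetic import BEAD_COLUMNS, RAW_COLUMNS

from conftest import brute_force_dbscan, brute_force_nn

XYZ = ["x_nm", "y_nm", "z_nm"]


def _raw(rows):
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def _beads(rows):
    return pd.DataFrame(rows, columns=BEAD_COLUMNS)


def _trace(ds, tid, points, t0=0.0):
    return [(ds, tid, t0 + i, *p) for i, p in enumerate(points)]


# ---------------------------------------------------------------------------
# alignment

class TestAlignDatasets:
    def test_noiseless_offset_recovered_exactly(self):
        beads = _beads([("A", 0, 0.0, 100.0, 200.0, 50.0),
                        ("B", 0, 0.0, 110.0, 200.0, 50.0)])
        raw = _raw(_trace("A", 0, [(0, 0, 0)] * 5)
                   + _trace("B", 0, [(10.0, 0, 0)] * 5))
        aligned, ab, shifts = align_datasets(raw, beads)
        assert shifts["B"] == (10.0, 0.0, 0.0)
        assert np.allclose(aligned.loc[aligned.dataset_id == "B", XYZ], 0.0)
        bb = ab[ab.dataset_id == "B"][XYZ].to_numpy()
        assert np.allclose(bb, [[100.0, 200.0, 50.0]])

    def test_identical_tracks_give_identity_transform(self):
        beads = _beads([(ds, b, t, 10.0 * b, 0.0, 0.0)
                        for ds in "AB" for b in range(3) for t in range(4)])
        raw = _raw(_trace("A", 0, [(1, 2, 3)] * 5)
                   + _trace("B", 0, [(4, 5, 6)] * 5))
        aligned, _, shifts = align_datasets(raw, beads)
        assert all(np.allclose(s, 0.0) for s in shifts.values())
        assert np.allclose(aligned[XYZ], raw[XYZ])

    def test_noisy_beads_recover_offset_within_sampling_error(self):
        rng = np.random.default_rng(0)
        true = np.array([7.0, -3.0, 2.0])
        bases = rng.uniform(0, 1000, (5, 3))  # beads shared across datasets
        rows = []
        for ds, off in (("A", np.zeros(3)), ("B", true)):
            for b in range(5):
                for t in range(10):
                    rows.append((ds, b, float(t),
                                 *(bases[b] + off + rng.normal(0, 1.0, 3))))
        beads = _beads(rows)
        raw = _raw(_trace("A", 0, [(0, 0, 0)] * 5)
                   + _trace("B", 0, [(0, 0, 0)] * 5))
        _, _, shifts = align_datasets(raw, beads)
        assert np.all(np.abs(np.asarray(shifts["B"]) - true) <= 2.0)

    def test_no_shared_bead_is_an_error(self):
        beads = _beads([("A", 0, 0.0, 0, 0, 0), ("B", 1, 0.0, 0, 0, 0)])
        raw = _raw(_trace("A", 0, [(0, 0, 0)]) + _trace("B", 0, [(0, 0, 0)]))
        with pytest.raises(ValueError, match="shared"):
            align_datasets(raw, beads)

    def test_alignment_commutes_with_global_translation(self, minflux_scene):
        """Translating a non-reference dataset's localizations and beads
        together leaves the aligned output unchanged (the reference dataset
        defines the frame)."""
        _, raw, beads, _ = minflux_scene
        a0, _, _ = align_datasets(raw, beads)
        raw2, beads2 = raw.copy(), beads.copy()
        ds = raw["dataset_id"].iloc[-1]
        t = np.array([50.0, -20.0, 10.0])
        raw2.loc[raw2.dataset_id == ds, XYZ] += t
        beads2.loc[beads2.dataset_id == ds, XYZ] += t
        a1, _, _ = align_datasets(raw2, beads2)
        assert np.allclose(a0[XYZ].to_numpy(), a1[XYZ].to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# event combination

class TestCombineEvents:
    def test_more_than_four_localizations_boundary(self):
        raw = _raw(_trace("A", 0, [(0, 0, 0), (1, 0, 0), (0, 1, 0),
                                   (1, 1, 0)])          # n=4: dropped
                   + _trace("A", 1, [(0, 0, 0)] * 5))   # n=5: kept
        out = combine_events(raw)
        assert list(out["trace_id"]) == [1]
        assert out["n_locs"].iloc[0] == 5

    def test_identical_points_give_zero_precision(self):
        raw = _raw(_trace("A", 0, [(2.0, 3.0, 4.0)] * 6))
        out = combine_events(raw)
        row = out.iloc[0]
        assert (row.x_nm, row.y_nm, row.z_nm) == (2.0, 3.0, 4.0)
        assert row.s_x == row.s_y == row.s_z == row.s_r == 0.0

    def test_precisions_match_standard_error_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal([10, 20, 30], [3, 2, 1], size=(12, 3))
        out = combine_events(_raw(_trace("A", 0, pts)))
        row = out.iloc[0]
        assert np.allclose([row.x_nm, row.y_nm, row.z_nm], pts.mean(axis=0))
        se = pts.std(axis=0, ddof=1) / np.sqrt(12)
        assert np.allclose([row.s_x, row.s_y, row.s_z], se)
        assert row.s_r == pytest.approx(np.sqrt((se[0]**2 + se[1]**2) / 2))

    def test_quadrature_convention(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 2, size=(10, 3))
        raw = _raw(_trace("A", 0, pts))
        rms = combine_events(raw, s_r_convention="rms")["s_r"].iloc[0]
        quad = combine_events(raw, s_r_convention="quadrature")["s_r"].iloc[0]
        assert quad == pytest.approx(rms * np.sqrt(2))
        with pytest.raises(ValueError):
            combine_events(raw, s_r_convention="bogus")

    def test_empty_input_gives_empty_output(self):
        out = combine_events(_raw([]))
        assert out.empty


# ---------------------------------------------------------------------------
# precision summary and filter

class TestPrecision:
    def _combined(self, s_r, s_z, ds="A"):
        n = len(s_r)
        return pd.DataFrame({
            "dataset_id": [ds] * n, "trace_id": range(n),
            "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "n_locs": 8,
            "s_x": s_r, "s_y": s_r, "s_z": s_z, "s_r": s_r,
        })

    def test_single_localization_summary(self):
        s = precision_summary(self._combined([2.5], [1.5]))
        assert s.median_s_r == 2.5 and s.median_s_z == 1.5

    def test_invariant_to_concatenation_order(self):
        a = self._combined([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], "A")
        b = self._combined([4.0, 5.0], [2.0, 2.5], "B")
        s1 = precision_summary(pd.concat([a, b], ignore_index=True))
        s2 = precision_summary(pd.concat([b, a], ignore_index=True))
        assert s1.median_s_r == s2.median_s_r
        assert s1.median_s_z == s2.median_s_z

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            precision_summary(self._combined([], []))

    def test_filter_direct_arithmetic(self):
        """9 events at 1 nm plus one at 3 nm on the worst axis: mean 1.2,
        threshold 2.4, only the 3 nm event removed."""
        s_z = [1.0] * 9 + [3.0]
        df = self._combined([0.1] * 10, s_z)
        out = filter_by_precision(df)
        assert len(out) == 9
        assert out["s_z"].max() == 1.0

    def test_all_equal_nothing_removed(self):
        df = self._combined([1.0] * 5, [0.5] * 5)
        assert len(filter_by_precision(df)) == 5

    def test_empty_passthrough_and_single_pass_semantics(self):
        assert filter_by_precision(self._combined([], [])).empty
        # single pass: threshold uses the pre-filter mean, so a second
        # application can remove more (regression for one-pass behaviour)
        s_z = [1.0] * 6 + [2.9, 10.0]
        once = filter_by_precision(self._combined([0.1] * 8, s_z))
        assert set(once["s_z"]) == {1.0, 2.9}
        twice = filter_by_precision(once)
        assert set(twice["s_z"]) == {1.0}

    def test_worst_axis_chosen_per_dataset(self):
        # dataset A: worst axis is s_r; B: worst axis is s_z
        # [1,1,1,1,3]: mean 1.4, threshold 2.8, the 3 nm event removed
        a = self._combined([1.0] * 4 + [3.0], [0.1] * 5, "A")
        b = self._combined([0.1] * 5, [1.0] * 4 + [3.0], "B")
        out = filter_by_precision(pd.concat([a, b], ignore_index=True))
        assert len(out[out.dataset_id == "A"]) == 4
        assert len(out[out.dataset_id == "B"]) == 4


# ---------------------------------------------------------------------------
# DBSCAN

class TestDbscan:
    def test_params_validated(self):
        with pytest.raises(ValueError):
            DbscanParams(epsilon=0.0)
        with pytest.raises(ValueError):
            DbscanParams(min_points=0)

    def test_ball_kept_far_point_noise(self):
        rng = np.random.default_rng(3)
        ball = rng.uniform(-25, 25, size=(8, 3))
        far = np.array([[1000.0, 1000.0, 1000.0]])
        labels = dbscan_labels(np.vstack([ball, far]), 120.0, 8)
        assert set(labels[:8]) == {0}
        assert labels[8] == -1

    def test_sparse_points_all_noise(self):
        pts = np.diag([1000.0, 2000.0, 3000.0])
        assert (dbscan_labels(pts, 120.0, 8) == -1).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        pts = rng.uniform(0, 600, size=(n, 3))
        got = dbscan_labels(pts, 120.0, 8)
        ref = brute_force_dbscan(pts, 120.0, 8)
        assert np.array_equal(got, ref)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 120))
    def test_cluster_partition_matches_sklearn(self, seed, n):
        """Core-point partition and noise set agree with scikit-learn's
        DBSCAN (border-point ties are implementation-defined)."""
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 400, size=(n, 3))
        ours = dbscan_labels(pts, 120.0, 8)
        sk = DBSCAN(eps=120.0, min_samples=8).fit(pts).labels_
        assert set(np.nonzero(ours == -1)[0]) == set(np.nonzero(sk == -1)[0])
        # identical partitions up to label renaming
        mapping = {}
        for o, s in zip(ours, sk):
            if o == -1:
                continue
            assert mapping.setdefault(o, s) == s

    def test_dbscan_filter_split(self):
        rng = np.random.default_rng(4)
        sig = rng.uniform(-30, 30, size=(20, 3))
        noise = rng.uniform(5000, 9000, size=(3, 3))
        df = pd.DataFrame(np.vstack([sig, noise]), columns=XYZ)
        df.insert(0, "dataset_id", "A")
        df.insert(1, "trace_id", range(len(df)))
        clustered, rejected = dbscan_filter(df)
        assert len(clustered) == 20 and len(rejected) == 3
        assert (clustered["cluster"] == 0).all()


# ---------------------------------------------------------------------------
# cross-dataset distances and sphere export

class TestCrossDatasetDistances:
    def _df(self, groups):
        rows = []
        for ds, pts in groups.items():
            for i, p in enumerate(pts):
                rows.append((ds, i, *p))
        return pd.DataFrame(rows, columns=["dataset_id", "trace_id", *XYZ])

    def test_one_two_two_three(self):
        df = self._df({"A": [(0, 0, 0)], "B": [(1, 2, 2)]})
        d = cross_dataset_min_distances(df)
        assert np.allclose(d[("A", "B")].distances, 3.0)

    def test_translated_dataset_constant_distance(self):
        pts = [(0, 0, 0), (500, 0, 0), (0, 500, 0)]
        t = np.array([3.0, 4.0, 0.0])
        df = self._df({"A": pts, "B": [tuple(np.array(p) + t) for p in pts]})
        d = cross_dataset_min_distances(df)
        assert np.allclose(d[("A", "B")].distances, 5.0)

    def test_matches_full_scan_for_all_pairs(self):
        rng = np.random.default_rng(5)
        groups = {ds: rng.uniform(0, 500, size=(100, 3)) for ds in "ABC"}
        d = cross_dataset_min_distances(self._df(groups))
        assert set(d) == {("A", "B"), ("A", "C"), ("B", "C")}
        for (a, b), summ in d.items():
            ref = np.concatenate([brute_force_nn(groups[a], groups[b]),
                                  brute_force_nn(groups[b], groups[a])])
            assert np.allclose(np.sort(summ.distances), np.sort(ref))

    def test_empty_dataset_pair_skipped_with_warning(self):
        df = self._df({"A": [(0, 0, 0)], "B": [(1, 2, 2)], "C": []})
        with pytest.warns(UserWarning, match="skipped"):
            d = cross_dataset_min_distances(df, datasets=["A", "B", "C"])
        assert set(d) == {("A", "B")}

    def test_single_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            cross_dataset_min_distances(self._df({"A": [(0, 0, 0)]}))


class TestSphereExport:
    def test_empty_input_gives_header_only(self, tmp_path):
        out = export_sphere_model(pd.DataFrame(columns=["dataset_id", *XYZ]),
                                  csv_path=tmp_path / "s.csv",
                                  ply_path=tmp_path / "s.ply")
        assert out.empty
        back = read_sphere_model(tmp_path / "s.csv")
        assert list(back.columns) == ["x_nm", "y_nm", "z_nm", "diameter_nm",
                                      "dataset_id"]
        ply = (tmp_path / "s.ply").read_text()
        assert "element vertex 0" in ply

    def test_round_trip_exact_and_default_diameter(self, tmp_path):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(0, 100, (17, 3)), columns=XYZ)
        df.insert(0, "dataset_id", "A")
        out = export_sphere_model(df, csv_path=tmp_path / "s.csv",
                                  ply_path=tmp_path / "s.ply")
        assert len(out) == 17
        assert (out["diameter_nm"] == 10.0).all()
        back = read_sphere_model(tmp_path / "s.csv")
        assert np.array_equal(back[XYZ].to_numpy(), df[XYZ].to_numpy())
        # PLY has one vertex line per record with radius 5
        lines = (tmp_path / "s.ply").read_text().splitlines()
        body = lines[lines.index("end_header") + 1:]
        assert len(body) == 17
        assert all(line.split()[-1] == "5.0" for line in body)
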