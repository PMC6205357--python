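"""Cohort I/O, analysis masking, dTLVC normalization and region summaries."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from lesionkit.cohort import (
    LesionMask,
    Template,
    VolumeGeometry,
    build_analysis_mask,
    dtlvc_normalize,
    lesion_frequency_map,
    load_cohort,
    region_overlap_summary,
)

from conftest import make_toy_cohort


def _write_mask(path, data, affine):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.uint8), affine), str(path))


class TestLoadCohort:
    def _setup(self, tmp_path, datas, affine=None, n_rows=None):
        affine = np.diag([2.0, 2.0, 2.0, 1.0]) if affine is None else affine
        paths = []
        for i, d in enumerate(datas):
            p = tmp_path / f"sub{i}.nii.gz"
            _write_mask(p, d, affine if np.ndim(affine) == 2 else affine[i])
            paths.append(p)
        n = len(datas) if n_rows is None else n_rows
        beh = pd.DataFrame({"participant_id": [f"s{i}" for i in range(n)],
                            "score": np.arange(n, dtype=float)})
        beh_path = tmp_path / "behavior.csv"
        beh.to_csv(beh_path, index=False)
        return paths, beh_path

    def test_lesion_size_in_cc(self, tmp_path):
        # 1000 lesioned voxels at 2x2x2 mm = 8000 mm^3 = 8 cc
        data = np.zeros((12, 12, 12))
        data.ravel()[:1000] = 1
        paths, beh = self._setup(tmp_path, [data])
        cohort = load_cohort(paths, beh)
        assert cohort.sizes_cc[0] == pytest.approx(8.0)
        assert cohort.participant_ids == ["s0"]

    def test_empty_mask_rejected(self, tmp_path):
        paths, beh = self._setup(tmp_path, [np.zeros((4, 4, 4))])
        with pytest.raises(ValueError, match="no lesioned voxels"):
            load_cohort(paths, beh)

    def test_non_binary_rejected(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = 2
        paths, beh = self._setup(tmp_path, [data])
        with pytest.raises(ValueError, match="not binary"):
            load_cohort(paths, beh)

    def test_geometry_mismatch_names_offending_file(self, tmp_path):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((5, 5, 5)); b[0, 0, 0] = 1
        paths, beh = self._setup(tmp_path, [a, b])
        with pytest.raises(ValueError, match="sub1"):
            load_cohort(paths, beh)

    def test_row_count_mismatch(self, tmp_path):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        paths, beh = self._setup(tmp_path, [a], n_rows=3)
        with pytest.raises(ValueError, match="behavior"):
            load_cohort(paths, beh)


class TestAnalysisMask:
    def _counted_cohort(self, n=128, n_a=12, n_b=13):
        """Voxel A lesioned by n_a participants, voxel B by n_b, voxel C by all."""
        masks = []
        for i in range(n):
            m = np.zeros((3, 3, 3), dtype=bool)
            m[0, 0, 0] = True  # voxel C, everyone
            if i < n_a:
                m[1, 1, 1] = True  # voxel A
            if i < n_b:
                m[2, 2, 2] = True  # voxel B
            masks.append(m)
        return make_toy_cohort(masks)

    def test_ten_percent_boundary(self):
        cohort = self._counted_cohort()
        mask = build_analysis_mask(cohort, 0.10)
        vol = mask.to_volume()
        assert not vol[1, 1, 1]  # 12/128 = 9.4% < 10%
        assert vol[2, 2, 2]  # 13/128 = 10.2% >= 10%
        assert vol[0, 0, 0]

    def test_empty_mask_errors(self):
        a = np.zeros((3, 3, 3), dtype=bool); a[0, 0, 0] = True
        b = np.zeros((3, 3, 3), dtype=bool); b[1, 1, 1] = True
        cohort = make_toy_cohort([a, b])
        with pytest.raises(ValueError, match="frequency threshold"):
            build_analysis_mask(cohort, min_frequency=1.0)

    def test_monotone_in_threshold(self, small_cohort):
        cohort, _ = small_cohort
        prev = None
        for f in (0.05, 0.10, 0.25, 0.5):
            mask = build_analysis_mask(cohort, f)
            if prev is not None:
                assert np.isin(mask.voxel_index, prev).all()
            prev = mask.voxel_index


class TestDtlvc:
    def test_entries_are_inverse_sqrt_volume(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        a.ravel()[:100] = True  # V = 100 -> entries 0.1
        b = np.zeros((5, 5, 5), dtype=bool)
        b.ravel()[25:50] = True  # overlaps a in mask region
        cohort = make_toy_cohort([a, b])
        mask = build_analysis_mask(cohort, 0.5)
        X = dtlvc_normalize(cohort, mask)
        nz = X.values[0][X.values[0] != 0]
        assert np.allclose(nz, 0.1)
        # intact voxels are exactly zero, lesioned exactly 1/sqrt(V)
        assert set(np.unique(X.values[0])) <= {0.0, 0.1}

    def test_smaller_lesions_weighted_more(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        a.ravel()[:100] = True
        b = np.zeros((10, 10, 10), dtype=bool)
        b.ravel()[:400] = True
        cohort = make_toy_cohort([a, b])
        mask = build_analysis_mask(cohort, 0.5)
        X = dtlvc_normalize(cohort, mask)
        assert np.allclose(X.values[0][X.values[0] != 0], 0.1)
        assert np.allclose(X.values[1][X.values[1] != 0], 0.05)

    def test_volume_counts_whole_lesion_not_mask(self):
        # participant 0 has 9 voxels outside the shared region: V = 10
        a = np.zeros((4, 4, 4), dtype=bool)
        a.ravel()[:10] = True
        b = np.zeros((4, 4, 4), dtype=bool)
        b.ravel()[0] = True
        cohort = make_toy_cohort([a, b])
        mask = build_analysis_mask(cohort, min_frequency=1.0)  # only voxel 0
        X = dtlvc_normalize(cohort, mask)
        assert X.values.shape == (2, 1)
        assert X.values[0, 0] == pytest.approx(1 / np.sqrt(10), abs=1e-15)
        assert X.values[1, 0] == pytest.approx(1.0)

    def test_round_trip_identity(self, small_cohort):
        cohort, _ = small_cohort
        mask = build_analysis_mask(cohort, 0.10)
        X = dtlvc_normalize(cohort, mask)
        V = cohort.sizes_voxels()
        for i in range(len(cohort)):
            nz = X.values[i][X.values[i] != 0]
            assert np.all(np.abs(nz**2 * V[i] - 1.0) < 1e-12)


class TestFrequencyMap:
    def test_equals_mean_of_masks(self, small_cohort):
        cohort, _ = small_cohort
        fm = lesion_frequency_map(cohort)
        oracle = np.mean([m.data for m in cohort.masks], axis=0)
        assert np.array_equal(fm, oracle)
        assert fm.min() >= 0 and fm.max() <= 1

    def test_single_participant_identity(self):
        a = np.zeros((3, 3, 3), dtype=bool); a[1, 1, 1] = True
        cohort = make_toy_cohort([a])
        assert np.array_equal(lesion_frequency_map(cohort), a.astype(float))

    def test_disjoint_pair_gives_halves(self):
        a = np.zeros((3, 3, 3), dtype=bool); a[0, 0, 0] = True
        b = np.zeros((3, 3, 3), dtype=bool); b[2, 2, 2] = True
        fm = lesion_frequency_map(make_toy_cohort([a, b]))
        assert set(np.unique(fm)) == {0.0, 0.5}


class TestRegionOverlap:
    def _template(self, geometry, voxels):
        return Template(geometry=geometry, voxels=np.asarray(voxels))

    def test_percent_of_region(self):
        geo = VolumeGeometry(shape=(4, 4, 4), affine=np.eye(4))
        parc = np.zeros((4, 4, 4), dtype=int)
        parc.ravel()[:8] = 1  # region 1: 8 voxels
        parc.ravel()[8:12] = 2  # region 2: 4 voxels
        parc.ravel()[20:24] = 3  # region 3: untouched
        tpl = self._template(geo, list(range(4)) + list(range(8, 12)))
        out = region_overlap_summary(tpl, parc)
        assert out.set_index("region_id")["percent"].to_dict() == {1: 50.0, 2: 100.0}
        # region 3 has zero overlap and is omitted
        assert 3 not in out["region_id"].values

    def test_template_denominator(self):
        geo = VolumeGeometry(shape=(4, 4, 4), affine=np.eye(4))
        parc = np.zeros((4, 4, 4), dtype=int)
        parc.ravel()[:8] = 1
        tpl = self._template(geo, range(4))  # 4 voxels, all in region 1
        out = region_overlap_summary(tpl, parc, denominator="template")
        assert out["percent"].iloc[0] == pytest.approx(100.0)

    def test_label_order_irrelevant(self):
        geo = VolumeGeometry(shape=(4, 4, 4), affine=np.eye(4))
        rng = np.random.default_rng(0)
        parc = rng.integers(0, 4, size=(4, 4, 4))
        tpl = self._template(geo, rng.choice(64, size=20, replace=False))
        out1 = region_overlap_summary(tpl, parc)
        relabel = np.select([parc == 1, parc == 2, parc == 3], [3, 1, 2], 0)
        out2 = region_overlap_summary(tpl, relabel)
        m1 = out1.set_index("region_id")["percent"]
        m2 = out2.set_index("region_id")["percent"]
        assert m1[1] == m2[3] and m1[2] == m2[1] and m1[3] == m2[2]
        assert ((out1["percent"] > 0) & (out1["percent"] <= 100)).all()

    def test_all_zero_parcellation_fatal(self):
        geo = VolumeGeometry(shape=(3, 3, 3), affine=np.eye(4))
        tpl = self._template(geo, [0])
        with pytest.raises(ValueError, match="no labelled regions"):
            region_overlap_summary(tpl, np.zeros((3, 3, 3), dtype=int))


class TestGeneratedInvariants:
    """Property tests over randomly generated miniature cohorts."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dtlvc_and_mask_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        shape = (5, 5, 5)
        masks = []
        for _ in range(n):
            m = np.zeros(125, dtype=bool)
            k = int(rng.integers(1, 60))
            m[rng.choice(125, size=k, replace=False)] = True
            masks.append(m.reshape(shape))
        cohort = make_toy_cohort(masks)
        # frequency map equals the voxelwise mean of the masks
        fm = lesion_frequency_map(cohort)
        assert np.array_equal(fm, np.mean(masks, axis=0))
        # analysis mask shrinks monotonically with the threshold
        prev = None
        for f in (0.1, 0.4, 0.8):
            try:
                am = build_analysis_mask(cohort, f)
            except ValueError:
                prev = np.array([], dtype=np.int64)
                continue
            if prev is not None:
                assert np.isin(am.voxel_index, prev).all() or prev is None
            prev = am.voxel_index
        # dtlvc round trip: (nonzero entry)^2 * V = 1 exactly
        am = build_analysis_mask(cohort, 1.0 / n)
        X = dtlvc_normalize(cohort, am)
        V = cohort.sizes_voxels()
        for i in range(n):
            nz = X.values[i][X.values[i] != 0]
            assert np.all(np.abs(nz**2 * V[i] - 1.0) < 1e-12)
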