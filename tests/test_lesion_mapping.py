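import numpy as np
import pytest

from strokekit.imageio import DwiVolume, SegMap
from strokekit.lesion_mapping import (AffineTransform, AtlasDefinition,
                                      compose, lesion_indices, load_transform,
                                      register_affine, render_report,
                                      save_transform, transform_atlas,
                                      transform_mask)
from strokekit.phantom import (LesionSpec, PhantomConfig, generate_case,
                               make_standard_space_pair)


class TestAffineTransform:
    def test_identity_and_inverse(self):
        t = AffineTransform.identity()
        np.testing.assert_array_equal(t.matrix, np.eye(4))
        m = np.eye(4)
        m[:3, 3] = (3, -2, 1)
        t = AffineTransform(m)
        np.testing.assert_allclose(t.inverse().matrix @ m, np.eye(4),
                                   atol=1e-12)

    def test_compose_order(self):
        a = np.eye(4); a[0, 3] = 1.0
        b = np.diag([2.0, 1, 1, 1])
        t = compose(AffineTransform(a), AffineTransform(b))
        # apply a first, then b: x -> 2*(x+1)
        np.testing.assert_allclose(t.matrix @ [1, 0, 0, 1], [4, 0, 0, 1])

    def test_singular_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((4, 4)))

    def test_save_load_round_trip(self, tmp_path):
        m = np.eye(4)
        m[:3, 3] = (5.0, -3.0, 7.0)
        path = tmp_path / "t.mat"
        save_transform(AffineTransform(m), path)
        back = load_transform(path)
        np.testing.assert_allclose(back.matrix, m)


@pytest.fixture(scope="module")
def native_case():
    cfg = PhantomConfig(seed=4)
    from strokekit.phantom import generate_atlas_phantom

    atlas = generate_atlas_phantom(cfg, 6)
    case = generate_case(cfg, atlas, LesionSpec(diameter_mm=14))
    return cfg, atlas, case


class TestRegistration:
    def test_recovers_known_transform(self, native_case):
        _, _, case = native_case
        std, truth = make_standard_space_pair(
            case.volume, translation_mm=(5.0, -3.0, 7.0), rotation_deg=10.0)
        est = register_affine(case.volume, std)
        # compare action on points within the brain, in mm
        pts = np.array([[0, 0, 0, 1], [20, 10, 4, 1], [-15, 18, -6, 1.0]]).T
        err = np.abs((est.matrix @ pts) - (truth.matrix @ pts))[:3]
        assert err.max() < 1.0

    def test_external_matrix_hook(self, native_case, tmp_path):
        _, _, case = native_case
        std, truth = make_standard_space_pair(case.volume)
        path = tmp_path / "ext.mat"
        save_transform(truth, path)
        est = register_affine(case.volume, std, method="external",
                              matrix_file=path)
        np.testing.assert_allclose(est.matrix, truth.matrix)

    def test_mask_round_trip_dice(self, native_case):
        from strokekit.metrics import dice
        _, _, case = native_case
        std, truth = make_standard_space_pair(
            case.volume, translation_mm=(4.0, -2.0, 7.0), rotation_deg=5.0)
        fwd = transform_mask(case.truth_mask, truth, std)
        back = transform_mask(fwd, truth.inverse(), case.volume)
        assert dice(back, case.truth_mask) > 0.7  # thick slices limit this


class TestLesionIndices:
    def test_conservation(self, native_case):
        _, atlas, case = native_case
        report = lesion_indices(case.truth_mask, atlas)
        counts = [r.voxels_in_region for r in report.rows]
        assert sum(counts) + report.voxels_outside == \
            report.total_lesion_voxels
        pct = sum(r.pct_of_lesion for r in report.rows)
        if report.voxels_outside == 0:
            assert pct == pytest.approx(100.0, abs=0.01)

    def test_empty_lesion_raises(self, native_case):
        cfg, atlas, case = native_case
        empty = SegMap(np.zeros_like(case.truth_mask.data),
                       case.truth_mask.spacing_mm, case.truth_mask.affine)
        with pytest.raises(ValueError, match="no lesion"):
            lesion_indices(empty, atlas)

    def test_grid_mismatch_raises(self, native_case):
        _, atlas, case = native_case
        small = SegMap(np.ones((4, 4, 2), dtype=np.uint8), (1, 1, 7),
                       np.eye(4))
        with pytest.raises(ValueError, match="mismatch"):
            lesion_indices(small, atlas)

    def test_render_formats(self, native_case):
        import json
        _, atlas, case = native_case
        rep = lesion_indices(case.truth_mask, atlas)
        text = render_report([rep], format="text")
        assert "total lesion voxels" in text
        data = json.loads(render_report([rep], format="json"))
        assert data[0]["total_lesion_voxels"] == rep.total_lesion_voxels
        with pytest.raises(ValueError):
            render_report([rep], format="xml")


class TestTransformAtlas:
    def test_identity_preserves_labels(self, native_case):
        _, atlas, case = native_case
        out = transform_atlas(atlas, AffineTransform.identity(), case.volume)
        np.testing.assert_array_equal(out.labels, atlas.labels)

    def test_far_translation_errors(self, native_case):
        _, atlas, case = native_case
        m = np.eye(4)
        m[:3, 3] = (10000, 0, 0)
        with pytest.raises(ValueError, match="intersect"):
            transform_atlas(atlas, AffineTransform(m), case.volume)
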