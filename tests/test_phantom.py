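import numpy as np
import pytest
from scipy import ndimage

from strokekit.phantom import (BRAIN_MEAN, LesionSpec, PhantomConfig,
                               derive_labels, feret_diameter_mm,
                               generate_atlas_phantom, generate_case,
                               make_standard_space_pair, simulate_cohort,
                               write_cases)


@pytest.fixture(scope="module")
def config():
    return PhantomConfig(seed=0)


@pytest.fixture(scope="module")
def atlas(config):
    return generate_atlas_phantom(config, 6)


class TestAtlasPhantom:
    def test_regions_partition_brain(self, atlas):
        brain = atlas.brain_mask()
        labeled = atlas.labels > 0
        np.testing.assert_array_equal(brain, labeled)
        assert set(np.unique(atlas.labels)) == set(range(7))

    def test_territory_split(self, atlas):
        ant = atlas.territory_mask("anterior")
        post = atlas.territory_mask("posterior")
        assert not np.any(ant & post)
        np.testing.assert_array_equal(ant | post, atlas.brain_mask())

    def test_too_fine_raises(self, config):
        with pytest.raises(ValueError, match="too fine"):
            generate_atlas_phantom(config, 100000)

    def test_deterministic(self, config):
        a1 = generate_atlas_phantom(config, 4)
        a2 = generate_atlas_phantom(config, 4)
        np.testing.assert_array_equal(a1.labels, a2.labels)


class TestGenerateCase:
    def test_contrast_contract(self, config, atlas):
        spec = LesionSpec(diameter_mm=12, intensity_contrast=5.0)
        case = generate_case(config, atlas, spec)
        inside = case.volume.data[case.truth_mask.data == 1]
        brain = (atlas.brain_mask()) & (case.truth_mask.data == 0)
        outside = case.volume.data[brain]
        sd = config.background_noise_sd
        assert (inside.mean() - outside.mean()) / sd >= 4.0

    def test_diameter_contract(self, config, atlas):
        for d in (8.0, 14.0, 24.0):
            case = generate_case(config, atlas, LesionSpec(diameter_mm=d))
            feret = feret_diameter_mm(case.truth_mask.data,
                                      case.truth_mask.spacing_mm)
            assert feret == pytest.approx(d, abs=1.0 + 1e-9)

    def test_territory_containment(self, config, atlas):
        for terr in ("anterior", "posterior"):
            case = generate_case(
                config, atlas, LesionSpec(diameter_mm=10, territory=terr))
            tmask = atlas.territory_mask(terr)
            assert np.all(tmask[case.truth_mask.data == 1])

    def test_component_count(self, config, atlas):
        case = generate_case(
            config, atlas, LesionSpec(diameter_mm=9, n_components=3))
        _, n = ndimage.label(case.truth_mask.data, np.ones((3, 3, 3)))
        assert n == 3

    def test_deterministic(self, config, atlas):
        spec = LesionSpec(diameter_mm=10)
        c1 = generate_case(config, atlas, spec)
        c2 = generate_case(config, atlas, spec)
        np.testing.assert_array_equal(c1.volume.data, c2.volume.data)
        np.testing.assert_array_equal(c1.truth_mask.data, c2.truth_mask.data)

    def test_oversized_lesion_raises(self, config, atlas):
        with pytest.raises(ValueError, match="diameter"):
            generate_case(config, atlas, LesionSpec(diameter_mm=200))

    def test_labels_derived(self, config, atlas):
        small = generate_case(config, atlas, LesionSpec(diameter_mm=8))
        assert small.size_label == "lacune"
        big = generate_case(config, atlas, LesionSpec(diameter_mm=24))
        assert big.size_label == "non_lacune"
        scattered = generate_case(
            config, atlas, LesionSpec(diameter_mm=8, n_components=2))
        assert scattered.size_label == "non_lacune"


class TestDeriveLabels:
    def test_scattered_never_lacune(self, config, atlas):
        mask = np.zeros(config.grid_shape, dtype=np.uint8)
        # two separate 2-voxel blobs inside the anterior territory
        ant = np.argwhere(atlas.territory_mask("anterior"))
        a, b = ant[10], ant[-10]
        mask[tuple(a)] = 1
        mask[tuple(b)] = 1
        from strokekit.imageio import SegMap
        seg = SegMap(mask, config.spacing_mm, config.grid_affine())
        size, _ = derive_labels(seg, config.spacing_mm, atlas)
        assert size == "non_lacune"

    def test_empty_mask_raises(self, config, atlas):
        from strokekit.imageio import SegMap
        seg = SegMap(np.zeros(config.grid_shape, dtype=np.uint8),
                     config.spacing_mm, config.grid_affine())
        with pytest.raises(ValueError, match="lesion"):
            derive_labels(seg, config.spacing_mm, atlas)


class TestCohort:
    def test_balanced_and_deterministic(self, config, atlas):
        cases = simulate_cohort(16, config, atlas, seed=9)
        sizes = [c.size_label for c in cases]
        assert sizes.count("lacune") == 8
        again = simulate_cohort(16, config, atlas, seed=9)
        np.testing.assert_array_equal(cases[3].volume.data,
                                      again[3].volume.data)

    def test_both_fraction(self, config, atlas):
        cases = simulate_cohort(16, config, atlas, seed=9, both_fraction=0.25)
        n_both = sum(c.territory_label == "both" for c in cases)
        assert n_both == 4

    def test_write_cases(self, config, atlas, tmp_path):
        cases = simulate_cohort(4, config, atlas, seed=2)
        manifest = write_cases(cases, tmp_path)
        assert len(manifest) == 4
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "case000_dwi.nii.gz").exists()
        assert (tmp_path / "case000_mask.nii.gz").exists()


class TestStandardSpacePair:
    def test_known_transform_round_trip(self, config, atlas):
        case = generate_case(config, atlas, LesionSpec(diameter_mm=14))
        # no z translation: with 7 mm slices any z shift clips a whole
        # slice of brain at the grid edge and moves the center of mass
        std, t = make_standard_space_pair(case.volume,
                                          translation_mm=(4.0, -2.0, 0.0),
                                          rotation_deg=8.0)
        assert std.data.shape == case.volume.data.shape
        # the true transform must map the native center of mass onto the
        # standard-space center of mass (world coordinates)
        from scipy import ndimage as ndi

        def com_world(vol):
            com = ndi.center_of_mass(np.clip(vol.data - BRAIN_MEAN / 2, 0, None))
            return (vol.affine @ np.array([*com, 1.0]))[:3]

        mapped = (t.matrix @ np.array([*com_world(case.volume), 1.0]))[:3]
        np.testing.assert_allclose(mapped, com_world(std), atol=1.5)
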