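import numpy as np
import pytest

from epidermtex.synthetic import (
    PlasticityShift,
    SpeciesModel,
    generate_dataset,
    generate_image,
    generate_plasticity_pair,
    well_separated_models,
)


class TestModels:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SpeciesModel(stomata_density=-1)
        with pytest.raises(ValueError):
            SpeciesModel(stomata_length_mean=5, stomata_width_mean=9)
        with pytest.raises(ValueError):
            PlasticityShift(density_factor=0)

    def test_shift_scales_trait_parameters_only(self):
        m = SpeciesModel(stomata_density=40, stomata_length_mean=20, stomata_width_mean=10)
        s = PlasticityShift(0.5, 1.5, 1.3).apply(m)
        assert s.stomata_density == 20
        assert s.stomata_length_mean == 30
        assert s.stomata_width_mean == 13
        assert s.mosaic_cell_scale == m.mosaic_cell_scale
        assert s.spectral_exponent == m.spectral_exponent

    def test_identity_shift_is_noop(self):
        m = well_separated_models(2)[1]
        assert PlasticityShift().apply(m) == m


class TestGenerateImage:
    def test_deterministic_given_seed(self):
        m = well_separated_models(3)[0]
        img1, tr1 = generate_image(m, (64, 64), seed=11)
        img2, tr2 = generate_image(m, (64, 64), seed=11)
        assert np.array_equal(img1, img2)
        assert tr1 == tr2
        img3, _ = generate_image(m, (64, 64), seed=12)
        assert not np.array_equal(img1, img3)

    def test_valid_gray_output(self):
        img, _ = generate_image(well_separated_models(1)[0], (64, 96), seed=0)
        assert img.shape == (64, 96)
        assert img.dtype == np.int64
        assert img.min() >= 0 and img.max() <= 255

    def test_zero_density_yields_zero_traits(self):
        m = SpeciesModel(stomata_density=0.0)
        _, tr = generate_image(m, (64, 64), seed=3)
        assert tr == {"density": 0.0, "guard_cell_length": 0.0, "complex_width": 0.0}

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            generate_image(SpeciesModel(), (32, 64), seed=0)

    def test_realized_counts_follow_poisson_mean(self):
        # 200 seeded draws at density 50: mean within 3*sqrt(50/200) of 50
        m = SpeciesModel(stomata_density=50.0)
        counts = [generate_image(m, (64, 64), seed=s)[1]["density"] for s in range(200)]
        assert abs(np.mean(counts) - 50.0) < 3 * np.sqrt(50.0 / 200)


class TestDatasets:
    def test_dataset_shapes_and_labels(self):
        models = well_separated_models(3)
        images, labels, traits = generate_dataset(models, 4, size=(64, 64), seed=5)
        assert len(images) == 12
        assert sorted(labels["species"].unique()) == [m.name for m in models]
        assert (labels["species"].value_counts() == 4).all()
        assert set(traits.columns) == {"sample_id", "density", "guard_cell_length", "complex_width"}
        assert list(traits["sample_id"]) == list(labels["sample_id"])
        # determinism of the whole dataset
        images_b, labels_b, _ = generate_dataset(models, 4, size=(64, 64), seed=5)
        assert all(np.array_equal(a, b) for a, b in zip(images, images_b))
        assert labels.equals(labels_b)

    def test_plasticity_pair_trait_means_shift_by_factors(self):
        m = SpeciesModel(stomata_density=60, stomata_length_mean=20,
                         stomata_length_std=1.0, stomata_width_mean=12,
                         stomata_width_std=0.8)
        shift = PlasticityShift(0.5, 1.5, 1.3)
        (i1, l1, t1), (i2, l2, t2) = generate_plasticity_pair(
            m, shift, 30, 30, size=(64, 64), seed=8
        )
        assert set(l1["environment"]) == {"gallery_forest"}
        assert set(l2["environment"]) == {"marsh_camp"}
        assert set(l2["species"]) == set(l1["species"])
        # density is Poisson(60) vs Poisson(30): compare within 4 standard errors
        assert abs(t2["density"].mean() - 30) < 4 * np.sqrt(30 / 30)
        assert t1["guard_cell_length"].mean() * 1.5 == pytest.approx(
            t2["guard_cell_length"].mean(), rel=0.05
        )
        assert t1["complex_width"].mean() * 1.3 == pytest.approx(
            t2["complex_width"].mean(), rel=0.05
        )
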