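import numpy as np
import pytest

import epidermtex as et
from epidermtex.imaging import enhance_contrast
from epidermtex.pipeline import make_feature_table, traits_only_table


def random_gray(rng, shape):
    return rng.integers(0, 256, size=shape, dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20160524)


@pytest.fixture(scope="session")
def species_panel():
    return et.well_separated_models(8)


@pytest.fixture(scope="session")
def synthetic_study(species_panel):
    """8 species x 12 images at 256x256 plus a 9-image shifted-environment
    hold-out of species 0 — the study layout shared by the pipeline and
    plasticity tests (generated once per session)."""
    images, labels, traits = et.generate_dataset(
        species_panel, 12, size=(256, 256), seed=123
    )
    shift = et.PlasticityShift(density_factor=0.5, length_factor=1.5, width_factor=1.3)
    _, (im2, lab2, tr2) = et.generate_plasticity_pair(
        species_panel[0], shift, 0, 9, size=(256, 256), seed=321
    )
    return {
        "images": images, "labels": labels, "traits": traits,
        "shift_images": im2, "shift_labels": lab2, "shift_traits": tr2,
    }


@pytest.fixture(scope="session")
def fourier_tables(synthetic_study):
    """Fourier-circular feature tables (enhanced images) for the study."""
    s = synthetic_study
    desc = et.FourierDescriptor(mode="circular")
    F1 = desc.transform([enhance_contrast(i) for i in s["images"]])
    F2 = desc.transform([enhance_contrast(i) for i in s["shift_images"]])
    lab, lab2 = s["labels"], s["shift_labels"]
    train = make_feature_table(F1, lab.species.tolist(), lab.sample_id.tolist(),
                               lab.environment.tolist())
    test = make_feature_table(F2, lab2.species.tolist(), lab2.sample_id.tolist(),
                              lab2.environment.tolist())
    return train, test


@pytest.fixture(scope="session")
def trait_tables(synthetic_study):
    s = synthetic_study
    return (traits_only_table(s["labels"], s["traits"]),
            traits_only_table(s["shift_labels"], s["shift_traits"]))
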