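import numpy as np
import pytest

from atlas_msi.core_model_io.model import MSIDataset, StudyDesign
from atlas_msi.synthetic_data import generate_atlas


@pytest.fixture(scope="session")
def atlas3():
    sections, truth = generate_atlas(3, (56, 80), seed=11)
    return sections, truth


@pytest.fixture()
def small_dataset():
    mz = np.arange(100.0, 110.0, 0.05)
    rng = np.random.default_rng(0)
    coords = np.array([[x, y] for y in range(3) for x in range(4)])
    inten = rng.poisson(50, size=(len(coords), len(mz))).astype(float)
    return MSIDataset(coords=coords, mz_axis=mz, intensities=inten,
                      meta={"molecular_class": "metabolite", "polarity": "-",
                            "animal_id": "m01", "section_id": "m01_metabolite",
                            "mass_range": (100.0, 110.0)}).validate()


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign.default()


@pytest.fixture(scope="session")
def mini_study(tmp_path_factory):
    """A small but complete study (2 groups x 3 animals, planted effects)."""
    from atlas_msi.synthetic_data import generate_study

    out = tmp_path_factory.mktemp("mini_study")
    design = StudyDesign.default({("WT", "CSD"): 3, ("R192Q", "CSD"): 3})
    manifest = generate_study(design, seed=17, out_dir=out, n_atlas_sections=2)
    return out, manifest
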