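import numpy as np
import pytest

from woodid.dataset import SpecimenRecord
from woodid.evaluation import ImagePrediction
from woodid.patches import PatchConfig
from woodid.synthetic import TextureClassSpec, example_class_specs, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def diffuse_spec():
    return TextureClassSpec(class_label="Demo", porosity="diffuse")


@pytest.fixture(scope="session")
def small_patch_cfg():
    return PatchConfig.desk_scale(256, 256)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """3 well-separated classes × 3 specimens × 2 images at 256×256."""
    out = tmp_path_factory.mktemp("tinyset")
    manifest = generate_dataset(
        example_class_specs(3), specimens_per_class=3, images_per_specimen=2,
        out_dir=out, seed=42, size_px=(256, 256),
    )
    return manifest


def make_records(spec_labels):
    """Quick specimen records with one dummy image path each."""
    return [
        SpecimenRecord(
            specimen_id=f"s{i:03d}",
            xylarium="SYNw",
            taxon=f"Synthetica {lab.lower()}",
            class_label=lab,
            image_paths=(f"s{i:03d}_0.png",),
        )
        for i, lab in enumerate(spec_labels)
    ]


def make_prediction(specimen_id, scores, labels):
    scores = np.asarray(scores, dtype=float)
    return ImagePrediction(
        image_path=f"{specimen_id}.png",
        specimen_id=specimen_id,
        scores=scores / scores.sum(),
        class_labels=tuple(labels),
    )
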