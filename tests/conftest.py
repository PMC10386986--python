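import numpy as np
import pytest

from pathomics import synthetic
from pathomics.tissues import TissueClass, CLASS_ORDER


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with a strong immune-cell effect, small tiles."""
    spec = synthetic.SyntheticCohortSpec(
        n_patients=60,
        true_beta={TissueClass.IC: 1.5},
        tiles_per_patient_per_class=2,
        tile_size_px=32,
        seed=42,
    )
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def labelled_tiles():
    """Six-class labelled tile set (40/class, 48 px) for classifier tests."""
    tiles = []
    for c in CLASS_ORDER:
        for i in range(40):
            tiles.append(
                synthetic.generate_tissue_tile(
                    c, 48, seed=i, patient_id=f"pt{i % 10}"
                )
            )
    return tiles


@pytest.fixture(scope="session")
def trained_small_classifier(labelled_tiles):
    from pathomics import classifier

    cfg = classifier.ClassifierConfig(epochs=6, seed=0)
    return classifier.train_classifier(labelled_tiles, cfg)


@pytest.fixture(scope="session")
def mif_field():
    spec = synthetic.SyntheticMIFSpec(group="none_recurrence", seed=7)
    return synthetic.generate_mif_field(spec)
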