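import numpy as np
import pytest

from pathimage.data_io import assign_survival_labels, harmonize
from pathimage.synthetic import PlantedEffect, SyntheticConfig, generate_multiomics


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-sample, 10-pathway, 3-omics cohort with one planted pathway."""
    cfg = SyntheticConfig(
        n_samples_per_class=(20, 30),
        n_pathways=10,
        genes_per_pathway=(5, 8),
        planted=[PlantedEffect(2, 1, 2.0)],
        survival_betas={0: 0.7},
        censoring_rate=0.1,
        seed=42,
    )
    matrices, pathways, clinical, truth = generate_multiomics(cfg)
    labels = assign_survival_labels(clinical, cfg.threshold_years)
    dataset = harmonize(matrices, labels)
    return dict(config=cfg, matrices=matrices, pathways=pathways,
                clinical=clinical, truth=truth, labels=labels, dataset=dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
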