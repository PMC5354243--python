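import numpy as np
import pytest

from focm_screen.data_io import Dataset, Sample
from focm_screen.panel import MetabolitePanel
from focm_screen.synthetic import SyntheticConfig, generate_cohorts

TOY_VARS = ("Methionine", "SAM", "SAH", "8-OHG", "GSSG", "Tyrosine", "fCystine", "Adenosine")


def make_dataset(X, labels, variables, vineland=None, ids=None):
    """Assemble a Dataset from an array and label list (test helper)."""
    X = np.asarray(X, dtype=float)
    panel = MetabolitePanel.reduced(variables)
    samples = []
    for i in range(X.shape[0]):
        samples.append(
            Sample(
                id=ids[i] if ids else f"s{i:03d}",
                cohort=labels[i],
                values=X[i],
                vineland=None if vineland is None else vineland[i],
            )
        )
    return Dataset(panel=panel, samples=samples, provenance={"source": "synthetic"})


@pytest.fixture
def toy_1d():
    """Two cleanly separated 1-D classes: A={0,1}, B={10,11}."""
    return make_dataset(
        [[0.0], [1.0], [10.0], [11.0]],
        ["ASD", "ASD", "NEU", "NEU"],
        ("Methionine",),
    )


@pytest.fixture
def planted_two_cohorts():
    """80+80 samples, three planted variables at delta=1.5 (seed fixed)."""
    cfg = SyntheticConfig(
        n_asd=80,
        n_sib=0,
        n_neu=80,
        variables=TOY_VARS,
        delta={"8-OHG": 1.5, "GSSG": 1.5, "Tyrosine": 1.5},
        vineland_link=None,
        seed=42,
    )
    ds, truth = generate_cohorts(cfg)
    return ds, truth


@pytest.fixture
def null_two_cohorts():
    """Same sizes, no planted shift anywhere."""
    cfg = SyntheticConfig(
        n_asd=80, n_sib=0, n_neu=80, variables=TOY_VARS, vineland_link=None, seed=7
    )
    ds, _ = generate_cohorts(cfg)
    return ds
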