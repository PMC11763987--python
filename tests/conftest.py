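import numpy as np
import pytest

from dihedra.features import assemble_matrix, impute_missing
from dihedra.synthetic import EnsembleParams, generate_ensemble, sample_dihedrals
from dihedra.variants import HUMAN_AMYLIN, VariantSpec, default_manifest, delete_positions


@pytest.fixture(scope="session")
def specs():
    return default_manifest()


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down ensemble layout for fast tests (2 x 30 frames)."""
    return EnsembleParams(n_trajectories=2, frames_per_trajectory=30, seed=11)


@pytest.fixture(scope="session")
def small_matrix(specs, small_params):
    """Imputed feature matrix of the default design at reduced depth."""
    tabs = [(s.name, s.class_label, sample_dihedrals(s, small_params)) for s in specs]
    return impute_missing(assemble_matrix(tabs))


@pytest.fixture(scope="session")
def deletion_spec():
    """A low-affinity construct missing reference residues 25 and 26."""
    return VariantSpec(
        "del2526",
        delete_positions(HUMAN_AMYLIN, (25, 26)),
        "low_affinity_antagonist",
        (25, 26),
    )


@pytest.fixture(scope="session")
def tiny_ensemble(specs, small_params):
    return generate_ensemble(specs[0], small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
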