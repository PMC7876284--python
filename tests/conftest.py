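"""Shared fixtures: expensive synthetic objects built once per session."""

import warnings

import numpy as np
import pytest

from spinefsu import febuild, ssm, synthetic

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*did not converge.*")


@pytest.fixture(scope="session")
def default_vertebra():
    return synthetic.generate_vertebra(synthetic.VertebraParams())


@pytest.fixture(scope="session")
def default_fsu():
    return synthetic.generate_fsu(synthetic.FSUSpec())


@pytest.fixture(scope="session")
def population():
    """50 corresponded vertebrae with 3 known smooth modes (noise-free)."""
    return synthetic.generate_population(
        synthetic.VertebraParams(), n=50, n_modes=3,
        mode_scales=synthetic.DEFAULT_MODE_SCALES, seed=1,
    )


@pytest.fixture(scope="session")
def shape_model(population):
    samples, _, _ = population
    aligned, _ = ssm.generalized_procrustes([s[0] for s in samples])
    return ssm.build_shape_model(aligned, 3, samples[0][1])


@pytest.fixture(scope="session")
def fe_model(default_fsu):
    fsu = default_fsu
    return febuild.assemble_fsu_model(
        fsu.upper_mesh, fsu.lower_mesh, fsu.upper_gt, fsu.lower_gt,
        grade="healthy",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
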