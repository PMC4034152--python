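import numpy as np
import pytest

import ectospec as es


def lorentzian(wn, center, fwhm, amplitude=1.0):
    hw = fwhm / 2.0
    return amplitude * hw**2 / ((wn - center) ** 2 + hw**2)


def gaussian(wn, center, fwhm, amplitude=1.0):
    return amplitude * np.exp(-4 * np.log(2) * (wn - center) ** 2 / fwhm**2)


def make_spectrum(values, sample_id="s", grid=es.CANONICAL_GRID, **meta):
    return es.Spectrum(grid, values, es.SampleMeta(sample_id=sample_id, **meta))


@pytest.fixture(scope="session")
def grid():
    return es.CANONICAL_GRID


@pytest.fixture(scope="session")
def templates():
    return es.builtin_templates()


@pytest.fixture(scope="session")
def default_dataset():
    """The study-composition synthetic dataset at default noise, seed 42."""
    return es.generate_dataset(es.GeneratorConfig())


@pytest.fixture(scope="session")
def default_tree(default_dataset):
    feats = es.extract_dataset_features(default_dataset)
    return es.ward_linkage(es.distance_matrix(feats))


@pytest.fixture(scope="session")
def default_truth(default_dataset):
    return {s.meta.sample_id: s.meta.species for s in default_dataset}
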