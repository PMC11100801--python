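"""Shared fixtures: small, fast phantom configurations.

Unit tests use deliberately tiny fields (a few cells, coarse voxels) so
the whole suite stays quick; full-scale recovery runs live in
test_acceptance.py.
"""

import numpy as np
import pytest

from mgquant.synthetic import GeneratorConfig, generate_microglia_volume


def tiny_config(seed: int = 0, **kw) -> GeneratorConfig:
    """A coarse-voxel 4-cell field that generates in well under a second."""
    kw.setdefault("voxel_size", (0.5, 0.25, 0.25))
    kw.setdefault("n_cells", 4)
    kw.setdefault("soma_radius", 2.0)
    kw.setdefault("process_length", 3.0)
    kw.setdefault("n_synaptic_puncta", 20)
    kw.setdefault("lysosome_fraction", 0.06)
    return GeneratorConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def tiny_field():
    """One shared small engulfment field with its truth."""
    return generate_microglia_volume(tiny_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
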