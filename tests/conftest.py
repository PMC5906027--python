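import numpy as np
import pytest

from lesion_rsa.core import GridSpec
from lesion_rsa import synth


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete synthetic world shared by unit tests.

    30 patients, 20 items in 5 categories, 6 connections (2 informative) on a
    10^3 grid — big enough for every stage to produce non-degenerate output,
    small enough to decode in seconds.
    """
    grid = GridSpec((10, 10, 10))
    template = synth.make_template(grid, n_connections=6,
                                   voxels_per_connection=60, seed=11)
    truth = synth.make_item_space(20, 5, 3, seed=11)
    informative = template.names[:2]
    synth.make_loadings(template, truth, informative, gain=2.0, seed=11)
    cohort = synth.simulate_lesions(template, 30, (12, 14), seed=11,
                                    n_foci=(2, 2), confine_to_regions=True)
    naming = synth.simulate_naming(cohort, template, truth, seed=11,
                                   target_accuracy=0.7)
    return dict(grid=grid, template=template, truth=truth, cohort=cohort,
                naming=naming, informative=informative)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
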