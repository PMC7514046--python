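import numpy as np
import pytest

from miniscrewsim import anatomy
from miniscrewsim.pipeline import RunConfig, measure_cohort, simulate
from miniscrewsim.stats import build_cohort_table


@pytest.fixture(scope="session")
def default_segments():
    """Noise-free default segment per (jaw, site), normodivergent, left."""
    return {
        (jaw, site): anatomy.make_segment(jaw, site, facial_type_params="normodivergent")
        for jaw in anatomy.JAWS
        for site in anatomy.SITES
    }


@pytest.fixture(scope="session")
def cohort60():
    """The full-size default run shared by the heavy acceptance tests.

    60 subjects (20 per facial group), 4 sites x 4 angles, bilateral ->
    1920 per-side records and 960 averaged rows.
    """
    config = RunConfig(n_per_group=20, seed=11)
    subjects = simulate(config)
    records = measure_cohort(subjects, config)
    table = build_cohort_table(subjects, records)
    return dict(config=config, subjects=subjects, records=records, table=table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
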