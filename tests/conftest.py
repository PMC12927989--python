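import numpy as np
import pandas as pd
import pytest

import myoentropy as me
from myoentropy import pipeline


@pytest.fixture(scope="session")
def tess100():
    """A 100-fiber jittered tessellation (default generator settings)."""
    return me.generate_tessellation(100, (122, 122), jitter=0.35, seed=7)


@pytest.fixture(scope="session")
def rendered_sample(tess100):
    """Noiseless render of tess100 with clustered types."""
    types = me.assign_fiber_types(tess100, clustering=0.4, seed=8)
    img, mask = me.render_histology_image(tess100, types, noise_sd=0.0, seed=9)
    return tess100, types, img, mask


@pytest.fixture(scope="session")
def small_cohort():
    """20 participants x ~60 fibers, full metrics computed."""
    cohort = me.generate_cohort(
        n_participants=20, fibers_per_participant=(60, 60), seed=42
    )
    fibers = pipeline.compute_fiber_metrics(cohort.fibers)
    return cohort, fibers


@pytest.fixture()
def zscored_cohort(small_cohort):
    cohort, fibers = small_cohort
    return cohort, me.stratified_zscore(fibers, min_stratum_n=2)
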