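import numpy as np
import pytest

from scintrec.segmentation import create_body_mask
from scintrec.synthetic import CohortSpec, PhantomSpec, render_cohort_images, simulate_cohort

#: Desk-scale phantom geometry shared across the suite.
SMALL_PHANTOM = dict(rows=128, cols=40)


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients with rendered images at desk-scale geometry."""
    patients = simulate_cohort(CohortSpec(n_patients=12, seed=11))
    render_cohort_images(
        patients, PhantomSpec(seed=11, **SMALL_PHANTOM), image_coupling=1.0
    )
    return patients


@pytest.fixture(scope="session")
def phantom_pair(small_cohort):
    """One rendered anterior/posterior pair with its segmentation masks."""
    p = small_cohort[0]
    seg_a = create_body_mask(p.images.anterior)
    seg_p = create_body_mask(p.images.posterior)
    return p, seg_a.mask, seg_p.mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
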