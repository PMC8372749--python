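"""Shared phantom fixtures (session-scoped: generation is the slow part)."""

import numpy as np
import pytest

from mmii.phantom import (PhantomSpec, default_implant_plan, make_implant_ct,
                          make_perfusion_pair, make_t1_phantom)

#: Absolute CT intensity isolating metal contacts from bone in the phantom
#: (bone renders at 1000, contacts at 3000).
CT_METAL_THRESHOLD = 1200.0


@pytest.fixture(scope="session")
def t1_case():
    """64^3 @ 2 mm T1 head phantom with landmark truth."""
    spec = PhantomSpec(seed=1)
    vol, truth = make_t1_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def implant_case():
    """102^3 @ 1.25 mm post-implant CT phantom, 3 electrodes x 8 contacts."""
    spec = PhantomSpec(dims=(102, 102, 102), voxel_size=1.25, seed=0)
    spec.implant_plan = default_implant_plan(spec)
    ct, truth = make_implant_ct(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def perfusion_case():
    """Perfusion pair with one +15% r=8 mm hyperperfusion blob."""
    spec = PhantomSpec(seed=0, blob_specs=[((15.0, 0.0, 15.0), 8.0, 0.15)])
    ictal, interictal, mask, truth = make_perfusion_pair(spec)
    return spec, ictal, interictal, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
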