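import numpy as np
import pytest

from steamref.sequence_models import (
    AcquisitionProtocol,
    ReferenceScheme,
    fibonacci_directions,
    postmortem_protocol,
)
from steamref.tissue_signals import BiexponentialModel, CylinderTwoCompartmentModel


@pytest.fixture(scope="session")
def protocol():
    """The published postmortem protocol (8 diffusion times, 30 directions)."""
    return postmortem_protocol()


@pytest.fixture(scope="session")
def biexp():
    """Biexponential model in the published line-plot regime."""
    return BiexponentialModel(f_s=0.3, D_s=0.2, D_f=1.0)


@pytest.fixture(scope="session")
def cylinder():
    """Default restricted-cylinder model: r=5 um, D_i=D_h=2, f_i=0.8, axis x."""
    return CylinderTwoCompartmentModel()


def make_protocol(
    b=2.5,
    b0_frac=0.2,
    Delta_list=(70.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0),
    delta=2.22,
    n_directions=8,
):
    """Small helper for protocols with a given nominal b and b0/b fraction."""
    scheme = ReferenceScheme(
        mode="fixed_b0",
        b0_at_delta_max=b0_frac * b if b0_frac > 0 else 1e-12,
        delta_max=max(Delta_list),
        n_axes=3,
    )
    return AcquisitionProtocol(
        Delta_list=Delta_list,
        delta=delta,
        nominal_b=b,
        directions=fibonacci_directions(n_directions),
        reference=scheme,
    )
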