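import numpy as np
import pytest

from plaqmap import (
    AcquisitionConfig,
    DepositSpec,
    TissueModel,
    VesselSpec,
    render_echo_stack,
)

TES_14 = np.linspace(9.0, 127.0, 14)


@pytest.fixture(scope="session")
def acq_default() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def tissue_default() -> TissueModel:
    return TissueModel()


def make_vessel(
    n_slices: int = 10,
    f_max: float = 0.25,
    shares=(0.5, 0.3, 0.2),
    lumen_radius: float = 2.5,
    outer_radius: float = 4.8,
    max_slice: int = 4,
    seed: int = 11,
    deposit_t2=(30.0, 25.0, 35.0),
) -> VesselSpec:
    """A hand-built three-deposit vessel used across tests."""
    weights = 0.3 + 0.7 * np.exp(
        -((np.arange(n_slices) - max_slice) ** 2) / 8.0
    )
    weights[max_slice] = 1.0
    angles = (0.3, 2.4, 4.4)
    deposits = [
        DepositSpec(angle=a, share=s, t2=t)
        for a, s, t in zip(angles, shares, deposit_t2)
    ]
    return VesselSpec(
        patient_id="P000",
        side="left",
        symptomatic=False,
        bifurcation_slice=max_slice,
        max_slice=max_slice,
        lumen_radius=lumen_radius,
        outer_radius=outer_radius,
        f_max=f_max,
        slice_weights=weights,
        deposits=deposits,
        seed=seed,
    )


@pytest.fixture(scope="session")
def simple_vessel() -> VesselSpec:
    return make_vessel()


@pytest.fixture(scope="session")
def rendered_vessel(simple_vessel, acq_default, tissue_default):
    """(stack, truth) of the noiseless three-deposit vessel."""
    return render_echo_stack(simple_vessel, acq_default, tissue_default)
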