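import numpy as np
import pytest

from patlaknet import simulate as sim


@pytest.fixture(scope="session")
def pif():
    return sim.PlasmaInputFunction()


@pytest.fixture(scope="session")
def protocol():
    return sim.AcquisitionProtocol()


@pytest.fixture(scope="session")
def equilibrium_protocol():
    """Thirteen passes spanning 600-3590 s, so a t* = 1800 s fit uses only
    frames inside the Patlak equilibrium window while the input function
    stays contiguously sampled."""
    return sim.AcquisitionProtocol(
        pass_windows=tuple((600.0 + 230.0 * k, 230.0) for k in range(13)),
        suv_window=(3600.0, 1200.0),
    )


def novb_subject(matrix=48, n_slices=4, seed=0):
    """A phantom with vb = 0 tissues (blood pool stays vb = 1).

    With no vascular fraction the Patlak slope equals K1*k3/(k2+k3)
    exactly in the equilibrium limit, which the identity tests rely on.
    """
    import dataclasses
    [s] = sim.make_cohort(1, variability=0.0, n_lesions_per_subject=0, seed=seed,
                          matrix=matrix, n_slices=n_slices)
    params = {}
    for label, p in s.params_by_label.items():
        params[label] = p if p.vb == 1.0 else dataclasses.replace(p, vb=0.0)
    return dataclasses.replace(s, params_by_label=params)


@pytest.fixture(scope="session")
def vb0_subject():
    return novb_subject()


@pytest.fixture(scope="session")
def noiseless_render(vb0_subject, equilibrium_protocol):
    return sim.render_subject(vb0_subject, equilibrium_protocol,
                              noise_scale=0.0, psf_fwhm=0.0, seed=0)
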