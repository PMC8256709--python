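import numpy as np
import pytest

from fibrilsaxs import StepDensityParams, default_truth, generate_saxs_profile
from fibrilsaxs.synth import default_saxs_q_grid


@pytest.fixture(scope="session")
def saxs_q():
    return default_saxs_q_grid()


@pytest.fixture(scope="session")
def control_truth():
    """Hydrated non-glycated control: D=65.5 nm, sigma=0.46, delta_rho=0.08."""
    return default_truth(seed=0)


@pytest.fixture(scope="session")
def control_profile(control_truth, saxs_q):
    """Noiseless meridional SAXS curve of the control truth."""
    return generate_saxs_profile(control_truth, saxs_q, noise="none")


def sampled_step_density(params: StepDensityParams, oversample: int = 2**14):
    """Explicitly sampled N-period two-level density (independent oracle).

    Returns (z, rho) with ``oversample`` samples per period.
    """
    n_tot = params.N * oversample
    z = (np.arange(n_tot) + 0.5) * params.D / oversample
    frac = (z / params.D) % 1.0
    rho = np.where(frac < params.sigma,
                   params.rho_ave + params.delta_rho,
                   params.rho_ave - params.delta_rho)
    return z, rho


def fourier_intensity_at(z, rho, q_values):
    """|direct Fourier sum of a sampled density|^2 at arbitrary q values."""
    dz = z[1] - z[0]
    q = np.atleast_1d(np.asarray(q_values, dtype=float))
    amp = np.array([np.sum(rho * np.exp(1j * qq * z)) * dz for qq in q])
    return np.abs(amp) ** 2
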