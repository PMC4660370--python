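import numpy as np
import pytest

from allokin import saxs as S


@pytest.fixture(scope="session")
def q_grid():
    """Instrument-like q grid: 0.005–0.35 Å⁻¹, 400 points."""
    return np.linspace(0.005, 0.35, 400)


@pytest.fixture(scope="session")
def sphere_curve_r40(q_grid):
    """Exact normalized sphere scattering curve, R = 40 Å, with tiny sigma."""
    I = S.sphere_form_factor(q_grid, 40.0) ** 2
    return S.ScatteringCurve(q_grid, I, sigma=np.full_like(q_grid, 1e-4))


def sphere_pofr_closed_form(r, R):
    """Closed-form pair-distance distribution of a homogeneous sphere."""
    x = np.asarray(r, dtype=float) / R
    p = r ** 2 * (1.0 - 0.75 * x + x ** 3 / 16.0)
    p = np.where(np.asarray(r) <= 2 * R, p, 0.0)
    return np.clip(p, 0.0, None)
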