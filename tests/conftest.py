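import numpy as np
import pytest

from fpowa import RawCurveSet, TimeGrid, build_basis, fit_penalized, select_lambda_gcv


@pytest.fixture
def unit_grid():
    return TimeGrid(np.linspace(0.0, 1.0, 21))


@pytest.fixture
def affine_set(unit_grid):
    """Three affine curves y = a t + b (exactly representable by the basis)."""
    t = unit_grid.points
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([0.5, -1.0, 0.0])
    return RawCurveSet(grid=unit_grid, values=a[:, None] * t + b[:, None])


@pytest.fixture
def sine_set(unit_grid):
    t = unit_grid.points
    phases = np.array([0.0, 0.05, 0.1, 0.15])
    vals = np.sin(2 * np.pi * (t[None, :] + phases[:, None]))
    return RawCurveSet(grid=unit_grid, values=vals)


def smooth_exact(raw, n_basis=None):
    """Unpenalized fit, adequate for exactly-representable curves."""
    basis = build_basis(raw.grid, n_basis)
    return fit_penalized(raw, basis, 0.0)


def smooth_gcv(raw, n_basis=None):
    basis = build_basis(raw.grid, n_basis)
    return select_lambda_gcv(raw, basis)
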