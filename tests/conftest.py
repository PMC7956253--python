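"""Shared fixtures: default physiology, packaged formulations, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from phagopbpk import (
    ModelSpec,
    OrganPhysiology,
    Physiology,
    load_all_formulations,
    load_physiology,
)
from phagopbpk.pbpk_core import CompiledModel, compile_model


@pytest.fixture(scope="session")
def phys():
    return load_physiology()


@pytest.fixture(scope="session")
def formulations():
    return load_all_formulations()


@pytest.fixture(scope="session")
def reference_formulation(formulations):
    """The formulation used for recovery and ordering experiments."""
    return formulations["mPEG5k-9.09%-80 nm"]


@pytest.fixture(scope="session")
def pcs_spec():
    return ModelSpec(variant="PCs")


@pytest.fixture(scope="session")
def epr_spec():
    return ModelSpec(variant="EPR")


@pytest.fixture(scope="session")
def two_organ_phys():
    """Reduced liver + rest-of-body circulation (no lung) for oracle runs."""
    organs = {
        "liver": OrganPhysiology("liver", volume_fraction=0.055,
                                 blood_volume_fraction=0.31, flow_fraction=0.3),
        "rest_of_body": OrganPhysiology("rest_of_body", volume_fraction=0.85,
                                        blood_volume_fraction=0.04, flow_fraction=0.7),
    }
    return Physiology(
        body_weight_kg=0.02,
        cardiac_output_ml_h=740.0,
        venous_volume_ml=0.654,
        arterial_volume_ml=0.326,
        organs=organs,
        tumour_volume_ml=0.55,
    )


def rk4_trajectory(model: CompiledModel, dose_mg: float, times: np.ndarray,
                   h: float = 1e-3) -> np.ndarray:
    """Fixed-step classical Runge-Kutta reference integration of a model RHS.

    Deliberately naive (no adaptivity, no stiffness handling beyond a small
    step) so it is independent of the production integrator; returns the
    state matrix at the requested times.
    """
    t_end = float(times[-1])
    y = model.initial_state(dose_mg).astype(float)
    out = np.empty((y.size, times.size))
    next_idx = 0
    t = 0.0
    if times[0] == 0.0:
        out[:, 0] = y
        next_idx = 1
    n_steps = int(np.ceil(t_end / h))
    for _ in range(n_steps):
        step = min(h, t_end - t)
        if step <= 0:
            break
        k1 = model.rhs(t, y)
        k2 = model.rhs(t + step / 2, y + step / 2 * k1)
        k3 = model.rhs(t + step / 2, y + step / 2 * k2)
        k4 = model.rhs(t + step, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += step
        while next_idx < times.size and times[next_idx] <= t + 1e-12:
            # state at the grid time: one partial RK4 step back-interpolation
            # is unnecessary because grid times are multiples of h
            out[:, next_idx] = y
            next_idx += 1
    return out


@pytest.fixture(scope="session")
def rk4_oracle():
    return rk4_trajectory
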