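"""Shared fixtures: synthetic cohorts at two scales.

The small cohort (16³ grid) keeps unit tests fast; the default-scale
cohorts (32³, n=400) back the benchmark-style analyses.
"""

import numpy as np
import pytest

import voxelopt as vx


@pytest.fixture(scope="session")
def small_spec():
    return vx.CohortSpec(
        n_subjects=60,
        grid_shape=(16, 16, 16),
        native_spacing_mm=2.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """60 subjects, 16³ grid, young/old design — fast classification data."""
    subjects, table = vx.generate_cohort(small_spec, design="two_group")
    return subjects, table


@pytest.fixture(scope="session")
def classification_cohort():
    """The default-scale classification cohort: 400 subjects, 32³ grid."""
    spec = vx.CohortSpec(seed=0)
    subjects, table = vx.generate_cohort(spec, design="two_group")
    return spec, subjects, table


def matern52_posterior_oracle(model, query_mm):
    """Direct kernel-matrix computation of the GP posterior from the fitted
    hyper-parameters — an independent linear-algebra oracle used to check
    the surrogate's predictions."""
    bounds = model.bounds
    X = bounds.to_unit(np.stack([o.params.as_array() for o in model.observations]))
    y = np.array([o.y for o in model.observations])
    y_z = (y - model.y_mean) / model.y_sd
    k1 = model.gpr.kernel_.k1
    c = k1.k1.constant_value
    ls = np.atleast_1d(k1.k2.length_scale)
    noise = model.gpr.kernel_.k2.noise_level

    def matern(a, b):
        d = np.sqrt((((a[:, None, :] - b[None, :, :]) / ls) ** 2).sum(-1))
        s5d = np.sqrt(5.0) * d
        return c * (1.0 + s5d + 5.0 * d**2 / 3.0) * np.exp(-s5d)

    K = matern(X, X) + (noise + 1e-10) * np.eye(len(X))
    Q = bounds.to_unit(np.atleast_2d(query_mm))
    ks = matern(Q, X)
    Kinv = np.linalg.inv(K)
    mean_z = ks @ Kinv @ y_z
    var_z = c - np.einsum("ij,jk,ik->i", ks, Kinv, ks)
    mean = mean_z * model.y_sd + model.y_mean
    sd = np.sqrt(np.clip(var_z, 0, None)) * model.y_sd
    return mean, sd


@pytest.fixture(scope="session")
def default_template():
    spec = vx.CohortSpec(seed=0)
    return vx.generate_atrophy_template(
        spec.grid_shape, spec.native_spacing_mm, spec.signal_scale_mm, spec.seed
    )
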