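"""Shared fixtures: the ⁹⁰Y spectrum, liver kernels, and a continuous
voxel-value oracle independent of the implementation's sampling scheme."""

import numpy as np
import pytest

from y90dose import build_beta_spectrum, build_radial_kernel, voxelize_kernel
from y90dose.media import LIVER, WATER


@pytest.fixture(scope="session")
def y90_spectrum():
    return build_beta_spectrum()


@pytest.fixture(scope="session")
def liver_kernel(y90_spectrum):
    return build_radial_kernel(y90_spectrum, LIVER)


@pytest.fixture(scope="session")
def water_kernel(y90_spectrum):
    return build_radial_kernel(y90_spectrum, WATER)


@pytest.fixture(scope="session")
def dpk4(liver_kernel):
    return voxelize_kernel(liver_kernel, 4.0)


@pytest.fixture(scope="session")
def dpk2(liver_kernel):
    return voxelize_kernel(liver_kernel, 2.0)


def continuous_voxel_oracle(kernel, voxel, idx, n_theta=200, n_u=2500):
    """Average of k(|t − s|) over source/target voxel pairs, evaluated as a
    1-D radial quadrature against the exact displacement density.

    The displacement t − s of two independent uniform points (source in the
    central voxel, target in the voxel at integer offset `idx`) has a
    separable triangular density centered at idx·voxel.  Reducing over
    spherical shells gives value = ∫ k(u) g(u) du with a smooth g, so the
    quadrature converges even though k ~ 1/u² near the origin.
    """
    a = float(voxel)
    c = np.asarray(idx, float) * a
    umax = float(np.linalg.norm(np.abs(c) + a))
    u = np.linspace(1e-6, umax, n_u)
    th = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    ph = (np.arange(2 * n_theta) + 0.5) * np.pi / n_theta
    st, ct = np.sin(th), np.cos(th)
    om = np.stack(
        [
            np.outer(st, np.cos(ph)).ravel(),
            np.outer(st, np.sin(ph)).ravel(),
            np.repeat(ct, len(ph)),
        ],
        axis=-1,
    )
    w = np.repeat(st, len(ph)) * (np.pi / n_theta) ** 2
    g = np.empty(len(u))
    for i, ui in enumerate(u):
        d = ui * om - c
        tri = np.clip(1.0 - np.abs(d) / a, 0.0, None) / a
        g[i] = float((tri.prod(axis=1) * w).sum()) * ui * ui
    return float(np.trapezoid(kernel.evaluate(u) * g, u))
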