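"""Shared fixtures: bench configurations and cached through-focus sweeps."""

from __future__ import annotations

import numpy as np
import pytest

import monovis as mv


@pytest.fixture(scope="session")
def cornea() -> mv.ModelCornea:
    return mv.ModelCornea()


@pytest.fixture(scope="session")
def cornea_perfect() -> mv.ModelCornea:
    return mv.ModelCornea(sa_coefficient_um=0.0)


@pytest.fixture(scope="session")
def cfg3() -> mv.BenchConfig:
    return mv.BenchConfig(aperture_diameter_mm=3.0)


@pytest.fixture(scope="session")
def cfg45() -> mv.BenchConfig:
    return mv.BenchConfig(aperture_diameter_mm=4.5)


@pytest.fixture(scope="session")
def acuity_cfg() -> mv.AcuityConfig:
    return mv.AcuityConfig()


@pytest.fixture(scope="session")
def csf3(cfg3, acuity_cfg) -> mv.NeuralCSF:
    return mv.default_csf(cfg3, acuity_cfg)


@pytest.fixture(scope="session")
def mono_curves_20d(cfg3, cornea, csf3, acuity_cfg):
    """Monocular defocus curves of both presets at 20 D, 3-mm aperture,
    refracted to emmetropia — the standard monovision inputs."""
    out = {}
    for name in ("quantum_like", "emv_like"):
        tfd = mv.emmetropic_sweep(mv.make_iol_design(name, 20.0), cornea, cfg3)
        out[name] = mv.to_monocular(
            mv.defocus_curve(tfd, csf3, acuity_cfg), acuity_cfg
        )
    return out


@pytest.fixture()
def flat_curve():
    """Monocular curve flat at 0.1 logMAR over the standard grid."""
    grid = np.round(np.arange(-2.5, 0.5001, 0.05), 10)
    return mv.DefocusCurve(grid, np.full(len(grid), 0.1), "monocular")
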