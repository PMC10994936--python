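"""Shared phantom fixtures.

Everything is generated programmatically; session scope keeps the larger
renders to one apiece.
"""

from __future__ import annotations

import numpy as np
import pytest

import octnad as on


@pytest.fixture(scope="session")
def homogeneous_noiseless():
    """Noiseless homogeneous half-space, mu = 1 mm^-1, 96^3."""
    spec = on.homogeneous_preset(1.0, n=96)
    return spec, on.render_volume(spec), on.build_mu_field(spec)


@pytest.fixture(scope="session")
def homogeneous_speckled():
    """Speckled homogeneous half-space, mu = 1 mm^-1, surface at 40 px."""
    spec = on.homogeneous_preset(
        1.0, n=96, noise="speckle", seed=3, surface_z_um=40 * 9.375
    )
    return spec, on.render_volume(spec), on.build_mu_field(spec)


@pytest.fixture(scope="session")
def glioma_flat():
    """glioma_preset rendered, surface-detected and flattened."""
    spec = on.glioma_preset()
    vol = on.render_volume(spec)
    truth = on.build_mu_field(spec)
    flat = on.flatten(vol, on.detect_surface(vol))
    return spec, flat, truth


@pytest.fixture(scope="session")
def tumor_roi():
    """A tumor-interior ROI for the glioma preset (en-face pixels)."""
    return on.EnfaceROI(x0=30, x1=50, y0=33, y1=53)


@pytest.fixture(scope="session")
def cylinder_flat():
    """Speckled cylinder phantom, flattened, with truth."""
    spec = on.cylinder_preset()
    vol = on.render_volume(spec)
    truth = on.build_mu_field(spec)
    flat = on.flatten(vol, on.detect_surface(vol))
    return spec, flat, truth
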