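"""Shared fixtures: tiny synthetic studies and the full phantom pipelines."""

from __future__ import annotations

import numpy as np
import pytest

from perimotion.io import EXPECTED_PHASES, CTVolume, PhaseSeries
from perimotion.phantom import PhantomSpec, generate_phantom_series
from perimotion.pipeline import run_study


def make_tiny_series(shape=(8, 8, 8), spacing=1.0, fill=0.0):
    """A nine-phase series of constant tiny volumes (plumbing tests)."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    volumes = [
        CTVolume(voxels=np.full(shape, fill, dtype=np.float32), affine=affine, phase_percent=p)
        for p in EXPECTED_PHASES
    ]
    return PhaseSeries(volumes=volumes, ref_index=4)


def make_blob_volume(shape=(32, 32, 32), spacing=1.0, center=None, radius=8.0,
                     inside=100.0, outside=0.0, phase=50):
    """A smooth spherical blob volume for registration tests."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    if center is None:
        center = np.asarray(shape) * spacing / 2.0
    idx = np.indices(shape).astype(float) * spacing
    r = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(3)))
    # smooth edge so intensity gradients exist everywhere near the boundary
    voxels = outside + (inside - outside) / (1.0 + np.exp((r - radius) / 1.5))
    return CTVolume(voxels=voxels.astype(np.float32), affine=affine, phase_percent=phase)


@pytest.fixture(scope="session")
def phantom_kappa0():
    """Free-sliding phantom study plus its pipeline result."""
    spec = PhantomSpec(adhesion_coupling=0.0, rng_seed=1)
    series, peri, eat, truth, line = generate_phantom_series(spec)
    result = run_study(series, peri, line)
    return {"spec": spec, "series": series, "peri": peri, "eat": eat,
            "truth": truth, "centerline": line, "result": result}


@pytest.fixture(scope="session")
def phantom_kappa1():
    """Fully adhered phantom study plus its pipeline result."""
    spec = PhantomSpec(adhesion_coupling=1.0, rng_seed=1)
    series, peri, eat, truth, line = generate_phantom_series(spec)
    result = run_study(series, peri, line)
    return {"spec": spec, "series": series, "peri": peri, "eat": eat,
            "truth": truth, "centerline": line, "result": result}
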