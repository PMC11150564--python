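"""Shared fixtures: simulated phantoms run once per session where possible."""

import numpy as np
import pytest

from dtialps import (
    ScalarMap,
    compute_mask,
    fit_tensor,
    scalar_maps,
    simulate_phantom,
)
from dtialps.synthetic import PhantomSpec, make_gradient_table


@pytest.fixture(scope="session")
def gtab64():
    return make_gradient_table(64, 1000.0, 1)


def run_pipeline(vol):
    """b0 mask -> WLS tensor fit -> scalar maps, as the CLI chains them."""
    b0 = ScalarMap(
        vol.data[..., vol.gradients.b0_mask].mean(axis=-1), vol.affine, "b0"
    )
    mask = compute_mask(b0)
    return scalar_maps(fit_tensor(vol, mask=mask))


@pytest.fixture(scope="session")
def phantom_noiseless(gtab64):
    """Noiseless default-geometry phantom with true ALPS index 1.44."""
    spec = PhantomSpec().with_alps_index(1.44)
    vol, sidecar = simulate_phantom(spec, gtab=gtab64)
    return vol, sidecar, run_pipeline(vol)


@pytest.fixture(scope="session")
def phantom_snr30(gtab64):
    """Same phantom at SNR 30 (seed fixed)."""
    spec = PhantomSpec(snr=30.0).with_alps_index(1.44)
    vol, sidecar = simulate_phantom(spec, seed=42, gtab=gtab64)
    return vol, sidecar, run_pipeline(vol)


def random_spd_tensors(n, rng, scale=1e-3):
    """Random positive-definite 3x3 tensors with realistic diffusivities."""
    out = []
    for _ in range(n):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        lam = rng.uniform(0.2, 2.2, 3) * scale
        out.append(q @ np.diag(lam) @ q.T)
    return out
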