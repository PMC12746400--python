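"""Shared fixtures.  The expensive seeded training runs are session-scoped so
unit and acceptance tests reuse one run instead of retraining."""

from __future__ import annotations

import numpy as np
import pytest

from cineflow.phantom import PhantomConfig, generate_cine_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Reference 64x64 phantom with default (study) conditions."""
    return generate_cine_phantom(PhantomConfig(grid_size=(64, 64), seed=1))


@pytest.fixture(scope="session")
def phantom32():
    return generate_cine_phantom(PhantomConfig(grid_size=(32, 32), seed=0))


@pytest.fixture(scope="session")
def static_phantom():
    return generate_cine_phantom(PhantomConfig(
        grid_size=(32, 32), contraction_amplitude=0.0, rotation_amplitude=0.0,
        noise_sigma=0.0, n_frames=5, seed=0))


@pytest.fixture(scope="session")
def trained_registrar(phantom32):
    """Tiny registration model, 300 self-supervised steps on one phantom."""
    from cineflow.estimators import MopnetRegistrar

    reg = MopnetRegistrar(profile="tiny", steps=300, seed=0)
    reg.fit([phantom32.images.frames])
    return reg


@pytest.fixture(scope="session")
def recon_case():
    """R=8 undersampled phantom with zero-filled and truth-flow kt-SLR recon."""
    from cineflow.moco import MocoConfig, ktslr_reconstruct
    from cineflow.pipeline import prepare_case

    gt, ks, zf = prepare_case(seed=3, grid=32, R=8.0)
    recon = ktslr_reconstruct(ks, gt.flow_to_reference(0),
                              MocoConfig(reference_frame=0))
    return gt, ks, zf, recon
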