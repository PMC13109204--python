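import numpy as np
import pytest

from patchpo import (
    PatchSimConfig,
    estimate_po_from_trace,
    simulate_patch_trace,
)

#: operating point of the multi-channel recovery checks: six identical
#: channels of -0.35 pA at moderate open probability, 60 s at 10 kHz with
#: 0.1 kHz digital filtering
MULTI_CHANNEL_CFG = dict(
    n_channels=6,
    p_open=0.34,
    unitary_amplitude=-0.35,
    noise_sd=0.05,
    duration=60.0,
)

SINGLE_CHANNEL_CFG = dict(
    n_channels=1,
    p_open=0.879,
    unitary_amplitude=-0.32,
    noise_sd=0.05,
    duration=60.0,
)


@pytest.fixture(scope="session")
def multi_channel_run():
    """One simulated six-channel patch plus its latent open counts."""
    cfg = PatchSimConfig(**MULTI_CHANNEL_CFG, seed=1)
    trace, latent = simulate_patch_trace(cfg)
    return cfg, trace, latent


@pytest.fixture(scope="session")
def multi_channel_estimates():
    """Full-pipeline estimates over ten seeds at the six-channel point.

    Shared between the open-probability and unitary-amplitude recovery
    checks so the simulations run once.
    """
    results = []
    for seed in range(1, 11):
        cfg = PatchSimConfig(**MULTI_CHANNEL_CFG, seed=seed)
        trace, _ = simulate_patch_trace(cfg)
        results.append(estimate_po_from_trace(trace, n_channels=6))
    return results


@pytest.fixture(scope="session")
def single_channel_run():
    cfg = PatchSimConfig(**SINGLE_CHANNEL_CFG, seed=7)
    trace, latent = simulate_patch_trace(cfg)
    return cfg, trace, latent
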