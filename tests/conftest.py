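"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from emgfuse import desk_config, generate_session
from emgfuse.preprocess import PairedWindows, WindowSet


@pytest.fixture(scope="session")
def desk_session():
    """An 8-class desk-scale synthetic subject (500 Hz, 1 s movement blocks)."""
    return generate_session(desk_config(seed=1), "S1")


@pytest.fixture(scope="session")
def tiny_session():
    """A 2-class desk-scale subject for fast end-to-end runs."""
    return generate_session(desk_config(seed=7, n_classes=2, movement_s=1.5), "S1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_paired(n: int, n_classes: int, L: int = 8, seed: int = 0) -> PairedWindows:
    """Small random paired window set with balanced labels."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes + 1
    return PairedWindows(
        emg=WindowSet(rng.normal(size=(n, 12, L)), labels, "emg"),
        acc=WindowSet(rng.normal(size=(n, 36, L)), labels, "acc"),
    )
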