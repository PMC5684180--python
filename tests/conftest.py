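import numpy as np
import pytest
from hypothesis import settings

import axomem as ax

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_binary_set():
    """10 balanced binary memories in a 200-neuron network (load 0.05)."""
    return ax.generate_random_memories(200, 10, 2, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_binary_net(small_binary_set):
    return ax.hebbian_train(small_binary_set)


@pytest.fixture(scope="session")
def face_like_set():
    """Small correlated grayscale family (stand-in for the face task)."""
    return ax.generate_correlated_family(300, 3, 8, 0.65, seed=5)


@pytest.fixture(scope="session")
def face_like_net(face_like_set):
    return ax.projection_train(face_like_set)
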