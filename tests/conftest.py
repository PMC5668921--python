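from __future__ import annotations

import pytest

from svannotate.synthetic import SimulationParams, simulate


@pytest.fixture(scope="session")
def tiny_study():
    """A small seeded study shared by read-only tests."""
    return simulate(SimulationParams(n_true_svs=60, seed=123))


@pytest.fixture(scope="session")
def tiny_events(tiny_study):
    from svannotate.merge import merge_callsets

    return merge_callsets(tiny_study.callsets, max_dist=1000)
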