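"""Shared fixtures: worked-scenario runs are session-scoped since the
pipeline is deterministic and several test modules inspect the same
results."""

import pytest

import ulcersim as us


@pytest.fixture(scope="session")
def healthy_result():
    return us.run_scenario(us.preset_config("healthy"))


@pytest.fixture(scope="session")
def impaired_result():
    return us.run_scenario(us.preset_config("impaired"))


@pytest.fixture(scope="session")
def healthy_repositioned_result():
    return us.run_scenario(us.preset_config("healthy", reposition_hours=2))


@pytest.fixture(scope="session")
def impaired_repositioned_result():
    return us.run_scenario(us.preset_config("impaired", reposition_hours=2))
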