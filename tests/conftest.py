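"""Shared fixtures; heavyweight solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from choicemdp.core import TaskSpec


@pytest.fixture(scope="session")
def fig8_spec():
    """Two-state MDP: action 1 pays 1000 once, action 2 pays 1; both then
    absorb into a reward-1 self-loop."""

    def actions(s):
        return (1, 2) if s == "s1" else (1,)

    def reward(s, a):
        if s == "s1":
            return 1000.0 if a == 1 else 1.0
        return 1.0

    def transitions(s, a):
        return [("s2", 1.0)]

    return TaskSpec(actions=actions, reward=reward, transitions=transitions,
                    states=["s1", "s2"], start=["s1"])


@pytest.fixture(scope="session")
def ns_model_090():
    from choicemdp.nonstationary import solve_nonstationary

    return solve_nonstationary(gamma=0.90, tol=1e-2)


@pytest.fixture(scope="session")
def ns_model_099():
    from choicemdp.nonstationary import solve_nonstationary

    return solve_nonstationary(gamma=0.99, tol=1e-2)


@pytest.fixture(scope="session")
def novelty_model_095():
    from choicemdp.novelty import solve_novelty

    return solve_novelty(gamma=0.95, p_switch=0.05, tol=1e-3)


@pytest.fixture(scope="session")
def patch_discounted():
    from choicemdp.patch import solve_patch

    return solve_patch(gamma=0.995)


@pytest.fixture(scope="session")
def patch_undiscounted():
    from choicemdp.patch import solve_patch

    return solve_patch(gamma=1.0)


@pytest.fixture(scope="session")
def beads_solution():
    from choicemdp.beads import solve_beads

    return solve_beads()


@pytest.fixture(scope="session")
def sampling_solution():
    from choicemdp.sampling import solve_sampling

    return solve_sampling()
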