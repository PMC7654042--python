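import pytest

from dualmcs.synthetic_data import rev10, study_corpus, toy_branch, toy_chain


@pytest.fixture(scope="session")
def chain():
    return toy_chain()


@pytest.fixture(scope="session")
def branch():
    """Branch-point fixture with a desired region (constrained MCS)."""
    return toy_branch(True)


@pytest.fixture(scope="session")
def branch_plain():
    """Branch-point fixture without a desired region."""
    return toy_branch(False)


@pytest.fixture(scope="session")
def rev10_problem():
    return rev10()


@pytest.fixture(scope="session")
def all_fixtures(chain, branch, rev10_problem):
    return {"toy_chain": chain, "toy_branch": branch, "rev10": rev10_problem}


@pytest.fixture(scope="session")
def mini_corpus():
    """Small generated corpus for unit-level cross-checks."""
    return study_corpus(seed=3, count=6)
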