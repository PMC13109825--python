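import pytest

from triageaudit.codebook import load_codebook
from triageaudit.cohort import build_persona_bank, build_slices, build_vignette_bank
from triageaudit.pipeline import AuditConfig, run_audit
from triageaudit.policy import load_policy

SEED = 1


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


@pytest.fixture(scope="session")
def personas():
    return build_persona_bank(SEED)


@pytest.fixture(scope="session")
def vignettes():
    return build_vignette_bank(SEED)


@pytest.fixture(scope="session")
def slices(personas, vignettes):
    return build_slices(personas, vignettes, SEED)


@pytest.fixture(scope="session")
def policy():
    return load_policy()


@pytest.fixture(scope="session")
def full_bundle():
    """One full simulated audit (default profile, seed 1), kept in memory."""
    return run_audit(AuditConfig(seed=SEED), write=False)
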