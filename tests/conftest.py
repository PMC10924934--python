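import pytest

from riskdecode import validation


@pytest.fixture(scope="session")
def recovery_study():
    """One full parameter-recovery run shared by every test that needs it.

    Plants all study encodings in a 4-subject synthetic cohort, runs the
    complete chain (raw synthesis through cluster inference), the two
    generalization analyses and the feature-importance comparison.
    """
    return validation.run_recovery_study(seed=21)
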