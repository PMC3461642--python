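import pytest

from lvrsim import emphysema_preset, healthy_preset


@pytest.fixture(scope="session")
def healthy():
    return healthy_preset()


@pytest.fixture(scope="session")
def emphysema():
    """Calibrated severe homogeneous emphysema baseline (RV/TLC=0.68, RV=5.8 L)."""
    return emphysema_preset()


@pytest.fixture(scope="session")
def emphysema_result(emphysema):
    return emphysema.run()


@pytest.fixture(scope="session")
def shifted(emphysema):
    """Baseline vs the treatment's pressure/height shifts alone (no removal)."""
    from lvrsim import run_treated, ult_treatment

    shift_only = ult_treatment(emphysema, n_removed=0.0)
    return emphysema.run(), run_treated(emphysema, shift_only)
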