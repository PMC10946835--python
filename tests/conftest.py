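import pytest

from stomasim import build_reference_model


@pytest.fixture(scope="session")
def base_model():
    return build_reference_model("base")


@pytest.fixture(scope="session")
def aba_model():
    return build_reference_model("with_aba")
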