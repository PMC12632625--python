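import pytest

from hostguest import TitrationProtocol


@pytest.fixture
def protocol():
    """A typical titration: 20 x 2 uL of 10 mM guest into 1 mM host, 200 uL cell."""
    return TitrationProtocol(
        cell_volume=200.0,
        cell_conc=1.0e-3,
        syringe_conc=1.0e-2,
        injection_volumes=(2.0,) * 20,
    )
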