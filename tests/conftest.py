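import pytest

from eyecare_cea.life_tables import calibrate_flat_mortality, flat_life_table
from eyecare_cea.reference_inputs import IMPLIED_ANNUITY_AGE63


@pytest.fixture(scope="session")
def calibrated_life_table():
    """Flat-mortality table whose discounted annuity from age 63 at 3%
    matches the value implied by the published no-surgery QALY total."""
    q = calibrate_flat_mortality(IMPLIED_ANNUITY_AGE63, start_age=63, rate=0.03)
    return flat_life_table(q)
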