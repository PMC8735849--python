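import pandas as pd
import pytest

from nudipep import fixtures as fx


@pytest.fixture(scope="session")
def fixture_table() -> pd.DataFrame:
    return fx.load_fixture_table()


@pytest.fixture(scope="session")
def printed_rows() -> pd.DataFrame:
    """Rows with both an observed mean and a printed theoretical mass."""
    return fx.printed_mass_rows()
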