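import numpy as np
import pandas as pd
import pytest

from fluxsample import SyntheticConfig, generate_campaign


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign shared by read-only tests."""
    return generate_campaign(SyntheticConfig(seed=7))


@pytest.fixture()
def small_campaign_csv(tmp_path):
    """Hand-written 3-collar campaign file in the documented dialect."""
    text = (
        "collar_id,x_km,y_km,subplot,date,R,T,W\n"
        "A,1.0,1.0,1,2012-06-06,2.5,20.0,25.0\n"
        "A,1.0,1.0,1,2012-06-12,3.0,22.0,30.0\n"
        "A,1.0,1.0,1,2012-06-18,3.5,24.0,20.0\n"
        "B,3.0,1.0,2,2012-06-06,1.5,19.0,22.0\n"
        "B,3.0,1.0,2,2012-06-12,2.0,21.0,28.0\n"
        "C,3.0,4.0,3,2012-06-06,4.0,23.0,35.0\n"
    )
    path = tmp_path / "campaign.csv"
    path.write_text(text)
    return path


def make_series(values_T, values_W, start="2012-06-01", freq="30min", collar="X"):
    """Build a ContinuousSeries from plain arrays for integration tests."""
    from fluxsample import ContinuousSeries

    n = len(values_T)
    idx = pd.date_range(start, periods=n, freq=freq)
    return ContinuousSeries(
        collar_id=collar,
        timestamps=idx,
        T_series=np.asarray(values_T, dtype=float),
        W_series=np.asarray(values_W, dtype=float),
    )
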