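import numpy as np
import pandas as pd

from indoair.exposure_stats import ConcentrationSeries, Environment


def make_series(values, pollutant="PM10", environment="indoor", start="2022-09-26 09:00"):
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=len(values), freq="min")
    return ConcentrationSeries(
        site_id="test",
        environment=Environment(environment),
        pollutant=pollutant,
        timestamps=ts,
        values=values,
    )
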