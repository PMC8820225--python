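import numpy as np
import pytest

from deltalogcv import SampleSummary


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def rainfall_summaries():
    """Summary statistics of daily rainfall (Aug 2018-19) at three stations
    in Nan province, Thailand, as printed in the source report: n = 62 days
    each, delta-hat = share of wet days, (mu-hat, sigma2-hat) = moments of
    log wet-day amounts."""
    rows = [
        ("Chiang Klang", 0.7258, 2.1189, 1.7857),
        ("Tha Wang Pha", 0.7903, 1.6448, 3.4406),
        ("Pua", 0.7419, 1.8971, 1.8346),
    ]
    return [
        SampleSummary.from_delta_hat(62, d, mu, s2, label=label)
        for label, d, mu, s2 in rows
    ]
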