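import numpy as np
import pytest

from npcscreen import GrowthSimConfig, WellTrace


@pytest.fixture
def noiseless_trace():
    """Exact exponential: N0=1000, DT=24 h, sampled every 12 h for 120 h."""
    times = tuple(np.arange(0.0, 121.0, 12.0))
    values = tuple(1000.0 * 2.0 ** (np.asarray(times) / 24.0))
    return WellTrace(
        plate_id="P1",
        well_id="w0",
        line_id="TS1",
        genotype="T21",
        condition="untreated",
        times=times,
        values=values,
    )


@pytest.fixture
def noiseless_config():
    return GrowthSimConfig(
        noise_cv=0.0,
        fail_fraction=0.0,
        n_lines_per_genotype=2,
        replicates_per_condition=4,
        seed=11,
    )


def make_trace(values, times=None, **meta):
    values = tuple(float(v) for v in values)
    if times is None:
        times = tuple(12.0 * i for i in range(len(values)))
    defaults = dict(
        plate_id="P1",
        well_id="w",
        line_id="L1",
        genotype="Eup",
        condition="untreated",
    )
    defaults.update(meta)
    return WellTrace(times=tuple(times), values=values, **defaults)
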