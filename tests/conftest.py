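import pandas as pd
import pytest

import stcr


def make_plots(rows):
    """Build a plot-table DataFrame from terse per-plot dicts."""
    defaults = dict(strip="LFS", fert_n=0.0, fert_p=0.0, fert_k=0.0, fym=0.0,
                    stv_n=280.0, stv_p=90.0, stv_k=240.0, yield_t=5.0,
                    uptake_n=30.0, uptake_p=12.0, uptake_k=30.0)
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, plot_id=f"P{i + 1}", treatment_id=f"T{i + 1}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def zero_noise_truth():
    return stcr.default_truth(0.0, 0.0)


@pytest.fixture(scope="session")
def main_frame(zero_noise_truth):
    """Zero-noise default 72-plot main experiment."""
    records = stcr.simulate_main_experiment(
        zero_noise_truth, stcr.simulate_gradient_strips(seed=11), seed=11)
    return stcr.records_to_frame(records)


@pytest.fixture(scope="session")
def calibrated(main_frame):
    return stcr.calibrate_basic_parameters(main_frame)


@pytest.fixture(scope="session")
def published_params():
    """The published basic-parameter set as a BasicParameters object."""
    truth = stcr.default_config()["truth"]
    return stcr.BasicParameters(values={x: dict(truth[x]) for x in "npk"})


@pytest.fixture(scope="session")
def published_equations(published_params):
    return stcr.derive_equation_set(published_params)
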