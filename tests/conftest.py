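import warnings

import numpy as np
import pandas as pd
import pytest

from floodshift import (
    CommunityScenario, HydroScenario, RunConfig, StageSeries, gen_community,
    gen_hydrograph, segment_cycles,
)


def triangle_levels(low=18.0, peak=28.0, step=0.5):
    """Symmetric triangular pulse low -> peak -> low at `step` m/day."""
    up = np.arange(low, peak + step / 2, step)
    down = up[::-1][1:]
    return np.concatenate([up, down])


@pytest.fixture
def triangle_two_pulse():
    """Two consecutive triangular pulses sharing the trough: one full cycle."""
    one = triangle_levels()
    levels = np.concatenate([one, one[1:]])
    dates = pd.date_range("2000-01-01", periods=len(levels), freq="D")
    return StageSeries(dates=pd.DatetimeIndex(dates), levels=levels)


@pytest.fixture(scope="session")
def synthetic_survey():
    """A full synthetic survey: hydrograph, cycles, community tables, truth."""
    cfg = RunConfig(stars_window=7, prewhiten=False)
    stage, hydro_truth = gen_hydrograph(HydroScenario(seed=11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cycles = [c for c in segment_cycles(stage, cfg) if c.usable]
    catch, effort, labels, truth = gen_community(
        CommunityScenario(seed=12), cycles)
    return {
        "config": cfg,
        "stage": stage,
        "hydro_truth": hydro_truth,
        "cycles": cycles,
        "catch": catch,
        "effort": effort,
        "labels": labels,
        "truth": truth,
    }
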