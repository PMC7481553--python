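"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

import lfaquant as lq
from lfaquant.pipeline import run_design
from lfaquant.simulate import (AnalyteSpec, DuplexDesign, LinearResponse,
                               StripSpec)


def otsu_bruteforce(values):
    """Exhaustive between-class-variance maximizer (independent oracle).

    Evaluates every candidate threshold (each observed level above the
    minimum) with the textbook definition w0*w1*(mu0-mu1)^2 computed from
    the raw class splits; ties resolve to the smallest threshold.
    """
    v = np.asarray(values, dtype=float)
    levels = np.unique(v)
    best_score, best_t = -1.0, None
    for t in levels[1:]:
        lo = v[v < t]
        hi = v[v >= t]
        w0 = lo.size / v.size
        w1 = hi.size / v.size
        score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return int(best_t)


def make_averaged(points, analyte="a", channel="green"):
    """Averaged-replicates table from (concentration, mean_auc) pairs."""
    return pd.DataFrame([
        {"analyte": analyte, "channel": channel,
         "replicate_group": f"L{i}", "concentration": c, "mean_auc": s,
         "sd_auc": 0.0, "n": 1, "singleton": True}
        for i, (c, s) in enumerate(points)])


#: 6 levels x 3 replicates = 18 strips; read noise 2% of the largest
#: test-band amplitude (160), on the 16-bit sensor with background 200.
CAL_LEVELS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
CAL_STRIP = StripSpec(bit_depth=16, background_level=200.0, noise_sd=3.2)


def make_duplex_design(seed, levels_a=CAL_LEVELS, levels_b=CAL_LEVELS,
                       replicates=3, crosstalk=0.0, strip_spec=CAL_STRIP):
    return DuplexDesign(
        analyte_a=AnalyteSpec("a", levels_a, "nM", LinearResponse(8.0),
                              "green"),
        analyte_b=AnalyteSpec("b", levels_b, "nM", LinearResponse(6.0),
                              "red"),
        control_amplitude=150.0, replicates=replicates,
        strip_spec=strip_spec, crosstalk=crosstalk, seed=seed)


@pytest.fixture(scope="session")
def sandwich_run():
    """One full sandwich-format pipeline run (simulate → quantify →
    calibrate) at a fixed seed, shared across tests."""
    experiment, results = run_design(lq.sandwich_preset(seed=1))
    return experiment, results
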