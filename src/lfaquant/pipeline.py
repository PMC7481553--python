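"""In-memory orchestration of simulate → quantify → calibrate.

Convenience layer used by the CLI, the test-bench and scripted analyses:
runs the quantification and calibration stages on a
:class:`~lfaquant.simulate.SimulatedExperiment` without touching disk.
"""

from __future__ import annotations

import pandas as pd

from .calibrate import (CalibrationResult, calibrate_experiment,
                        merge_with_design)
from .quantify import quantify_batch
from .simulate import DuplexDesign, SimulatedExperiment, \
    generate_duplex_experiment


def quantify_experiment(experiment: SimulatedExperiment,
                        **quantify_kwargs) -> pd.DataFrame:
    """Band measurements for every capture of a simulated experiment.

    Both channels of every strip are quantified with shared consensus
    band windows per channel (see
    :func:`lfaquant.quantify.quantify_batch`).
    """
    images = []
    for strip in experiment.strips:
        images.append((strip.image_id, strip.green))
        images.append((strip.image_id, strip.red))
    quantify_kwargs.setdefault("n_lanes", 1)
    quantify_kwargs.setdefault("expected_n", 2)
    return quantify_batch(images, **quantify_kwargs)


def calibrate_simulated(experiment: SimulatedExperiment,
                        include_saturated: bool = False,
                        **quantify_kwargs
                        ) -> dict[tuple[str, str], CalibrationResult]:
    """Quantify and calibrate a simulated experiment in one call.

    Control lines validate the run and are dropped before fitting; the
    test-line measurements are joined to the experiment's design table.
    """
    measurements = quantify_experiment(experiment, **quantify_kwargs)
    tests_only = measurements[measurements["kind"] != "control"]
    merged, _ = merge_with_design(tests_only, experiment.design_table)
    return calibrate_experiment(merged, include_saturated=include_saturated)


def run_design(design: DuplexDesign, **kwargs
               ) -> tuple[SimulatedExperiment,
                          dict[tuple[str, str], CalibrationResult]]:
    """Generate, quantify and calibrate a duplex design."""
    experiment = generate_duplex_experiment(design)
    return experiment, calibrate_simulated(experiment, **kwargs)
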