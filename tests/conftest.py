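import logging
from dataclasses import dataclass

import numpy as np
import pytest

from needleloc import (PhantomConfig, PipelineConfig, generate_phantom_pair,
                       run_pipeline, score_trial)
from needleloc import bmode_axis, doppler_axis, evaluation
from needleloc.phantom import batch_configs

logging.disable(logging.INFO)


@dataclass
class BatchTrial:
    config: PhantomConfig
    truth: object
    initial_axis_error_mm: float
    refined_axis_error_mm: float
    report: evaluation.ErrorReport


@pytest.fixture(scope="session")
def phantom_batch() -> list[BatchTrial]:
    """30 seeded phantom trials spanning 0-65 degrees and 40-80 mm depths,
    run through the full pipeline, with per-stage axis errors recorded.

    Session-scoped: the batch is shared by the stage-improvement property
    test and the end-to-end accuracy tests.
    """
    trials = []
    pc = PipelineConfig()
    for cfg in batch_configs(n_trials=30, seed=0):
        bmode, doppler, truth = generate_phantom_pair(cfg)
        pre = doppler_axis.preprocess_doppler(doppler)
        clusters = doppler_axis.cluster_doppler(pre, pc.dbscan)
        axis0 = doppler_axis.initial_axis(clusters, doppler.shape, doppler=pre)
        err0 = evaluation.axis_error(truth, axis0, cfg.pixel_spacing)
        result = run_pipeline(doppler, bmode, pc)
        err1 = evaluation.axis_error(truth, result.axis, cfg.pixel_spacing)
        report = score_trial(truth, result, cfg.pixel_spacing)
        trials.append(BatchTrial(config=cfg, truth=truth,
                                 initial_axis_error_mm=err0,
                                 refined_axis_error_mm=err1,
                                 report=report))
    return trials


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
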