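"""Shared fixtures: small synthetic cohorts and fast pipeline configs.

Unit tests run on short-duration cohorts (the generative structure is the
same; only session length and booster sizes shrink) so the suite stays
fast.  The acceptance tests use the full desk-scale cohort.
"""

import numpy as np
import pytest

from scrubstep import (
    Instruction,
    Mode,
    PipelineConfig,
    Placement,
    SimulationConfig,
    default_signal_models,
    generate_cohort,
)
from scrubstep.synth import DEFAULT_NOISE_SD, StepSignalModel


def fast_sim_config(n_participants=2, sessions_per_condition=1, seed=5,
                    duration_s=12.0) -> SimulationConfig:
    """Short sessions, default generative structure otherwise."""
    cfg = SimulationConfig.desk_scale(
        n_participants=n_participants,
        sessions_per_condition=sessions_per_condition,
        seed=seed,
    )
    cfg.duration_mean_sd = {
        cond: (duration_s, 1.0) for cond in cfg.duration_mean_sd
    }
    return cfg


def fast_pipeline_config(**overrides) -> PipelineConfig:
    base = dict(
        placements=(Placement.RF,),
        selection_params={"num_boost_round": 8, "max_depth": 3, "max_bin": 32},
        classifier_params={"num_boost_round": 15, "max_depth": 3,
                           "learning_rate": 0.4, "max_bin": 32},
        train_stride=3,
        seed=0,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def noiseless_models():
    models = default_signal_models()
    return {
        lab: StepSignalModel(
            oscillation_hz=m.oscillation_hz,
            accel_amplitude=m.accel_amplitude,
            gyro_amplitude=m.gyro_amplitude,
            mean_orientation=m.mean_orientation,
            emg_envelope=m.emg_envelope,
            noise_sd={k: 0.0 for k in DEFAULT_NOISE_SD},
        )
        for lab, m in models.items()
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 participants x 4 short sessions (one per condition), 4 placements."""
    return generate_cohort(fast_sim_config())


@pytest.fixture(scope="session")
def one_session(tiny_cohort):
    return tiny_cohort[0]
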