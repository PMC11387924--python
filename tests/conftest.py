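"""Shared fixtures: small synthetic nights kept fast enough for CI."""

import numpy as np
import pytest

from nightvitals import (
    EpochSeries,
    Hypnogram,
    SimulationConfig,
    make_cohort,
    simulate_hypnogram,
)
from nightvitals.epochs import REFERENCE_STAGES, epoch_grid
from nightvitals.records import DeviceNight, NightRecord
from nightvitals.simulate import DeviceModel, true_vitals_series


@pytest.fixture(scope="session")
def small_config():
    """A 2-hour night keeps beat/waveform synthesis cheap in unit tests."""
    return SimulationConfig(n_participants=5, night_duration_s=7200, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from nightvitals import emfit_model, somnofy_model, wsa_model

    return make_cohort(small_config,
                       [wsa_model(), emfit_model(), somnofy_model()], seed=7)


def constant_hypnogram(n_epochs, stage="N2", epoch_s=30.0):
    grid = epoch_grid(n_epochs * epoch_s, epoch_s)
    return Hypnogram(grid, np.repeat(stage, n_epochs), epoch_s,
                     vocabulary=REFERENCE_STAGES)


def identity_device(name="ideal", **overrides):
    """A device model with every corruption parameter switched off."""
    params = dict(name=name, epoch_s=30.0, stage_accuracy=1.0)
    params.update(overrides)
    return DeviceModel(**params)


def truth_record(pid, config, seed, device_models=(), stage_structured=True,
                 hr_offset=0.0, br_offset=0.0):
    """A NightRecord whose reference series are the noise-free truth,
    with devices observing that same truth — the controlled setting for
    identity and parameter-recovery checks."""
    from nightvitals.simulate import apply_device_model

    if stage_structured:
        hyp = simulate_hypnogram(config, seed)
    else:
        hyp = constant_hypnogram(config.n_epochs)
    true_hr, true_br = true_vitals_series(hyp, config, hr_offset, br_offset)
    record = NightRecord(participant_id=pid, ref_hr=true_hr, ref_br=true_br,
                         hypnogram=hyp, lights_off_s=0.0,
                         lights_on_s=config.night_duration_s)
    for i, model in enumerate(device_models):
        hr, br, dev_hyp = apply_device_model(true_hr, true_br, hyp, model,
                                             seed=seed * 1000 + i)
        record.devices[model.name] = DeviceNight(device=model.name, hr=hr,
                                                 br=br, hypnogram=dev_hyp)
    return record
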