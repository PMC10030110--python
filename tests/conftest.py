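import numpy as np
import pytest

import terrarun as tr


@pytest.fixture(scope="session")
def subject():
    return tr.SubjectParams()


@pytest.fixture(scope="session")
def flat_field():
    return tr.generate_terrain(tr.terrain_spec("flat", length=10.0))


@pytest.fixture(scope="session")
def uneven1_small():
    """A short uneven-I-class field for unit tests."""
    return tr.generate_terrain(tr.terrain_spec("uneven1", seed=11, length=8.0))


@pytest.fixture(scope="session")
def uneven2_small():
    return tr.generate_terrain(tr.terrain_spec("uneven2", seed=12, length=8.0))


@pytest.fixture(scope="session")
def uneven1_table(uneven1_small):
    return tr.PatchStatTable(uneven1_small)


@pytest.fixture(scope="session")
def clean_flat_trial(flat_field):
    """Noise-free trial with deterministic per-step parameters."""
    gait = tr.GaitSpec(seed=1, duration_s=25.0, step_length_sd=0.0,
                       step_width_sd=0.0, foot_landing_speed_sd=0.0,
                       marker_noise_sd=0.0, force_noise_sd=0.0)
    markers, forces, truth = tr.generate_trial(gait, flat_field)
    return gait, markers, forces, truth


@pytest.fixture(scope="session")
def variable_flat_trial(flat_field):
    """Noise-free markers but per-step variability in the gait."""
    gait = tr.GaitSpec(seed=2, duration_s=25.0, marker_noise_sd=0.0,
                       force_noise_sd=0.5)
    markers, forces, truth = tr.generate_trial(gait, flat_field)
    return gait, markers, forces, truth


def non_turnaround_steps(truth):
    """Indices of ground-truth steps away from direction reversals and
    the trace boundaries (where the capture volume would end)."""
    flips = np.flatnonzero(np.diff(truth.directions) != 0)
    excl = set()
    for f in flips:
        excl.update((f - 1, f, f + 1))
    excl.update((0, truth.touchdown_times.size - 1))
    return [k for k in range(truth.touchdown_times.size) if k not in excl]
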