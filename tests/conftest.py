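import numpy as np
import pytest

from claysub.core import Arm, ExperimentDataset, PairedReplicate, Scale, UnitMeasurement
from claysub.synth import SynthSpec, generate_dataset


def make_unit(
    arm="loaded",
    clay=50.0,
    initial_wood=3.44,
    leftover=1.15,
    initial_volume=207.0,
    final_volume=None,
):
    if final_volume is None:
        final_volume = initial_volume if arm == "unloaded" else 0.5 * initial_volume
    return UnitMeasurement(
        arm=Arm(arm),
        clay_mass=clay,
        initial_wood=initial_wood,
        leftover_wood=leftover,
        initial_volume=initial_volume,
        final_volume=final_volume,
    )


def make_replicate(rid="r1", contacted=True, **loaded_kw):
    return PairedReplicate(
        replicate_id=rid,
        unloaded=make_unit("unloaded", clay=40.0, leftover=0.4),
        loaded=make_unit("loaded", **loaded_kw),
        contacted_both=contacted,
    )


def make_dataset(flags, scale="lab"):
    reps = tuple(make_replicate(rid=f"r{i}", contacted=f) for i, f in enumerate(flags))
    return ExperimentDataset(scale=Scale(scale), replicates=reps, duration_days=30)


@pytest.fixture(scope="session")
def lab_dataset():
    return generate_dataset(SynthSpec.lab_defaults(seed=7))


@pytest.fixture(scope="session")
def field_dataset():
    return generate_dataset(SynthSpec.field_defaults(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
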